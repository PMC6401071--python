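"""Fusion-status differential expression, hypergeometric enrichment and
copy-number association."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fusionscape.breakage import BreakageNullConfig
from fusionscape.calls import FusionCall
from fusionscape.expression import (ExpressionMatrix, FusionExpressionModel,
                                    active_gene_enrichment,
                                    copy_number_association,
                                    fusion_expression_test,
                                    fusion_status_matrix, rank_sum_test)


def _call(sample, gene):
    return FusionCall(sample=sample, gene5=gene, gene3="OTHER",
                      chrom5="chr1", pos5=1, strand5="+",
                      chrom3="chr2", pos3=2, strand3="+", probability=0.9)


class TestStatusMatrix:
    def test_indicator_rows(self):
        calls = [_call("s1", "A"), _call("s3", "A")]
        m = fusion_status_matrix(calls, ["s1", "s2", "s3", "s4"], ["A", "B"])
        assert m.loc["A"].tolist() == [1, 0, 1, 0]
        assert m.loc["B"].tolist() == [0, 0, 0, 0]

    def test_unknown_sample_ignored_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            m = fusion_status_matrix([_call("zz", "A")], ["s1"], ["A"])
        assert m.loc["A", "s1"] == 0
        assert any("absent" in r.message for r in caplog.records)


def brute_force_ranksum_p(x, y):
    """Exhaustive enumeration of all rank assignments (independent oracle)."""
    pooled = np.concatenate([x, y])
    m = len(x)
    ranks = stats.rankdata(pooled)
    obs = ranks[:m].sum()
    us = np.array([ranks[list(c)].sum()
                   for c in combinations(range(len(pooled)), m)])
    p = 2 * min((us >= obs).sum(), (us <= obs).sum()) / len(us)
    return min(1.0, p)


class TestRankSum:
    def test_known_exact_p_small_groups(self):
        p, const = rank_sum_test(np.array([10., 12, 14]),
                                 np.array([1., 2, 3, 4, 5]))
        assert p == pytest.approx(2 / 56)
        assert not const

    def test_matches_enumeration_for_small_groups(self):
        rng = np.random.default_rng(2)
        for m, n in [(3, 4), (5, 5), (2, 8), (6, 3)]:
            x = rng.normal(0, 1, m)
            y = rng.normal(1, 1, n)
            p, _ = rank_sum_test(x, y)
            assert p == pytest.approx(brute_force_ranksum_p(x, y), abs=1e-12)

    def test_constant_input_flagged(self):
        p, const = rank_sum_test(np.array([2., 2]), np.array([2., 2, 2]))
        assert p == 1.0 and const


class TestFusionExpressionTest:
    def test_exact_example_row(self):
        expr = pd.DataFrame(
            [[10, 12, 14, 1, 2, 3, 4, 5]], index=["G"],
            columns=[f"s{i}" for i in range(8)], dtype=float)
        status = pd.DataFrame([[1, 1, 1, 0, 0, 0, 0, 0]], index=["G"],
                              columns=expr.columns)
        rows = fusion_expression_test(expr, status, min_positives=3)
        r = rows[0]
        assert r.p_value == pytest.approx(2 / 56)
        assert r.fold_change == pytest.approx(12.01 / 3.01)
        assert r.fold_change == pytest.approx(4.0, abs=0.02)
        assert r.q_value == r.p_value  # single test

    def test_too_few_positives_skipped(self):
        expr = pd.DataFrame(np.ones((2, 6)), index=["A", "B"],
                            columns=[f"s{i}" for i in range(6)])
        status = pd.DataFrame([[1, 1, 0, 0, 0, 0], [1, 1, 1, 0, 0, 0]],
                              index=["A", "B"], columns=expr.columns)
        rows = fusion_expression_test(expr, status, min_positives=3)
        assert [r.gene for r in rows] == ["B"]
        assert rows[0].constant  # all values equal

    def test_bh_qvalues_are_step_up(self, null_cohort, null_filtered):
        expr = null_cohort.expression
        status = fusion_status_matrix(null_filtered, list(expr.columns),
                                      list(expr.index))
        rows = fusion_expression_test(expr, status)
        p = np.array(sorted(r.p_value for r in rows))
        q = np.array(sorted(r.q_value for r in rows))
        m = len(p)
        manual = np.minimum.accumulate((p * m / np.arange(1, m + 1))[::-1]) \
            [::-1]
        assert np.allclose(q, np.sort(manual))
        assert (q >= p - 1e-12).all()

    def test_null_cohort_type_one_error_controlled(self, null_cohort,
                                                   null_filtered):
        rows = FusionExpressionModel(null_cohort.expression,
                                     null_filtered).fit().rows
        p = np.array([r.p_value for r in rows])
        q = np.array([r.q_value for r in rows])
        assert (p < 0.05).mean() <= 0.10   # twice the nominal level
        assert (q < 0.05).mean() <= 0.10

    def test_planted_recovery(self, recovery_cohort, recovery_filtered):
        res = FusionExpressionModel(recovery_cohort.expression,
                                    recovery_filtered).fit()
        planted = {e["gene"] for e in recovery_cohort.manifest.planted_genes}
        sig = {r.gene for r in res.significant(0.01)}
        assert len(planted & sig) >= 18
        # no forced downregulation: planted folds all above 1
        by_gene = {r.gene: r for r in res.rows}
        assert all(by_gene[g].fold_change > 1 for g in planted)


def direct_hypergeom_sum(k, M, n, K):
    return sum(math.comb(n, i) * math.comb(M - n, K - i) / math.comb(M, K)
               for i in range(k, min(n, K) + 1))


class TestActiveGeneEnrichment:
    def test_direct_summation_example(self):
        universe = [f"g{i}" for i in range(100)]
        fusion = [f"g{i}" for i in (0, 3, 7, 11, 19, 30, 40, 55, 70, 90)]
        res = active_gene_enrichment(fusion, universe, top_n=20)
        k = res["overlap"].iloc[0]
        assert k == 5
        assert res["p_value"].iloc[0] == pytest.approx(
            direct_hypergeom_sum(5, 100, 20, 10))

    def test_degenerate_cases(self):
        universe = [f"g{i}" for i in range(50)]
        res = active_gene_enrichment(["g49"], universe, top_n=50)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)
        # k = 0: P(X >= 0) = 1
        res0 = active_gene_enrichment(["g49"], universe, top_n=1)
        assert res0["p_value"].iloc[0] == pytest.approx(1.0)

    def test_gene_outside_universe_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            res = active_gene_enrichment(["g1", "nope"],
                                         [f"g{i}" for i in range(30)],
                                         top_n=5)
        assert res["n_fusion_genes"].iloc[0] == 1


class TestCopyNumberAssociation:
    def test_null_cohort_unit_folds(self, null_cohort, null_filtered):
        res = copy_number_association(
            null_filtered, null_cohort.copy_number,
            BreakageNullConfig(500, seed=2))
        for st, r in res.items():
            if r.null_mean > 20:
                assert 0.8 < r.fold_enrichment < 1.25

    def test_amplification_coupling_detected(self, recovery_cohort,
                                             recovery_filtered):
        res = copy_number_association(
            recovery_filtered, recovery_cohort.copy_number,
            BreakageNullConfig(500, seed=2))
        assert res[2].fold_enrichment > 1.2
        assert res[2].p_value < 0.01

    def test_single_state_everywhere(self):
        cn = pd.DataFrame(np.zeros((3, 4), dtype=int),
                          index=["A", "B", "C"],
                          columns=[f"s{i}" for i in range(4)])
        calls = [_call("s0", "A"), _call("s1", "B")]
        res = copy_number_association(calls, cn,
                                      BreakageNullConfig(200, seed=0))
        assert res[0].fold_enrichment == pytest.approx(1.0)
        assert res[0].p_value == 1.0

    def test_no_overlap_errors(self):
        cn = pd.DataFrame(np.zeros((1, 1), dtype=int), index=["X"],
                          columns=["sX"])
        with pytest.raises(ValueError):
            copy_number_association([_call("s0", "A")], cn)


class TestExpressionMatrix:
    def test_rejects_negative_and_duplicates(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(pd.DataFrame([[-1.0]], index=["g"],
                                          columns=["s"]))
        with pytest.raises(ValueError):
            ExpressionMatrix(pd.DataFrame([[1.0], [2.0]],
                                          index=["g", "g"], columns=["s"]))

    def test_tsv_round_trip(self, tmp_path):
        df = pd.DataFrame(np.arange(6, dtype=float).reshape(2, 3),
                          index=["a", "b"], columns=["s1", "s2", "s3"])
        m = ExpressionMatrix(df)
        m.to_tsv(tmp_path / "e.tsv")
        back = ExpressionMatrix.from_tsv(tmp_path / "e.tsv")
        pd.testing.assert_frame_equal(back.data, df,
                                      check_names=False)
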