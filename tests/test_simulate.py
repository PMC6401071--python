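"""Synthetic cohort generator: determinism, planted structure, fixture IO."""

import numpy as np
import pandas as pd
import pytest

from fusionscape.calls import (filter_by_probability, read_defuse_table,
                               subtract_panel_of_normals)
from fusionscape.genome import BreakpointLaw, write_gtf
from fusionscape.simulate import (CohortConfig, PlantedAnchor, PlantedGene,
                                  simulate_cohort, simulate_genome)


class TestGenome:
    def test_gene_counts(self):
        cfg = CohortConfig(seed=5, n_chromosomes=2,
                           genes_per_chromosome=(50, 50),
                           planted_genes=[], planted_anchors=[])
        _, transcripts, loci = simulate_genome(cfg)
        assert len(loci) == 100
        assert all(t.is_coding for t in transcripts.values())

    def test_deterministic_gtf_bytes(self, tmp_path):
        cfg = CohortConfig(seed=5, n_chromosomes=2,
                           genes_per_chromosome=(20, 20),
                           planted_genes=[], planted_anchors=[])
        for name in ("a.gtf", "b.gtf"):
            _, transcripts, _ = simulate_genome(cfg)
            write_gtf(transcripts.values(), tmp_path / name)
        assert (tmp_path / "a.gtf").read_bytes() == \
            (tmp_path / "b.gtf").read_bytes()

    def test_first_introns_longer_than_last(self):
        cfg = CohortConfig(seed=7, n_chromosomes=5,
                           genes_per_chromosome=tuple([200] * 5),
                           planted_genes=[], planted_anchors=[])
        _, transcripts, _ = simulate_genome(cfg)
        first, last = [], []
        for t in transcripts.values():
            gaps = [t.exons[i + 1][0] - t.exons[i][1]
                    for i in range(len(t.exons) - 1)]
            if len(gaps) < 2:
                continue
            if t.strand == "-":
                gaps = gaps[::-1]
            first.append(gaps[0])
            last.append(gaps[-1])
        assert len(first) > 900
        assert np.mean(first) > np.mean(last)

    def test_infeasible_packing_names_chromosome(self):
        cfg = CohortConfig(seed=5, n_chromosomes=1,
                           genes_per_chromosome=(50,),
                           chromosome_length=10_000,
                           planted_genes=[], planted_anchors=[])
        with pytest.raises(ValueError, match="chr1"):
            simulate_genome(cfg)


class TestFusions:
    def test_full_intrachromosomal_config(self):
        cfg = CohortConfig(seed=3, n_tumors=20, n_chromosomes=4,
                           genes_per_chromosome=tuple([30] * 4),
                           intrachromosomal_prop=1.0,
                           planted_genes=[], planted_anchors=[],
                           fp_pool_size=0, fp_reserved_genes=0,
                           fp_calls_per_tumor_mean=0.0)
        cohort = simulate_cohort(cfg)
        assert all(not c.interchromosomal for c in cohort.tumor_calls)

    def test_burden_median_near_target(self, recovery_filtered):
        counts = pd.Series([c.sample for c in recovery_filtered]) \
            .value_counts()
        assert abs(counts.median() - 21) <= 3

    def test_every_fp_pool_pair_in_normals(self, recovery_cohort):
        normal_pairs = {frozenset((c.gene5, c.gene3))
                        for c in recovery_cohort.normal_calls}
        pool = {frozenset(p) for p in recovery_cohort.manifest.fp_pairs}
        assert pool == normal_pairs

    def test_post_filter_calls_equal_manifest_truth(self, recovery_cohort,
                                                    recovery_filtered):
        key = lambda c: (c.sample, c.gene5, c.gene3, c.pos5, c.pos3)
        assert {key(c) for c in recovery_filtered} == \
            {key(c) for c in recovery_cohort.true_calls}

    def test_intrachromosomal_proportion_recovered(self, recovery_filtered):
        intra = np.mean([not c.interchromosomal for c in recovery_filtered])
        assert abs(intra - 0.70) <= 0.03

    def test_single_exon_genome_matches_cdna_uniform_null(self):
        """With no introns and no region reweighting, breakpoint region
        proportions converge to the cDNA region length fractions."""
        cfg = CohortConfig(seed=13, n_tumors=60, n_chromosomes=4,
                           genes_per_chromosome=tuple([40] * 4),
                           exon_count_range=(1, 1),
                           exon_length_range=(1500, 2500),
                           region_weights5=None, region_weights3=None,
                           planted_genes=[], planted_anchors=[],
                           fp_pool_size=0, fp_reserved_genes=0,
                           fp_calls_per_tumor_mean=0.0)
        cohort = simulate_cohort(cfg)
        laws = {t.gene: BreakpointLaw.of(t)
                for t in cohort.transcripts.values()}
        expected, observed = np.zeros(3), np.zeros(3)
        from fusionscape.genome import classify_cdna_region, REGIONS
        for c in cohort.tumor_calls:
            for gene, cdna in ((c.gene5, c.cdna5), (c.gene3, c.cdna3)):
                expected += laws[gene].region_probs()
                t = laws[gene].transcript
                observed[REGIONS.index(classify_cdna_region(t, cdna))] += 1
        n = observed.sum()
        for k in range(3):
            se = np.sqrt(expected[k] / n * (1 - expected[k] / n) / n)
            assert abs(observed[k] / n - expected[k] / n) < 4 * se + 1e-9


class TestExpressionEffects:
    def test_planted_fold_recovered_in_medians(self):
        cfg = CohortConfig(seed=21, n_tumors=200, n_chromosomes=6,
                           genes_per_chromosome=tuple([50] * 6),
                           planted_genes=[PlantedGene(fold=8.0,
                                                      n_positive=20)],
                           planted_anchors=[])
        cohort = simulate_cohort(cfg)
        entry = cohort.manifest.planted_genes[0]
        pos = entry["positive_samples"]
        neg = [s for s in cohort.expression.columns if s not in set(pos)]
        row = cohort.expression.loc[entry["gene"]]
        ratio = row[pos].median() / row[neg].median()
        assert 6 <= ratio <= 10

    def test_anchor_kernel_fold_profile(self, recovery_cohort):
        entry = recovery_cohort.manifest.planted_anchors[0]
        gene, F, L = entry["gene"], entry["peak_fold"], entry["decay_bp"]
        pos = set(entry["positive_samples"])
        loc = recovery_cohort.loci[gene]
        expr = recovery_cohort.expression
        neg = [s for s in expr.columns if s not in pos]
        pos = [s for s in expr.columns if s in pos]
        for g in recovery_cohort.loci.values():
            if g.chrom != loc.chrom or g.symbol == gene:
                continue
            d = abs(g.midpoint - loc.midpoint)
            if d > 1.5 * L:
                continue
            want = 1.0 + (F - 1.0) * max(0.0, 1.0 - d / L)
            row = expr.loc[g.symbol]
            got = row[pos].median() / row[neg].median()
            # multiplicative noise sigma(ln)=0.5 over ~19 positives
            assert abs(np.log(got) - np.log(want)) < 0.5

    def test_effect_free_cohort_has_unit_folds(self, null_cohort,
                                               null_filtered):
        from fusionscape.expression import fusion_status_matrix
        expr = null_cohort.expression
        status = fusion_status_matrix(null_filtered, list(expr.columns),
                                      list(expr.index))
        X = expr.to_numpy()
        S = status.to_numpy().astype(bool)
        lfs = []
        for i in range(X.shape[0]):
            if 3 <= S[i].sum() <= X.shape[1] - 3:
                lfs.append(np.log2(X[i, S[i]].mean() / X[i, ~S[i]].mean()))
        lfs = np.array(lfs)
        assert abs(np.mean(lfs)) < 0.02
        assert np.abs(lfs).max() < 1.5


class TestFixtureIO:
    def test_fixture_files_and_round_trip(self, tmp_path, tiny_cohort):
        paths = tiny_cohort.write_fixture(tmp_path / "fx")
        assert len(paths) == 8
        for p in paths.values():
            assert p.exists()
        back = read_defuse_table(paths["tumor_calls"])
        assert len(back) == len(tiny_cohort.tumor_calls)
        key = lambda c: (c.sample, c.gene5, c.gene3, c.pos5, c.pos3,
                         round(c.probability, 9))
        assert {key(c) for c in back} == \
            {key(c) for c in tiny_cohort.tumor_calls}

    def test_manifest_lists_planted_genes(self, tmp_path, recovery_cohort):
        from fusionscape.simulate import TruthManifest
        p = tmp_path / "m.json"
        recovery_cohort.manifest.to_json(p)
        m = TruthManifest.from_json(p)
        assert len(m.planted_genes) == 20
        assert len(m.planted_anchors) == 10
        assert all(e["gene"] in recovery_cohort.loci
                   for e in m.planted_genes + m.planted_anchors)

    def test_seed_determinism_of_expression(self):
        cfg = dict(seed=33, n_tumors=10, n_chromosomes=2,
                   genes_per_chromosome=(15, 15),
                   planted_genes=[], planted_anchors=[])
        a = simulate_cohort(CohortConfig(**cfg))
        b = simulate_cohort(CohortConfig(**cfg))
        pd.testing.assert_frame_equal(a.expression, b.expression)
        assert [c.pos5 for c in a.tumor_calls] == \
            [c.pos5 for c in b.tumor_calls]


class TestConfigValidation:
    def test_bad_proportion_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(intrachromosomal_prop=1.4)

    def test_bad_region_weights_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(region_weights5=(0.5, 0.2, 0.2))

    def test_anchor_decay_bounded_by_window(self):
        with pytest.raises(ValueError):
            CohortConfig(planted_anchors=[
                PlantedAnchor(peak_fold=3.0, decay_bp=2e6, n_positive=5)])
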