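"""Breakage-and-rejoin null: closed forms, permutation tests, KS machinery."""

import numpy as np
import pytest

from fusionscape.breakage import (BreakageNullConfig, RegionProfile,
                                  cds_positional_test, compare_region_profiles,
                                  expected_intrachromosomal_fraction,
                                  expected_region_distribution,
                                  intrachromosomal_enrichment,
                                  region_enrichment_test)
from fusionscape.calls import FusionCall
from fusionscape.genome import (BreakpointLaw, ChromosomeTable,
                                TranscriptModel)
from fusionscape.hg19 import hg19_table

from conftest import random_transcript


def _call_on(t5, g5, t3, g3, sample="s"):
    return FusionCall(sample=sample, gene5=t5.gene, gene3=t3.gene,
                      chrom5=t5.chrom, pos5=g5, strand5=t5.strand,
                      chrom3=t3.chrom, pos3=g3, strand3=t3.strand,
                      probability=0.9, transcript5=t5.transcript_id,
                      transcript3=t3.transcript_id)


class TestExpectedIntrachromosomalFraction:
    def test_single_chromosome(self):
        assert expected_intrachromosomal_fraction(
            ChromosomeTable(("c1",), (100,))) == 1.0

    def test_two_equal_chromosomes(self):
        # closed form 2L^2 / (2L)^2 = 1/2
        t = ChromosomeTable(("a", "b"), (500, 500))
        assert expected_intrachromosomal_fraction(t) == pytest.approx(0.5)

    def test_hg19_value_and_fold_rounding(self):
        q = expected_intrachromosomal_fraction(hg19_table())
        assert q == pytest.approx(0.0497, abs=0.001)
        assert round(0.708 / q) == 14

    def test_simulation_converges_to_closed_form(self):
        rng = np.random.default_rng(8)
        for _ in range(3):
            n = int(rng.integers(2, 12))
            t = ChromosomeTable(tuple(f"c{i}" for i in range(n)),
                                tuple(int(x) for x in
                                      rng.integers(10**6, 10**8, n)))
            q = expected_intrachromosomal_fraction(t)
            sim = expected_intrachromosomal_fraction(
                t, BreakageNullConfig(100_000, seed=3), analytic=False)
            se = np.sqrt(q * (1 - q) / 100_000)
            assert abs(sim - q) < 3 * se + 1e-12


class TestIntrachromosomalEnrichment:
    def test_single_chromosome_null_is_saturated(self):
        table = ChromosomeTable(("c1",), (10_000,))
        t = TranscriptModel("t", "G", "c1", "+", ((0, 500),), 100, 400)
        calls = [_call_on(t, 10, t, 20)] * 5
        r = intrachromosomal_enrichment(calls, table,
                                        BreakageNullConfig(2000, seed=0))
        assert r.fold_enrichment == pytest.approx(1.0)
        assert r.p_value == 1.0

    def test_depletion_gives_fold_below_one(self):
        table = ChromosomeTable(("c1", "c2"), (1000, 1000))
        t1 = TranscriptModel("t1", "A", "c1", "+", ((0, 500),), 100, 400)
        t2 = TranscriptModel("t2", "B", "c2", "+", ((0, 500),), 100, 400)
        calls = [_call_on(t1, 10, t2, 20)] * 40  # all interchromosomal
        r = intrachromosomal_enrichment(calls, table,
                                        BreakageNullConfig(2000, seed=0))
        assert r.fold_enrichment < 1.0
        assert r.p_value > 0.5

    def test_p_floor_and_determinism(self, recovery_filtered,
                                     recovery_cohort):
        cfg = BreakageNullConfig(5000, seed=4)
        a = intrachromosomal_enrichment(recovery_filtered,
                                        recovery_cohort.chrom_table, cfg)
        b = intrachromosomal_enrichment(recovery_filtered,
                                        recovery_cohort.chrom_table, cfg)
        assert a == b
        assert a.p_value >= 1 / 5001


class TestExpectedRegionDistribution:
    def test_single_exon_gene_is_cdna_uniform(self):
        t = TranscriptModel("s", "G", "chr1", "+", ((0, 600),), 100, 400)
        d = expected_region_distribution([t])
        assert d["region_proportions"] == pytest.approx(
            {"UTR5": 1 / 6, "CDS": 1 / 2, "UTR3": 1 / 3})

    def test_huge_intron_in_cds_shifts_mass_5prime(self):
        """An intron near the CDS 5' end projects its mass onto the donor
        junction, raising the CDS proportion and shifting relative CDS
        position mass toward 0."""
        no_intron = TranscriptModel("a", "G", "chr1", "+", ((0, 600),),
                                    100, 400)
        # same cDNA, but a 50 kb intron after cDNA base 150 (CDS-resident)
        with_intron = TranscriptModel(
            "b", "G", "chr1", "+", ((0, 150), (50_150, 50_600)), 100, 50_400)
        assert with_intron.cdna_length == 600
        assert (with_intron.utr5_length, with_intron.cds_length) == (100, 300)
        d0 = expected_region_distribution([no_intron])
        d1 = expected_region_distribution([with_intron])
        assert d1["region_proportions"]["CDS"] > \
            d0["region_proportions"]["CDS"]
        h0, h1 = d0["relative_cds_histogram"], d1["relative_cds_histogram"]
        # the intron atom sits at relative position (149-100)/300 ~ 0.16,
        # so nearly all CDS mass falls in the first fifth of the CDS
        k = len(h1) // 5
        assert h1[:k].sum() > 0.9
        assert h0[:k].sum() < 0.3

    def test_matches_per_base_enumeration(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            t = random_transcript(rng)
            law = BreakpointLaw.of(t)
            counts = law.region_counts()
            d = expected_region_distribution([t])
            total = sum(counts.values())
            for r, c in counts.items():
                assert d["region_proportions"][r] == pytest.approx(c / total)
            assert sum(d["region_proportions"].values()) == pytest.approx(1.0)

    def test_no_coding_transcripts_errors(self):
        t = TranscriptModel("n", "G", "chr1", "+", ((0, 500),))
        with pytest.raises(ValueError):
            expected_region_distribution([t])


class TestRegionEnrichmentTest:
    def test_single_call_respects_p_floor(self):
        t = TranscriptModel("t", "G", "chr1", "+", ((0, 600),), 100, 400)
        calls = [_call_on(t, 10, t, 550)]
        res = region_enrichment_test(calls, {"t": t},
                                     BreakageNullConfig(1000, seed=0))
        for r in res.values():
            assert r.p_value >= 1 / 1001

    def test_utr_bias_detected_at_500_calls(self, null_cohort):
        """Breakpoints reweighted toward UTRs give enrichment p < 0.01."""
        rng = np.random.default_rng(3)
        ts = list(null_cohort.transcripts.values())[:250]
        calls = []
        for i in range(250):
            t5, t3 = ts[i], ts[(i + 7) % 250]
            l5, l3 = BreakpointLaw.of(t5), BreakpointLaw.of(t3)
            region5 = ["UTR5", "CDS", "UTR3"][int(rng.choice(
                3, p=[0.3, 0.4, 0.3]))]
            region3 = ["UTR5", "CDS", "UTR3"][int(rng.choice(
                3, p=[0.3, 0.4, 0.3]))]
            calls.append(_call_on(t5, l5.sample_genomic(rng, region5),
                                  t3, l3.sample_genomic(rng, region3)))
        res = region_enrichment_test(calls, null_cohort.transcripts,
                                     BreakageNullConfig(2000, seed=5))
        assert res["UTR5"].p_value < 0.01
        assert res["UTR3"].p_value < 0.01
        assert res["CDS"].p_value < 0.01  # depletion, two-sided
        assert res["UTR5"].fold_enrichment > 1
        assert res["CDS"].fold_enrichment < 1


class TestCdsPositionalTest:
    def test_point_mass_cds_gives_zero_distance(self):
        # CDS = a single exonic base: every draw lands on the same relative
        # position, so observed and expected are identical point masses
        t = TranscriptModel("t", "G", "chr1", "+", ((0, 600),), 100, 101)
        calls = [_call_on(t, 100, t, 100, sample=f"s{i}") for i in range(10)]
        res = cds_positional_test(calls, {"t": t},
                                  BreakageNullConfig(1000, seed=0))
        assert res["overall"]["statistic"] == pytest.approx(0.0)

    def test_null_calibration(self, null_cohort):
        """Observed positions drawn from the expected law give roughly
        uniform p-values."""
        rng = np.random.default_rng(11)
        ts = list(null_cohort.transcripts.values())[:60]
        ps = []
        for rep in range(40):
            calls = []
            for i in range(30):
                t5, t3 = ts[i], ts[(i + 3) % 60]
                g5 = BreakpointLaw.of(t5).sample_genomic(rng)
                g3 = BreakpointLaw.of(t3).sample_genomic(rng)
                calls.append(_call_on(t5, g5, t3, g3))
            res = cds_positional_test(
                calls, null_cohort.transcripts,
                BreakageNullConfig(1000, seed=int(rng.integers(2 ** 31))))
            ps.append(res["overall"]["p_value"])
        ps = np.array(ps)
        assert (ps < 0.05).mean() <= 0.15
        assert 0.25 <= ps.mean() <= 0.75

    def test_zero_cds_breakpoints_error(self):
        t = TranscriptModel("t", "G", "chr1", "+", ((0, 600),), 100, 400)
        calls = [_call_on(t, 10, t, 550)]  # both in UTRs
        with pytest.raises(ValueError):
            cds_positional_test(calls, {"t": t},
                                BreakageNullConfig(1000, seed=0))


class TestCompareRegionProfiles:
    @staticmethod
    def _profile(u5, cds, u3):
        return RegionProfile(counts={
            "5p": {"UTR5": u5, "CDS": cds, "UTR3": u3},
            "3p": {"UTR5": 0, "CDS": 0, "UTR3": 0}})

    def test_identical_profiles_give_p_one(self):
        a = self._profile(30, 50, 20)
        res = compare_region_profiles(a, self._profile(30, 50, 20))
        assert res["k_sample"]["p_value"] == 1.0
        assert res["k_sample"]["statistic"] == 0.0

    def test_opposite_profiles_give_tiny_p(self):
        res = compare_region_profiles(self._profile(90, 10, 0),
                                      self._profile(10, 90, 0),
                                      region="UTR5")
        assert res["two_sample"]["p_value"] < 1e-15

    def test_proportions_only_input_rejected(self):
        bad = RegionProfile(counts={
            "5p": {"UTR5": 0.3, "CDS": 0.5, "UTR3": 0.2},
            "3p": {"UTR5": 0, "CDS": 0, "UTR3": 0}})
        with pytest.raises(ValueError, match="counts"):
            compare_region_profiles(bad, self._profile(10, 10, 10))
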