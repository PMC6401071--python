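"""Shared fixtures: toy transcripts and session-scoped synthetic cohorts."""

import numpy as np
import pytest

from fusionscape.calls import filter_by_probability, subtract_panel_of_normals
from fusionscape.genome import TranscriptModel, cdna_to_genomic
from fusionscape.simulate import CohortConfig, simulate_cohort


@pytest.fixture
def toy_plus() -> TranscriptModel:
    """Two-exon gene: exons [100,200), [300,450); CDS [150,400); + strand."""
    return TranscriptModel("toy.t1", "TOY", "chr1", "+",
                           ((100, 200), (300, 450)), 150, 400)


@pytest.fixture
def toy_minus() -> TranscriptModel:
    """Same structure on the - strand."""
    return TranscriptModel("toy.t1m", "TOYM", "chr1", "-",
                           ((100, 200), (300, 450)), 150, 400)


def random_transcript(rng: np.random.Generator, coding: bool = True
                      ) -> TranscriptModel:
    """A random small transcript with valid CDS bounds (test helper)."""
    n_ex = int(rng.integers(1, 6))
    exons, pos = [], int(rng.integers(0, 500))
    for _ in range(n_ex):
        length = int(rng.integers(50, 300))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(1, 2000))
    strand = "+" if rng.random() < 0.5 else "-"
    t = TranscriptModel("r.t1", "R", "chr1", strand, tuple(exons))
    if not coding:
        return t
    L = t.cdna_length
    u5 = int(rng.integers(5, L // 3))
    u3 = int(rng.integers(5, L // 3))
    g1 = cdna_to_genomic(t, u5)
    g2 = cdna_to_genomic(t, L - u3 - 1)
    return TranscriptModel("r.t1", "R", "chr1", strand, tuple(exons),
                           min(g1, g2), max(g1, g2) + 1)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Default planted-effect cohort: 24 chromosomes, 200 tumors, 20 planted
    fusion-upregulated genes (fold 4), 10 anchors (peak fold 3, 1 Mb decay),
    70% intrachromosomal fusions."""
    return simulate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def recovery_filtered(recovery_cohort):
    return subtract_panel_of_normals(
        filter_by_probability(recovery_cohort.tumor_calls),
        recovery_cohort.normal_calls)


@pytest.fixture(scope="session")
def null_cohort():
    """Effect-free cohort: 200 samples, 1,000 genes, all effects off."""
    return simulate_cohort(CohortConfig.effect_free(seed=23))


@pytest.fixture(scope="session")
def null_filtered(null_cohort):
    return subtract_panel_of_normals(
        filter_by_probability(null_cohort.tumor_calls),
        null_cohort.normal_calls)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small fast cohort for file round trips and pipeline smoke tests."""
    cfg = CohortConfig(seed=9, n_tumors=40, n_chromosomes=6,
                       genes_per_chromosome=tuple([30] * 6),
                       planted_genes=[], planted_anchors=[])
    return simulate_cohort(cfg)
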