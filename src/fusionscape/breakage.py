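"""Uniform chromosome breakage-and-rejoin null model and breakpoint statistics.

The null assumes a uniform rate of breakage over the genomic space: a fusion
is formed by two breakpoints drawn independently and uniformly over the
concatenated chromosomes.  Under this model the expected same-chromosome
fraction has the closed form sum(L_i^2) / (sum(L_i))^2.  Position statistics
within fused transcripts use the matching per-transcript law: breakpoints
uniform over the transcript's genomic span, intron mass projected onto
donor-side exon junctions (see :mod:`fusionscape.genome`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .calls import FusionCall
from .genome import (REGIONS, BreakpointLaw, ChromosomeTable, TranscriptModel,
                     classify_cdna_region, genomic_to_cdna,
                     relative_cds_position)

logger = logging.getLogger(__name__)


@dataclass
class BreakageNullConfig:
    """Permutation settings for the breakage null."""

    n_permutations: int = 100_000
    seed: int = 0
    space: str = "whole_genome"  # or "transcript_spans"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.n_permutations < 1_000:
            warnings.warn("fewer than 1,000 permutations: reported p-values "
                          "are coarse", stacklevel=2)


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed statistic vs a permutation null."""

    observed: float
    null_mean: float
    fold_enrichment: float
    p_value: float
    n_permutations: int
    seed: int
    tail: str = "greater"  # tail used for the reported p

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0,1]")


@dataclass
class RegionProfile:
    """Breakpoint counts and proportions over cDNA regions, per partner end."""

    counts: dict[str, dict[str, int]]  # end ("5p"/"3p") -> region -> count

    def proportions(self, end: str) -> dict[str, float]:
        c = self.counts[end]
        total = sum(c.values())
        if total == 0:
            raise ValueError(f"no counts for end {end}")
        return {r: c[r] / total for r in REGIONS}

    def pooled_counts(self) -> dict[str, int]:
        return {r: sum(self.counts[e][r] for e in self.counts) for r in REGIONS}


def _add_one_p(n_extreme: int, n_perm: int) -> float:
    return (1 + n_extreme) / (n_perm + 1)


def expected_intrachromosomal_fraction(
    chrom_table: ChromosomeTable,
    config: BreakageNullConfig | None = None,
    analytic: bool = True,
) -> float:
    """Expected same-chromosome fraction of random breakpoint pairs.

    Analytic mode evaluates the closed form sum(L_i^2)/(sum L_i)^2; simulation
    mode draws ``n_permutations`` independent uniform breakpoint pairs over the
    genome and returns the observed same-chromosome fraction.
    """
    L = np.asarray(chrom_table.lengths, dtype=float)
    if analytic:
        return float((L ** 2).sum() / L.sum() ** 2)
    if config is None:
        config = BreakageNullConfig()
    rng = np.random.default_rng(config.seed)
    p = L / L.sum()
    a = rng.choice(len(L), size=config.n_permutations, p=p)
    b = rng.choice(len(L), size=config.n_permutations, p=p)
    return float(np.mean(a == b))


def intrachromosomal_enrichment(
    calls: Sequence[FusionCall],
    chrom_table: ChromosomeTable,
    config: BreakageNullConfig | None = None,
) -> EnrichmentResult:
    """Observed intrachromosomal fraction vs the uniform breakage null.

    Each permutation redraws |calls| breakpoint pairs uniformly over the
    genome; the null fraction is the per-permutation same-chromosome fraction
    (equivalently Binomial(|calls|, q)/|calls| with q the closed form).
    """
    if not calls:
        raise ValueError("need at least one call")
    if config is None:
        config = BreakageNullConfig()
    rng = np.random.default_rng(config.seed)
    n = len(calls)
    observed = sum(not c.interchromosomal for c in calls) / n
    q = expected_intrachromosomal_fraction(chrom_table)
    null = rng.binomial(n, q, size=config.n_permutations) / n
    p = _add_one_p(int(np.sum(null >= observed)), config.n_permutations)
    return EnrichmentResult(
        observed=observed, null_mean=float(null.mean()),
        fold_enrichment=observed / q, p_value=p,
        n_permutations=config.n_permutations, seed=config.seed)


# --------------------------------------------------------------------------- #
# Region-level expectations and tests
# --------------------------------------------------------------------------- #

def expected_region_distribution(
    transcripts: Mapping[str, TranscriptModel] | Sequence[TranscriptModel],
    n_bins: int = 50,
) -> dict:
    """Expected cDNA breakpoint distribution under uniform genomic breakage.

    Aggregates the exact per-transcript law over all coding transcripts,
    weighting each by its genomic span length (a uniform breakpoint over the
    union of spans).  Returns region proportions, a binned distribution of
    relative cDNA position and a binned distribution of relative CDS position.
    Matches exhaustive per-base enumeration exactly.
    """
    ts = list(transcripts.values()) if isinstance(transcripts, Mapping) \
        else list(transcripts)
    ts = [t for t in ts if t.is_coding]
    if not ts:
        raise ValueError("no coding transcripts in annotation")

    region_mass = dict.fromkeys(REGIONS, 0)
    cdna_hist = np.zeros(n_bins)
    cds_hist = np.zeros(n_bins)
    cds_mass = 0.0
    for t in ts:
        law = BreakpointLaw.of(t)
        for r, m in law.region_counts().items():
            region_mass[r] += m
        b0, b1 = t.utr5_length, t.utr5_length + t.cds_length
        # exonic segments: uniform over integer cDNA bases
        for lo, hi in law.segments:
            pos = np.arange(lo, hi)
            cdna_hist += np.bincount(
                np.minimum((pos / t.cdna_length * n_bins).astype(int),
                           n_bins - 1), minlength=n_bins)
            in_cds = pos[(pos >= b0) & (pos < b1)]
            if in_cds.size:
                rel = (in_cds - b0) / t.cds_length
                cds_hist += np.bincount(
                    np.minimum((rel * n_bins).astype(int), n_bins - 1),
                    minlength=n_bins)
                cds_mass += in_cds.size
        for pos, mass in law.atoms:
            cdna_hist[min(int(pos / t.cdna_length * n_bins), n_bins - 1)] += mass
            if b0 <= pos < b1:
                rel = (pos - b0) / t.cds_length
                cds_hist[min(int(rel * n_bins), n_bins - 1)] += mass
                cds_mass += mass

    total = sum(region_mass.values())
    return {
        "region_proportions": {r: region_mass[r] / total for r in REGIONS},
        "region_counts": dict(region_mass),
        "relative_cdna_histogram": cdna_hist / cdna_hist.sum(),
        "relative_cds_histogram": cds_hist / max(cds_mass, 1.0),
        "n_bins": n_bins,
    }


def _resolve_breakpoints(
    calls: Sequence[FusionCall],
    transcripts: Mapping[str, TranscriptModel],
) -> tuple[list[tuple[TranscriptModel, int, str]], int]:
    """Flatten calls into (transcript, cDNA position, end) records.

    cDNA positions are recomputed from genomic coordinates when absent.
    Ends whose transcript cannot be resolved (or is non-coding) are skipped
    and counted.
    """
    by_gene: dict[str, TranscriptModel] = {t.gene: t for t in
                                           transcripts.values()}
    records: list[tuple[TranscriptModel, int, str]] = []
    skipped = 0
    for c in calls:
        for end, tid, gene, pos, cdna in (
                ("5p", c.transcript5, c.gene5, c.pos5, c.cdna5),
                ("3p", c.transcript3, c.gene3, c.pos3, c.cdna3)):
            t = transcripts.get(tid) if tid else by_gene.get(gene)
            if t is None or not t.is_coding:
                skipped += 1
                continue
            if cdna is None:
                try:
                    cdna = genomic_to_cdna(t, pos).position
                except ValueError:
                    skipped += 1
                    continue
            records.append((t, int(cdna), end))
    return records, skipped


def observed_region_profile(
    calls: Sequence[FusionCall],
    transcripts: Mapping[str, TranscriptModel],
) -> RegionProfile:
    """Count observed breakpoint regions per partner end."""
    records, skipped = _resolve_breakpoints(calls, transcripts)
    if skipped:
        logger.warning("%d breakpoint ends unresolvable; excluded", skipped)
    counts = {"5p": dict.fromkeys(REGIONS, 0), "3p": dict.fromkeys(REGIONS, 0)}
    for t, cdna, end in records:
        counts[end][classify_cdna_region(t, cdna)] += 1
    return RegionProfile(counts=counts)


def region_enrichment_test(
    calls: Sequence[FusionCall],
    transcripts: Mapping[str, TranscriptModel],
    config: BreakageNullConfig | None = None,
) -> dict[str, EnrichmentResult]:
    """Two-sided permutation test of breakpoint-region usage per region.

    The null redraws every breakpoint uniformly over its own transcript's
    genomic span (conditioning on which transcripts were fused), so the test
    isolates positional bias from gene selection.  Both enrichment and
    depletion are detectable; the reported p is two-sided with the add-one
    correction.
    """
    if config is None:
        config = BreakageNullConfig()
    rng = np.random.default_rng(config.seed)
    records, skipped = _resolve_breakpoints(calls, transcripts)
    if skipped:
        logger.warning("%d breakpoint ends unresolvable; excluded", skipped)
    if not records:
        raise ValueError("no resolvable breakpoints")

    obs = np.zeros(3, dtype=int)
    law_cache: dict[str, np.ndarray] = {}
    group_n: dict[str, int] = {}
    for t, cdna, _end in records:
        obs[REGIONS.index(classify_cdna_region(t, cdna))] += 1
        if t.transcript_id not in law_cache:
            law_cache[t.transcript_id] = BreakpointLaw.of(t).region_probs()
        group_n[t.transcript_id] = group_n.get(t.transcript_id, 0) + 1

    # each permutation redraws every breakpoint within its own transcript;
    # grouping by transcript turns the redraw into one multinomial per group
    null_counts = np.zeros((config.n_permutations, 3), dtype=np.int64)
    for tid, n_g in group_n.items():
        null_counts += rng.multinomial(n_g, law_cache[tid],
                                       size=config.n_permutations)

    out: dict[str, EnrichmentResult] = {}
    for k, region in enumerate(REGIONS):
        null_k = null_counts[:, k]
        p_hi = _add_one_p(int(np.sum(null_k >= obs[k])), config.n_permutations)
        p_lo = _add_one_p(int(np.sum(null_k <= obs[k])), config.n_permutations)
        p = min(1.0, 2.0 * min(p_hi, p_lo))
        null_mean = float(null_k.mean())
        out[region] = EnrichmentResult(
            observed=float(obs[k]), null_mean=null_mean,
            fold_enrichment=float(obs[k]) / null_mean if null_mean > 0
            else float("inf"),
            p_value=p, n_permutations=config.n_permutations,
            seed=config.seed, tail="two-sided")
    return out


def sample_expected_cds_positions(
    calls: Sequence[FusionCall],
    transcripts: Mapping[str, TranscriptModel],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample relative CDS positions from the conditional breakage null.

    Mirrors the redraw null of :func:`region_enrichment_test` conditioned on
    the breakpoint landing in the CDS: a breakpoint record is chosen with
    probability proportional to its transcript's CDS-landing mass, then a cDNA
    position is drawn from that transcript's law restricted to the CDS.
    """
    records, _ = _resolve_breakpoints(calls, transcripts)
    laws, weights = [], []
    seen: dict[str, int] = {}
    mult: list[int] = []
    for t, _cdna, _end in records:
        if t.transcript_id in seen:
            mult[seen[t.transcript_id]] += 1
            continue
        seen[t.transcript_id] = len(laws)
        law = BreakpointLaw.of(t)
        laws.append(law)
        weights.append(law.region_probs()[1] * law.total_mass)
        mult.append(1)
    w = np.asarray(weights) * np.asarray(mult)
    if w.sum() == 0:
        raise ValueError("no CDS mass among observed transcripts")
    counts = rng.multinomial(n, w / w.sum())
    out = []
    for law, k in zip(laws, counts):
        if k == 0:
            continue
        pos = law.sample_cdna(rng, int(k), region="CDS")
        t = law.transcript
        out.append((pos - t.utr5_length) / t.cds_length)
    return np.concatenate(out)


def cds_positional_test(
    calls: Sequence[FusionCall],
    transcripts: Mapping[str, TranscriptModel],
    config: BreakageNullConfig | None = None,
    expected_sample_factor: int = 10,
) -> dict:
    """Two-sample KS test of observed vs expected relative CDS positions.

    Reports the overall comparison plus the N-terminal ([0, 0.5)) and
    C-terminal ([0.5, 1)) halves separately, each as a two-sample KS between
    the observed positions in that half and a large expected-distribution
    sample restricted to the same half.
    """
    if config is None:
        config = BreakageNullConfig()
    rng = np.random.default_rng(config.seed)
    records, _ = _resolve_breakpoints(calls, transcripts)
    obs = np.array([relative_cds_position(t, cdna)
                    for t, cdna, _end in records
                    if classify_cdna_region(t, cdna) == "CDS"])
    if obs.size == 0:
        raise ValueError("no CDS-resident breakpoints")
    if obs.size < 8:
        warnings.warn("fewer than 8 CDS breakpoints: KS test is underpowered",
                      stacklevel=2)
    n_exp = max(expected_sample_factor * obs.size, 1000)
    exp = sample_expected_cds_positions(calls, transcripts, n_exp, rng)

    def _ks(a: np.ndarray, b: np.ndarray) -> dict:
        if a.size == 0 or b.size == 0:
            return {"statistic": float("nan"), "p_value": float("nan"),
                    "n_observed": int(a.size)}
        res = stats.ks_2samp(a, b, method="asymp")
        return {"statistic": float(res.statistic),
                "p_value": float(res.pvalue), "n_observed": int(a.size)}

    return {
        "overall": _ks(obs, exp),
        "n_terminal": _ks(obs[obs < 0.5], exp[exp < 0.5]),
        "c_terminal": _ks(obs[obs >= 0.5], exp[exp >= 0.5]),
        "n_expected_sample": int(exp.size),
    }


def compare_region_profiles(
    profile_a: RegionProfile,
    profile_b: RegionProfile,
    region: str = "CDS",
    end: str | None = None,
) -> dict:
    """Chi-square homogeneity tests between two cohorts' region profiles.

    The k-sample test uses the full region x cohort contingency table; the
    2-sample test collapses to ``region`` vs rest (2x2, continuity-corrected).
    Profiles must carry raw counts.
    """
    def _counts(p: RegionProfile) -> np.ndarray:
        c = p.counts[end] if end else p.pooled_counts()
        arr = np.array([c[r] for r in REGIONS], dtype=float)
        if not np.allclose(arr, np.round(arr)) or arr.sum() < 1:
            raise ValueError("profiles must carry raw counts, not proportions")
        if arr.sum() <= 3 and np.all(arr <= 1):
            raise ValueError("profiles must carry raw counts, not proportions")
        return arr

    a, b = _counts(profile_a), _counts(profile_b)
    table = np.stack([a, b])
    table = table[:, table.sum(axis=0) > 0]  # drop unobserved regions
    if np.all(a == b):
        k_p = 1.0
        k_stat = 0.0
    else:
        k_stat, k_p, _, expected = stats.chi2_contingency(table,
                                                          correction=False)
        if (expected < 5).any():
            warnings.warn("expected cell count < 5: consider an exact test",
                          stacklevel=2)
    i = REGIONS.index(region)
    t2 = np.array([[a[i], a.sum() - a[i]], [b[i], b.sum() - b[i]]])
    if np.all(t2[0] == t2[1]):
        s2, p2 = 0.0, 1.0
    else:
        s2, p2, _, expected2 = stats.chi2_contingency(t2, correction=True)
        if (expected2 < 5).any():
            warnings.warn("expected cell count < 5: consider an exact test",
                          stacklevel=2)
    return {"k_sample": {"statistic": float(k_stat), "p_value": float(k_p)},
            "two_sample": {"region": region, "statistic": float(s2),
                           "p_value": float(p2)}}


# --------------------------------------------------------------------------- #
# Model / Results wrappers
# --------------------------------------------------------------------------- #

class BreakageNullModel:
    """Breakage-and-rejoin null model fitted to a cohort of fusion calls.

    Parameters
    ----------
    calls : filtered fusion calls
    chrom_table : chromosome lengths defining the genomic space
    transcripts : representative transcript models (for region statistics)
    """

    def __init__(self, calls: Sequence[FusionCall],
                 chrom_table: ChromosomeTable,
                 transcripts: Mapping[str, TranscriptModel] | None = None):
        self.calls = list(calls)
        self.chrom_table = chrom_table
        self.transcripts = dict(transcripts) if transcripts else None

    def fit(self, n_permutations: int = 100_000, seed: int = 0
            ) -> "BreakageNullResults":
        config = BreakageNullConfig(n_permutations=n_permutations, seed=seed)
        intra = intrachromosomal_enrichment(self.calls, self.chrom_table,
                                            config)
        region_tests = region_profile = ks = None
        if self.transcripts:
            region_profile = observed_region_profile(self.calls,
                                                     self.transcripts)
            region_tests = region_enrichment_test(self.calls, self.transcripts,
                                                  config)
            ks = cds_positional_test(self.calls, self.transcripts, config)
        return BreakageNullResults(
            expected_intra=expected_intrachromosomal_fraction(self.chrom_table),
            intrachromosomal=intra, region_profile=region_profile,
            region_tests=region_tests, cds_ks=ks, n_calls=len(self.calls))


@dataclass
class BreakageNullResults:
    """Fitted breakage-null statistics with a text summary."""

    expected_intra: float
    intrachromosomal: EnrichmentResult
    region_profile: RegionProfile | None
    region_tests: dict[str, EnrichmentResult] | None
    cds_ks: dict | None
    n_calls: int

    def summary(self) -> str:
        r = self.intrachromosomal
        lines = [
            "Breakage-and-rejoin null model",
            "=" * 46,
            f"calls analysed:                 {self.n_calls}",
            f"observed intrachromosomal:      {r.observed:.3f}",
            f"expected under uniform null:    {self.expected_intra:.4f}",
            f"fold enrichment:                {r.fold_enrichment:.2f}",
            f"permutation p (n={r.n_permutations}):   {r.p_value:.3g}",
        ]
        if self.region_tests:
            lines.append("-" * 46)
            lines.append("region      observed  null mean  fold     p")
            for region, res in self.region_tests.items():
                lines.append(f"{region:<10} {res.observed:>8.0f}  "
                             f"{res.null_mean:>9.1f}  "
                             f"{res.fold_enrichment:>5.2f}  {res.p_value:.3g}")
        if self.cds_ks:
            c = self.cds_ks["c_terminal"]
            lines.append("-" * 46)
            lines.append(f"CDS C-terminal KS: D={c['statistic']:.3f} "
                         f"p={c['p_value']:.3g} (n={c['n_observed']})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return {
            "expected_intrachromosomal_fraction": self.expected_intra,
            "intrachromosomal": asdict(self.intrachromosomal),
            "region_tests": {k: asdict(v) for k, v in
                             (self.region_tests or {}).items()},
            "region_profile": self.region_profile.counts
            if self.region_profile else None,
            "cds_ks": self.cds_ks,
            "n_calls": self.n_calls,
        }
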