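"""Anchor-gene regional dysregulation scan.

Every gene involved in a retained fusion is an *anchor*.  For each anchor,
genes whose locus midpoint lies within a +/-1 Mb window on the same chromosome
are its neighbors; each (anchor, neighbor) pair contributes a fold change of
the neighbor's expression in anchor-fusion-positive vs -negative samples.
The aggregate picture is a loess-smoothed curve of log2 fold change against
signed genomic distance, judged against a label-randomization null in which
each anchor's fusion-status labels are independently permuted across samples.
Pair-level p-values reuse the same permutations, pooling the null |log2 fold|
values across pairs so the empirical p lattice is fine enough for
Benjamini-Hochberg control across thousands of pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .calls import FusionCall
from .expression import (ExpressionMatrix, FOLD_CHANGE_EPS,
                         fusion_status_matrix, rank_sum_test)
from .genome import ChromosomeTable, GeneLocus

logger = logging.getLogger(__name__)

DEFAULT_HALF_WIDTH = 1_000_000
DEFAULT_SPAN = 0.3
DEFAULT_N_RANDOMIZATIONS = 200


@dataclass
class AnchorWindow:
    """Neighbors of one anchor gene within the +/- half-width window."""

    anchor: str
    neighbors: list[tuple[str, float]]  # (gene, signed midpoint distance)


@dataclass
class RegionalProfile:
    """Aggregate smoothed fold-change profile with randomization envelope."""

    grid: np.ndarray                 # distances
    observed_curve: np.ndarray       # loess of log2 fold on the grid
    envelope_lo: np.ndarray          # pointwise 2.5% null quantile
    envelope_hi: np.ndarray          # pointwise 97.5% null quantile
    n_randomizations: int
    seed: int
    span: float
    null_log2fold: np.ndarray = field(repr=False)  # (n_rand, n_pairs) null

    def exceeds_envelope(self) -> np.ndarray:
        return (self.observed_curve > self.envelope_hi) | \
            (self.observed_curve < self.envelope_lo)


def build_anchor_windows(
    loci: Mapping[str, GeneLocus],
    anchor_genes: Sequence[str],
    half_width: float = DEFAULT_HALF_WIDTH,
) -> list[AnchorWindow]:
    """Neighbors on the anchor's chromosome with |midpoint distance| within
    the half-width; the anchor itself is excluded.  Anchors missing from the
    annotation are skipped with a warning."""
    by_chrom: dict[str, list[GeneLocus]] = {}
    for g in loci.values():
        by_chrom.setdefault(g.chrom, []).append(g)
    windows: list[AnchorWindow] = []
    for anchor in dict.fromkeys(anchor_genes):
        if anchor not in loci:
            logger.warning("anchor %s absent from annotation; skipped", anchor)
            continue
        a = loci[anchor]
        neigh = [(g.symbol, g.midpoint - a.midpoint)
                 for g in by_chrom[a.chrom]
                 if g.symbol != anchor and
                 abs(g.midpoint - a.midpoint) <= half_width]
        neigh.sort(key=lambda x: x[1])
        windows.append(AnchorWindow(anchor=anchor, neighbors=neigh))
    return windows


def _pair_arrays(
    expression: pd.DataFrame,
    windows: Sequence[AnchorWindow],
    status: pd.DataFrame,
    min_positives: int,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray]:
    """Flatten windows into aligned pair arrays.

    Returns (pairs table, neighbor expression matrix (P x S), anchor status
    matrix (A x S), anchor index per pair).
    """
    gene_rows = {g: i for i, g in enumerate(expression.index)}
    anchors, rows = [], []
    skipped = 0
    for w in windows:
        if w.anchor not in status.index:
            skipped += 1
            continue
        svec = status.loc[w.anchor].to_numpy()
        if svec.sum() < min_positives or svec.sum() == svec.size:
            skipped += 1
            continue
        a_idx = len(anchors)
        anchors.append(w.anchor)
        for gene, dist in w.neighbors:
            if gene in gene_rows:
                rows.append((w.anchor, gene, dist, a_idx, gene_rows[gene]))
    if skipped:
        logger.info("%d anchors skipped (missing or < %d positive samples)",
                    skipped, min_positives)
    pairs = pd.DataFrame(rows, columns=["anchor", "neighbor", "distance",
                                        "anchor_idx", "gene_row"])
    E = expression.to_numpy(float)[pairs["gene_row"].to_numpy(int)] \
        if len(pairs) else np.empty((0, expression.shape[1]))
    S = status.loc[anchors].to_numpy(bool) if anchors \
        else np.empty((0, expression.shape[1]), bool)
    return pairs, E, S, pairs["anchor_idx"].to_numpy(int) \
        if len(pairs) else np.empty(0, int)


def _pair_log2folds(E: np.ndarray, S_anchor: np.ndarray,
                    a_idx: np.ndarray) -> np.ndarray:
    """log2 fold change per pair given an anchor-status matrix."""
    St = S_anchor[a_idx]                      # (P, S) positives per pair
    n_pos = St.sum(axis=1)
    n_neg = St.shape[1] - n_pos
    pos_mean = (E * St).sum(axis=1) / n_pos
    neg_mean = (E * ~St).sum(axis=1) / n_neg
    return np.log2((pos_mean + FOLD_CHANGE_EPS) / (neg_mean + FOLD_CHANGE_EPS))


def neighbor_fold_changes(
    expression: ExpressionMatrix | pd.DataFrame,
    windows: Sequence[AnchorWindow],
    status: pd.DataFrame,
    min_positives: int = 3,
) -> pd.DataFrame:
    """Per (anchor, neighbor) fold change and rank-sum p-value.

    Anchors with fewer than ``min_positives`` fusion-positive samples are
    skipped.  Fold changes use the same pseudocount convention as the
    gene-level association screen.
    """
    df = expression.data if isinstance(expression, ExpressionMatrix) \
        else expression
    status = status.reindex(columns=df.columns).fillna(0).astype(np.int8)
    pairs, E, S, a_idx = _pair_arrays(df, windows, status, min_positives)
    if len(pairs) == 0:
        return pairs.assign(fold_change=[], log2_fold=[], p_value=[],
                            n_positive=[])
    lf = _pair_log2folds(E, S, a_idx)
    pvals = np.empty(len(pairs))
    for i in range(len(pairs)):
        mask = S[a_idx[i]]
        pvals[i], _ = rank_sum_test(E[i, mask], E[i, ~mask])
    out = pairs.drop(columns=["gene_row"]).copy()
    out["n_positive"] = S.sum(axis=1)[a_idx]
    out["fold_change"] = 2.0 ** lf
    out["log2_fold"] = lf
    out["p_value"] = pvals
    return out


def _loess_curve(x: np.ndarray, y: np.ndarray, grid: np.ndarray,
                 span: float) -> np.ndarray:
    """Local-linear tricube smoother evaluated on a grid.

    statsmodels' lowess cannot combine ``delta`` with ``xvals``, so the curve
    is computed on the (delta-thinned) data points and linearly interpolated
    onto the grid.
    """
    if np.allclose(y, y[0]):
        return np.full(grid.shape, y[0], dtype=float)
    delta = 0.01 * (x.max() - x.min())
    fitted = lowess(y, x, frac=span, it=0, delta=delta, return_sorted=True)
    xs, ys = fitted[:, 0], fitted[:, 1]
    xs, keep = np.unique(xs, return_index=True)
    return np.interp(grid, xs, ys[keep])


def aggregate_profile(
    expression: ExpressionMatrix | pd.DataFrame,
    windows: Sequence[AnchorWindow],
    status: pd.DataFrame,
    min_positives: int = 3,
    span: float = DEFAULT_SPAN,
    n_randomizations: int = DEFAULT_N_RANDOMIZATIONS,
    seed: int = 0,
    half_width: float = DEFAULT_HALF_WIDTH,
    grid_points: int = 81,
) -> tuple[pd.DataFrame, RegionalProfile]:
    """Observed loess profile of log2 fold vs distance plus randomization null.

    Each randomization independently permutes every anchor's fusion-status
    labels across samples, recomputes all pair log2 folds and the smoothed
    curve; the envelope is the pointwise 2.5%/97.5% quantile band.  The pooled
    per-pair null |log2 fold| values are retained for pair-level calling.
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1; a randomization "
                         "null is required")
    if n_randomizations < 100:
        warnings.warn("fewer than 100 randomizations: envelope quantiles are "
                      "coarse", stacklevel=2)
    df = expression.data if isinstance(expression, ExpressionMatrix) \
        else expression
    status = status.reindex(columns=df.columns).fillna(0).astype(np.int8)
    pairs, E, S, a_idx = _pair_arrays(df, windows, status, min_positives)
    if len(pairs) < 50:
        warnings.warn(f"only {len(pairs)} anchor-neighbor pairs: aggregate "
                      "curve may be unstable", stacklevel=2)
    if len(pairs) == 0:
        raise ValueError("no anchor-neighbor pairs")
    rng = np.random.default_rng(seed)
    x = pairs["distance"].to_numpy(float)
    grid = np.linspace(-half_width, half_width, grid_points)

    lf_obs = _pair_log2folds(E, S, a_idx)
    observed_curve = _loess_curve(x, lf_obs, grid, span)

    null_curves = np.empty((n_randomizations, grid_points))
    null_lf = np.empty((n_randomizations, len(pairs)))
    for b in range(n_randomizations):
        S_perm = rng.permuted(S, axis=1)
        lf_b = _pair_log2folds(E, S_perm, a_idx)
        null_lf[b] = lf_b
        null_curves[b] = _loess_curve(x, lf_b, grid, span)
    lo, hi = np.quantile(null_curves, [0.025, 0.975], axis=0)

    profile = RegionalProfile(
        grid=grid, observed_curve=observed_curve, envelope_lo=lo,
        envelope_hi=hi, n_randomizations=n_randomizations, seed=seed,
        span=span, null_log2fold=null_lf)
    out = pairs.drop(columns=["gene_row"]).copy()
    out["n_positive"] = S.sum(axis=1)[a_idx]
    out["fold_change"] = 2.0 ** lf_obs
    out["log2_fold"] = lf_obs
    return out, profile


def call_dysregulated_genes(
    pairs: pd.DataFrame,
    profile: RegionalProfile,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Pair-level empirical test against the pooled randomization null.

    Each pair's log2 fold is studentized by its own permutation mean and
    standard deviation (pairs differ greatly in positive-group size, so raw
    log folds are not exchangeable across pairs); the standardized null
    values are then pooled across pairs, giving a p lattice fine enough for
    BH across thousands of pairs:
    p = (1 + #{pooled null |z| >= observed |z|}) / (pool size + 1).
    Returns pairs with q < threshold, grouped by neighbor gene.
    """
    if profile.n_randomizations < 1 or profile.null_log2fold.size == 0:
        raise ValueError("a randomization null is required")
    null = profile.null_log2fold
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, np.inf)  # constant pairs can never be called
    obs = np.abs((pairs["log2_fold"].to_numpy(float) - mu) / sd)
    null_z = np.sort(np.abs((null - mu) / sd).ravel())
    n_null = null_z.size
    n_ge = n_null - np.searchsorted(null_z, obs, side="left")
    p = (1 + n_ge) / (n_null + 1)
    q = multipletests(p, method="fdr_bh")[1]
    called = pairs.assign(empirical_p=p, q_value=q)
    called = called[called["q_value"] < q_threshold]
    if called.empty:
        return pd.DataFrame(columns=["neighbor", "anchors", "n_anchors",
                                     "best_q", "max_abs_log2_fold"])
    grouped = called.groupby("neighbor").agg(
        anchors=("anchor", lambda s: sorted(set(s))),
        n_anchors=("anchor", "nunique"),
        best_q=("q_value", "min"),
        max_abs_log2_fold=("log2_fold", lambda s: float(np.abs(s).max())),
    ).reset_index()
    return grouped.sort_values("best_q").reset_index(drop=True)


def top_decile_threshold(
    fold_changes: Sequence[float],
    genes: Sequence[str] | None = None,
) -> tuple[float, list[str]]:
    """90th-percentile fold-change cutoff (linear interpolation) and the genes
    strictly above it, for export to external enrichment tools."""
    fc = np.asarray(fold_changes, float)
    if fc.size < 10:
        raise ValueError("need at least 10 fold changes for a decile cutoff")
    cutoff = float(np.percentile(fc, 90))
    selected: list[str] = []
    if genes is not None:
        selected = sorted({g for g, f in zip(genes, fc) if f > cutoff})
    return cutoff, selected


def chromosome_fusion_ratio(
    calls: Sequence[FusionCall],
    chrom_table: ChromosomeTable,
) -> pd.DataFrame:
    """Per-chromosome observed / expected breakpoint-end ratio (expected
    proportional to chromosome length) — tabular genome-wide summary."""
    counts = dict.fromkeys(chrom_table.names, 0)
    total = 0
    for c in calls:
        for chrom in (c.chrom5, c.chrom3):
            if chrom in counts:
                counts[chrom] += 1
                total += 1
    L = np.asarray(chrom_table.lengths, float)
    expected = L / L.sum() * total
    return pd.DataFrame({
        "chromosome": chrom_table.names,
        "observed": [counts[n] for n in chrom_table.names],
        "expected": expected,
        "ratio": [counts[n] / e if e > 0 else np.nan
                  for n, e in zip(chrom_table.names, expected)],
    })


# --------------------------------------------------------------------------- #
# Model / Results wrappers
# --------------------------------------------------------------------------- #

class RegionalScanModel:
    """Anchor-window regional dysregulation scan over a cohort."""

    def __init__(self, expression: ExpressionMatrix | pd.DataFrame,
                 calls: Sequence[FusionCall],
                 loci: Mapping[str, GeneLocus]):
        self.expression = expression if isinstance(expression,
                                                   ExpressionMatrix) \
            else ExpressionMatrix(expression)
        self.calls = list(calls)
        self.loci = dict(loci)

    def fit(self, half_width: float = DEFAULT_HALF_WIDTH,
            min_positives: int = 3, span: float = DEFAULT_SPAN,
            n_randomizations: int = DEFAULT_N_RANDOMIZATIONS,
            seed: int = 0, q_threshold: float = 0.05,
            anchor_genes: Sequence[str] | None = None
            ) -> "RegionalScanResults":
        anchors = sorted(anchor_genes) if anchor_genes is not None else \
            sorted({g for c in self.calls for g in (c.gene5, c.gene3)})
        status = fusion_status_matrix(self.calls,
                                      list(self.expression.samples), anchors)
        windows = build_anchor_windows(self.loci, anchors, half_width)
        pairs, profile = aggregate_profile(
            self.expression, windows, status, min_positives=min_positives,
            span=span, n_randomizations=n_randomizations, seed=seed,
            half_width=half_width)
        # rank-sum p per pair for the per-pair report
        pair_report = neighbor_fold_changes(self.expression, windows, status,
                                            min_positives)
        called = call_dysregulated_genes(pairs, profile, q_threshold)
        return RegionalScanResults(pairs=pair_report, profile=profile,
                                   called=called, q_threshold=q_threshold)


@dataclass
class RegionalScanResults:
    pairs: pd.DataFrame
    profile: RegionalProfile
    called: pd.DataFrame
    q_threshold: float

    @property
    def n_dysregulated_genes(self) -> int:
        return len(self.called)

    @property
    def n_anchor_genes(self) -> int:
        if self.called.empty:
            return 0
        return len({a for anchors in self.called["anchors"] for a in anchors})

    def summary(self) -> str:
        exceed = self.profile.exceeds_envelope()
        lines = [
            "Regional dysregulation scan",
            "=" * 48,
            f"anchor-neighbor pairs:            {len(self.pairs)}",
            f"randomizations:                   "
            f"{self.profile.n_randomizations}",
            f"grid points outside null band:    {int(exceed.sum())} / "
            f"{exceed.size}",
            f"dysregulated neighbor genes (q<{self.q_threshold:g}): "
            f"{self.n_dysregulated_genes}",
            f"anchor genes implicated:          {self.n_anchor_genes}",
        ]
        return "\n".join(lines)
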