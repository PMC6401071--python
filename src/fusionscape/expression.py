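"""Fusion-status differential expression and related enrichment tests.

For every gene carried by at least ``min_positives`` fusion-positive samples,
fusion-positive and fusion-negative FPKM values are compared with a two-sided
Wilcoxon rank-sum test (exact for small tie-free groups, normal approximation
with tie correction otherwise), fold change is the ratio of group means with a
small pseudocount, and q-values are Benjamini-Hochberg across all tested
genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .breakage import BreakageNullConfig, EnrichmentResult, _add_one_p
from .calls import FusionCall

logger = logging.getLogger(__name__)

#: pseudocount added to both group means before taking the ratio
FOLD_CHANGE_EPS = 0.01

#: copy-number states in a GISTIC-style thresholded matrix
CN_STATES = (-2, -1, 0, 1, 2)


class ExpressionMatrix:
    """Genes x samples FPKM matrix (thin validated pandas wrapper)."""

    def __init__(self, data: pd.DataFrame):
        if data.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if data.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        values = data.to_numpy(float)
        if (values < 0).any():
            raise ValueError("negative FPKM entries")
        self.data = data.astype(float)

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene")


@dataclass(frozen=True)
class GeneAssociationRow:
    """Per-gene fusion-status differential-expression record."""

    gene: str
    n_positive: int
    n_negative: int
    fold_change: float
    p_value: float
    q_value: float
    constant: bool = False


def fusion_status_matrix(
    calls: Sequence[FusionCall],
    samples: Sequence[str],
    genes: Sequence[str],
) -> pd.DataFrame:
    """Binary gene x sample indicator: 1 iff the sample carries a call with
    the gene as either partner.  Calls from samples absent from the matrix are
    ignored with a warning."""
    sample_set = set(samples)
    status = pd.DataFrame(0, index=pd.Index(genes, name="gene"),
                          columns=list(samples), dtype=np.int8)
    gene_set = set(genes)
    missing_samples = set()
    for c in calls:
        if c.sample not in sample_set:
            missing_samples.add(c.sample)
            continue
        for g in (c.gene5, c.gene3):
            if g in gene_set:
                status.at[g, c.sample] = 1
    if missing_samples:
        logger.warning("%d call samples absent from expression matrix; "
                       "ignored", len(missing_samples))
    return status


def fold_change(pos: np.ndarray, neg: np.ndarray,
                eps: float = FOLD_CHANGE_EPS) -> float:
    """(mean FPKM in positives + eps) / (mean FPKM in negatives + eps)."""
    return (float(np.mean(pos)) + eps) / (float(np.mean(neg)) + eps)


def rank_sum_test(pos: np.ndarray, neg: np.ndarray) -> tuple[float, bool]:
    """Two-sided rank-sum p-value; exact for tie-free groups both <= 25.

    Returns (p, constant_flag); a constant combined sample yields p = 1 by
    convention.
    """
    combined = np.concatenate([pos, neg])
    if np.all(combined == combined[0]):
        return 1.0, True
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (len(pos) <= 25 and len(neg) <= 25 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method=method)
    return float(res.pvalue), False


def fusion_expression_test(
    expression: ExpressionMatrix | pd.DataFrame,
    status: pd.DataFrame,
    min_positives: int = 3,
) -> list[GeneAssociationRow]:
    """Per-gene fusion-positive vs fusion-negative rank-sum screen.

    Genes with fewer than ``min_positives`` fusion-positive samples (or with
    no negative samples) are skipped and excluded from the BH multiplicity
    burden.  Rows are sorted by q-value.
    """
    if min_positives < 2:
        raise ValueError("min_positives must be >= 2")
    df = expression.data if isinstance(expression, ExpressionMatrix) \
        else expression
    common = [s for s in df.columns if s in status.columns]
    if not common:
        raise ValueError("no shared samples between expression and status")
    X = df[common].to_numpy(float)
    S = status.reindex(index=df.index, columns=common).fillna(0) \
        .to_numpy(np.int8)
    rows: list[dict] = []
    for gi, gene in enumerate(df.index):
        mask = S[gi].astype(bool)
        n_pos = int(mask.sum())
        n_neg = int((~mask).sum())
        if n_pos < min_positives or n_neg == 0:
            continue
        pos, neg = X[gi, mask], X[gi, ~mask]
        p, const = rank_sum_test(pos, neg)
        rows.append({"gene": gene, "n_positive": n_pos, "n_negative": n_neg,
                     "fold_change": fold_change(pos, neg), "p_value": p,
                     "constant": const})
    if not rows:
        return []
    pvals = np.array([r["p_value"] for r in rows])
    q = multipletests(pvals, method="fdr_bh")[1]
    out = [GeneAssociationRow(q_value=float(qi), **r)
           for r, qi in zip(rows, q)]
    return sorted(out, key=lambda r: (r.q_value, r.p_value, r.gene))


def association_table(rows: Sequence[GeneAssociationRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def active_gene_enrichment(
    fusion_genes: Sequence[str],
    reference_ranking: Sequence[str],
    top_n: int | Sequence[int] = (200, 500, 1000, 2000),
) -> pd.DataFrame:
    """Cumulative hypergeometric enrichment of fusion genes among the top-n
    most highly expressed genes of a reference ranking.

    p = P(X >= k) with X ~ Hypergeom(universe, top n, |fusion genes|) and
    k the observed overlap.  Fusion genes outside the ranking universe are
    excluded with a warning.
    """
    universe = list(dict.fromkeys(reference_ranking))
    uni_set = set(universe)
    genes = [g for g in dict.fromkeys(fusion_genes) if g in uni_set]
    dropped = len(set(fusion_genes)) - len(genes)
    if dropped:
        logger.warning("%d fusion genes outside ranking universe; excluded",
                       dropped)
    M, K = len(universe), len(genes)
    ns = [top_n] if isinstance(top_n, int) else list(top_n)
    rows = []
    for n in ns:
        if n > M:
            raise ValueError(f"top_n {n} exceeds universe size {M}")
        top = set(universe[:n])
        k = sum(g in top for g in genes)
        p = float(stats.hypergeom.sf(k - 1, M, n, K))  # P(X >= k)
        rows.append({"top_n": n, "overlap": k, "universe": M,
                     "n_fusion_genes": K, "p_value": p})
    return pd.DataFrame(rows)


def copy_number_association(
    calls: Sequence[FusionCall],
    copy_number: pd.DataFrame,
    config: BreakageNullConfig | None = None,
) -> dict[int, EnrichmentResult]:
    """Copy-number state usage of fused (gene, sample) pairs vs background.

    The observed statistic per state is the count of fused (gene, sample)
    pairs in that state; the null resamples equally many (gene, sample) pairs
    uniformly without replacement from the whole matrix, ``n_permutations``
    times.  Two-sided empirical p with add-one correction per state.
    """
    if config is None:
        config = BreakageNullConfig(n_permutations=1000)
    rng = np.random.default_rng(config.seed)
    genes = set(copy_number.index)
    samples = set(copy_number.columns)
    pairs = {(g, c.sample) for c in calls for g in (c.gene5, c.gene3)
             if g in genes and c.sample in samples}
    if not pairs:
        raise ValueError("no fused (gene, sample) pairs overlap the "
                         "copy-number matrix")
    cn = copy_number.to_numpy(int)
    gi = {g: i for i, g in enumerate(copy_number.index)}
    si = {s: i for i, s in enumerate(copy_number.columns)}
    fused_states = np.array([cn[gi[g], si[s]] for g, s in pairs])
    k = fused_states.size
    flat = cn.ravel()

    obs = {st: int(np.sum(fused_states == st)) for st in CN_STATES}
    null = np.zeros((config.n_permutations, len(CN_STATES)), dtype=np.int64)
    for b in range(config.n_permutations):
        draw = flat[rng.choice(flat.size, size=k, replace=False)]
        for j, st in enumerate(CN_STATES):
            null[b, j] = np.sum(draw == st)

    out: dict[int, EnrichmentResult] = {}
    for j, st in enumerate(CN_STATES):
        null_j = null[:, j]
        p_hi = _add_one_p(int(np.sum(null_j >= obs[st])), config.n_permutations)
        p_lo = _add_one_p(int(np.sum(null_j <= obs[st])), config.n_permutations)
        null_mean = float(null_j.mean())
        out[st] = EnrichmentResult(
            observed=float(obs[st]), null_mean=null_mean,
            fold_enrichment=obs[st] / null_mean if null_mean > 0 else
            float("inf"),
            p_value=min(1.0, 2 * min(p_hi, p_lo)),
            n_permutations=config.n_permutations, seed=config.seed,
            tail="two-sided")
    return out


# --------------------------------------------------------------------------- #
# Model / Results wrappers
# --------------------------------------------------------------------------- #

class FusionExpressionModel:
    """Fusion-status differential-expression screen over a cohort."""

    def __init__(self, expression: ExpressionMatrix | pd.DataFrame,
                 calls: Sequence[FusionCall]):
        self.expression = expression if isinstance(expression,
                                                   ExpressionMatrix) \
            else ExpressionMatrix(expression)
        self.calls = list(calls)

    def fit(self, min_positives: int = 3) -> "FusionExpressionResults":
        status = fusion_status_matrix(
            self.calls, list(self.expression.samples),
            list(self.expression.genes))
        rows = fusion_expression_test(self.expression, status, min_positives)
        return FusionExpressionResults(rows=rows, status=status,
                                       min_positives=min_positives)


@dataclass
class FusionExpressionResults:
    rows: list[GeneAssociationRow]
    status: pd.DataFrame
    min_positives: int

    def significant(self, q_threshold: float = 0.01
                    ) -> list[GeneAssociationRow]:
        return [r for r in self.rows if r.q_value < q_threshold]

    @property
    def table(self) -> pd.DataFrame:
        return association_table(self.rows)

    def summary(self, q_threshold: float = 0.01, top: int = 15) -> str:
        sig = self.significant(q_threshold)
        lines = [
            "Fusion-status differential expression",
            "=" * 52,
            f"genes tested (>= {self.min_positives} positives): "
            f"{len(self.rows)}",
            f"significant at q < {q_threshold:g}:         {len(sig)}",
            "-" * 52,
            f"{'gene':<14}{'n+':>4}{'fold':>9}{'q-value':>12}",
        ]
        for r in self.rows[:top]:
            lines.append(f"{r.gene:<14}{r.n_positive:>4}"
                         f"{r.fold_change:>9.2f}{r.q_value:>12.3g}")
        return "\n".join(lines)
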