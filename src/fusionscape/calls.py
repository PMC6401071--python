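"""Reading, filtering and summarizing defuse-style fusion-call tables.

Two filters reproduce the study design: a classifier-probability cutoff
(inclusive, default 0.81) and panel-of-normals subtraction, which removes any
tumor call whose unordered gene-symbol pair also occurs among calls predicted
in normal control samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GeneLocus, are_adjacent

logger = logging.getLogger(__name__)

#: default classifier-probability cutoff
DEFAULT_PROBABILITY_THRESHOLD = 0.81

#: canonical column names and accepted synonyms (defuse v0.6 dialect)
_COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "sample": ("sample", "sample_id", "library_name"),
    "gene5": ("gene5", "gene_name1"),
    "gene3": ("gene3", "gene_name2"),
    "transcript5": ("transcript5", "transcript1"),
    "transcript3": ("transcript3", "transcript2"),
    "chrom5": ("chrom5", "gene_chromosome1"),
    "chrom3": ("chrom3", "gene_chromosome2"),
    "pos5": ("pos5", "genomic_break_pos1"),
    "pos3": ("pos3", "genomic_break_pos2"),
    "strand5": ("strand5", "genomic_strand1"),
    "strand3": ("strand3", "genomic_strand2"),
    "probability": ("probability",),
    "cdna5": ("cdna5", "breakpoint_cdna_pos1"),
    "cdna3": ("cdna3", "breakpoint_cdna_pos2"),
    "adjacent": ("adjacent",),
    "read_through": ("read_through", "readthrough"),
    "interchromosomal": ("interchromosomal",),
}
_MANDATORY = ("sample", "gene5", "gene3", "chrom5", "chrom3",
              "pos5", "pos3", "strand5", "strand3", "probability")


@dataclass(frozen=True)
class FusionCall:
    """One predicted fusion transcript in one sample."""

    sample: str
    gene5: str
    gene3: str
    chrom5: str
    pos5: int
    strand5: str
    chrom3: str
    pos3: int
    strand3: str
    probability: float
    transcript5: str | None = None
    transcript3: str | None = None
    cdna5: int | None = None
    cdna3: int | None = None
    adjacent: bool | None = None
    read_through: bool | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability {self.probability} outside [0,1]")

    @property
    def interchromosomal(self) -> bool:
        return self.chrom5 != self.chrom3

    @property
    def gene_pair(self) -> frozenset[str]:
        """Unordered partner-gene pair, the panel-of-normals matching key."""
        return frozenset((self.gene5, self.gene3))

    @property
    def breakpoint_pair(self) -> frozenset[tuple[str, int]]:
        return frozenset(((self.chrom5, self.pos5), (self.chrom3, self.pos3)))


@dataclass(frozen=True)
class BurdenSummary:
    """Cohort-level per-sample fusion-count summary."""

    per_sample: Mapping[str, int]
    median: float
    q25: float
    q75: float
    min: int
    max: int

    @property
    def iqr(self) -> tuple[float, float]:
        return (self.q25, self.q75)


def read_defuse_table(path: str | Path) -> list[FusionCall]:
    """Parse a defuse-like TSV into FusionCall records.

    Rows that cannot be parsed (bad probability, non-integer coordinates) are
    rejected with a line-numbered warning; a missing mandatory column is a hard
    error naming the column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    colmap: dict[str, str] = {}
    for canon, synonyms in _COLUMN_SYNONYMS.items():
        for s in synonyms:
            if s in df.columns:
                colmap[canon] = s
                break
    for canon in _MANDATORY:
        if canon not in colmap:
            raise ValueError(f"{path}: missing mandatory column {canon!r}")

    def _opt_str(v) -> str | None:
        return None if v is None or (isinstance(v, float) and np.isnan(v)) \
            or str(v) in ("", "NA", "nan") else str(v)

    def _opt_int(v) -> int | None:
        s = _opt_str(v)
        return None if s is None else int(float(s))

    sub = pd.DataFrame({c: df[colmap[c]] for c in colmap})
    calls: list[FusionCall] = []
    for i, rec in enumerate(sub.to_dict("records"), start=2):
        try:
            call = FusionCall(
                sample=str(rec["sample"]),
                gene5=str(rec["gene5"]), gene3=str(rec["gene3"]),
                chrom5=str(rec["chrom5"]), pos5=int(rec["pos5"]),
                strand5=str(rec["strand5"]),
                chrom3=str(rec["chrom3"]), pos3=int(rec["pos3"]),
                strand3=str(rec["strand3"]),
                probability=float(rec["probability"]),
                transcript5=_opt_str(rec.get("transcript5")),
                transcript3=_opt_str(rec.get("transcript3")),
                cdna5=_opt_int(rec.get("cdna5")),
                cdna3=_opt_int(rec.get("cdna3")),
            )
        except (TypeError, ValueError) as exc:
            logger.warning("%s: line %d rejected: %s", path, i, exc)
            continue
        calls.append(call)
    return calls


def write_defuse_table(calls: Iterable[FusionCall], path: str | Path) -> None:
    cols = ["sample", "gene5", "gene3", "transcript5", "transcript3",
            "chrom5", "pos5", "strand5", "chrom3", "pos3", "strand3",
            "cdna5", "cdna3", "probability"]
    rows = [{c: getattr(k, c) for c in cols} for k in calls]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def filter_by_probability(
    calls: Sequence[FusionCall],
    threshold: float = DEFAULT_PROBABILITY_THRESHOLD,
) -> list[FusionCall]:
    """Retain calls with classifier probability >= threshold (inclusive)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside [0,1]")
    return [c for c in calls if c.probability >= threshold]


def subtract_panel_of_normals(
    calls: Sequence[FusionCall],
    normal_calls: Sequence[FusionCall],
    match: str = "pair",
) -> list[FusionCall]:
    """Remove tumor calls whose partner pair occurs in any normal sample.

    ``match='pair'`` (default) matches on the unordered gene-symbol pair;
    ``match='breakpoint'`` on the unordered genomic-breakpoint pair.
    """
    if match not in ("pair", "breakpoint"):
        raise ValueError(f"unknown match mode {match!r}")
    key = (lambda c: c.gene_pair) if match == "pair" \
        else (lambda c: c.breakpoint_pair)
    blacklist = {key(c) for c in normal_calls}
    return [c for c in calls if key(c) not in blacklist]


def burden_summary(calls: Sequence[FusionCall]) -> BurdenSummary:
    """Per-sample fusion counts with median and interquartile range."""
    if not calls:
        raise ValueError("burden_summary requires at least one call")
    counts = pd.Series([c.sample for c in calls]).value_counts().sort_index()
    arr = counts.to_numpy(float)
    q25, med, q75 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    return BurdenSummary(per_sample=counts.to_dict(), median=float(med),
                         q25=float(q25), q75=float(q75),
                         min=int(arr.min()), max=int(arr.max()))


def classify_rearrangements(
    calls: Sequence[FusionCall],
    loci: Mapping[str, GeneLocus],
) -> pd.DataFrame:
    """Fractions of chromosomal / adjacency / read-through classes.

    Read-through requires adjacency, equal gene strands and the 5' partner
    lying upstream of the 3' partner in transcription direction.  Calls whose
    partner genes cannot be resolved in the annotation count as ``unknown``.
    """
    n = len(calls)
    if n == 0:
        return pd.DataFrame(columns=["partition", "klass", "count", "fraction"])
    counters = {
        "chromosomal": {"intrachromosomal": 0, "interchromosomal": 0},
        "adjacency": {"adjacent": 0, "non_adjacent": 0, "unknown": 0},
        "read_through": {"read_through": 0, "other": 0, "unknown": 0},
    }
    for c in calls:
        counters["chromosomal"][
            "interchromosomal" if c.interchromosomal else "intrachromosomal"] += 1
        if c.gene5 not in loci or c.gene3 not in loci:
            counters["adjacency"]["unknown"] += 1
            counters["read_through"]["unknown"] += 1
            logger.warning("call %s-%s: partner gene not in annotation",
                           c.gene5, c.gene3)
            continue
        adj = are_adjacent(c.gene5, c.gene3, loci)
        counters["adjacency"]["adjacent" if adj else "non_adjacent"] += 1
        g5, g3 = loci[c.gene5], loci[c.gene3]
        rt = False
        if adj and g5.strand == g3.strand:
            if g5.strand == "+":
                rt = g5.start < g3.start
            else:
                rt = g5.start > g3.start
        counters["read_through"]["read_through" if rt else "other"] += 1
    rows = [
        {"partition": part, "klass": k, "count": v, "fraction": v / n}
        for part, d in counters.items() for k, v in d.items()
    ]
    return pd.DataFrame(rows)


def is_read_through(call: FusionCall, loci: Mapping[str, GeneLocus]) -> bool:
    """Read-through flag for a single call (adjacent, same strand, ordered)."""
    if call.gene5 not in loci or call.gene3 not in loci:
        raise KeyError("partner gene not in annotation")
    if not are_adjacent(call.gene5, call.gene3, loci):
        return False
    g5, g3 = loci[call.gene5], loci[call.gene3]
    if g5.strand != g3.strand:
        return False
    return g5.start < g3.start if g5.strand == "+" else g5.start > g3.start
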