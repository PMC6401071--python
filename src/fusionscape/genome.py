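"""Gene-annotation data structures and genomic <-> cDNA coordinate arithmetic.

Every breakpoint statistic downstream rests on three primitives defined here:

* mapping a genomic coordinate into transcript (cDNA) space, with intronic
  positions projected onto the donor-side exon junction (the last transcribed
  base before the intron) — this is what puts intron mass at the 5' end of
  cDNAs and drives the expected N-terminal breakpoint excess;
* classifying a cDNA position into 5'UTR / CDS / 3'UTR;
* the exact per-transcript distribution of cDNA positions induced by a
  breakpoint falling uniformly over the transcript's genomic span.

All internal coordinates are 0-based half-open; GTF's 1-based closed
coordinates are converted at the reader/writer boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: cDNA region labels, in transcript order.
REGIONS = ("UTR5", "CDS", "UTR3")


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True)
class ChromosomeTable:
    """Chromosome names and lengths: the genomic space of the breakage null."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise AnnotationError("names and lengths differ in length")
        if len(self.names) == 0:
            raise AnnotationError("chromosome table is empty")
        if len(set(self.names)) != len(self.names):
            raise AnnotationError("duplicate chromosome names")
        if any(l <= 0 for l in self.lengths):
            raise AnnotationError("chromosome lengths must be positive")

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def length_of(self, name: str) -> int:
        try:
            return self.lengths[self.names.index(name)]
        except ValueError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.names

    @classmethod
    def from_mapping(cls, sizes: Mapping[str, int]) -> "ChromosomeTable":
        return cls(tuple(sizes), tuple(int(v) for v in sizes.values()))

    @classmethod
    def from_file(cls, path: str | Path) -> "ChromosomeTable":
        """Read a UCSC chrom.sizes file (two-column TSV: name, length)."""
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                         names=["name", "length"], dtype={0: str})
        return cls(tuple(df["name"]), tuple(int(x) for x in df["length"]))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for n, l in zip(self.names, self.lengths):
                fh.write(f"{n}\t{l}\n")


class CdnaPosition(NamedTuple):
    """A cDNA coordinate plus whether it was projected from an intron."""

    position: int
    intron_derived: bool


@dataclass
class TranscriptModel:
    """Exon structure and CDS boundaries of one representative transcript.

    ``exons`` are 0-based half-open genomic intervals, non-overlapping and
    sorted by genomic coordinate.  ``cds_start``/``cds_end`` delimit the coding
    genomic span as a half-open interval; both must land on exonic bases
    (``cds_end`` may equal an exon end).  Non-coding transcripts carry
    ``cds_start is None``.
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    # derived, filled in __post_init__
    cdna_length: int = field(init=False, repr=False)
    utr5_length: int = field(init=False, repr=False)
    cds_length: int = field(init=False, repr=False)
    utr3_length: int = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: no exons")
        ex = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e) in ex:
            if e <= s:
                raise AnnotationError(f"{self.transcript_id}: empty exon [{s},{e})")
        for (_, e0), (s1, _) in zip(ex, ex[1:]):
            if s1 < e0:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
        self.exons = tuple(ex)
        self._starts = np.array([s for s, _ in ex])
        self._ends = np.array([e for _, e in ex])
        self._cum = np.concatenate([[0], np.cumsum(self._ends - self._starts)])
        self.cdna_length = int(self._cum[-1])
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(f"{self.transcript_id}: partial CDS bounds")
        if self.cds_start is not None:
            if not (self.span[0] <= self.cds_start < self.cds_end <= self.span[1]):
                raise AnnotationError(f"{self.transcript_id}: CDS outside span")
            b0 = self._exonic_bases_before(self.cds_start)
            b1 = self._exonic_bases_before(self.cds_end)
            self.cds_length = int(b1 - b0)
            if self.cds_length <= 0:
                raise AnnotationError(f"{self.transcript_id}: empty CDS")
            if self.strand == "+":
                self.utr5_length = int(b0)
            else:
                self.utr5_length = int(self.cdna_length - b1)
            self.utr3_length = self.cdna_length - self.utr5_length - self.cds_length
        else:
            self.cds_length = 0
            self.utr5_length = 0
            self.utr3_length = 0

    # ------------------------------------------------------------------ #

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span (first exon start, last exon end)."""
        return int(self._starts[0]), int(self._ends[-1])

    @property
    def span_length(self) -> int:
        s, e = self.span
        return e - s

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def _exonic_bases_before(self, g: int) -> int:
        """Number of exonic bases with genomic coordinate < g."""
        i = int(np.searchsorted(self._starts, g, side="right")) - 1
        if i < 0:
            return 0
        base = int(self._cum[i])
        return base + min(int(self._ends[i]), g) - int(self._starts[i]) \
            if g > self._starts[i] else base

    def _plus_offset(self, g: int) -> tuple[int, bool]:
        """Offset of g in plus-strand exonic order; intronic -> donor-side."""
        s, e = self.span
        if not (s <= g < e):
            raise ValueError(
                f"position {g} outside span [{s},{e}) of {self.transcript_id}")
        i = int(np.searchsorted(self._starts, g, side="right")) - 1
        if g < self._ends[i]:  # exonic
            return int(self._cum[i]) + g - int(self._starts[i]), False
        # intronic, between exon i and exon i+1
        if self.strand == "+":
            # donor side = last base of the left exon
            return int(self._cum[i + 1]) - 1, True
        # minus strand: donor exon is the genomic-right one; its last
        # transcribed base is its leftmost genomic base
        return int(self._cum[i + 1]), True


def genomic_to_cdna(transcript: TranscriptModel, position: int) -> CdnaPosition:
    """Map a genomic position within the transcript span to cDNA space.

    Exonic positions map exactly (strand-aware).  Intronic positions are
    projected onto the donor-side exon junction: the cDNA coordinate of the
    last transcribed base before the intron, flagged ``intron_derived``.
    """
    off, intronic = transcript._plus_offset(int(position))
    if transcript.strand == "+":
        return CdnaPosition(off, intronic)
    return CdnaPosition(transcript.cdna_length - 1 - off, intronic)


def cdna_to_genomic(transcript: TranscriptModel, position: int) -> int:
    """Inverse of :func:`genomic_to_cdna` for exonic cDNA positions."""
    if not (0 <= position < transcript.cdna_length):
        raise ValueError(f"cDNA position {position} out of range")
    off = position if transcript.strand == "+" \
        else transcript.cdna_length - 1 - position
    i = int(np.searchsorted(transcript._cum, off, side="right")) - 1
    return int(transcript._starts[i]) + off - int(transcript._cum[i])


def classify_cdna_region(transcript: TranscriptModel, position: int) -> str:
    """Classify a cDNA position as UTR5 / CDS / UTR3 (half-open boundaries)."""
    if not transcript.is_coding:
        raise ValueError(f"{transcript.transcript_id} is non-coding")
    if not (0 <= position < transcript.cdna_length):
        raise ValueError(f"cDNA position {position} out of range "
                         f"[0,{transcript.cdna_length})")
    if position < transcript.utr5_length:
        return "UTR5"
    if position < transcript.utr5_length + transcript.cds_length:
        return "CDS"
    return "UTR3"


def relative_cds_position(transcript: TranscriptModel, position: int) -> float:
    """Fractional position within the CDS: 0 = start codon side, ->1 = stop."""
    if classify_cdna_region(transcript, position) != "CDS":
        raise ValueError(f"cDNA position {position} is not in the CDS")
    return (position - transcript.utr5_length) / transcript.cds_length


@dataclass(frozen=True)
class GeneLocus:
    """One point-like handle per gene for adjacency and distance work."""

    symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    transcript_id: str

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def are_adjacent(gene_a: str, gene_b: str,
                 loci: Mapping[str, GeneLocus]) -> bool:
    """True iff both genes share a chromosome and no third gene's span lies
    strictly inside the gap between their spans."""
    try:
        a, b = loci[gene_a], loci[gene_b]
    except KeyError as exc:
        raise KeyError(f"unknown gene {exc.args[0]!r}") from None
    if a.chrom != b.chrom or a.symbol == b.symbol:
        return False
    gap_lo = min(a.end, b.end)
    gap_hi = max(a.start, b.start)
    if gap_lo >= gap_hi:  # overlapping or abutting spans
        return True
    for g in loci.values():
        if g.symbol in (a.symbol, b.symbol) or g.chrom != a.chrom:
            continue
        if g.start >= gap_lo and g.end <= gap_hi:
            return False
    return True


# --------------------------------------------------------------------------- #
# Per-transcript breakpoint-position law under uniform genomic breakage
# --------------------------------------------------------------------------- #

@dataclass
class BreakpointLaw:
    """Exact distribution of cDNA positions when a breakpoint falls uniformly
    over a transcript's genomic span.

    Exon bases map one-to-one; every base of an intron projects onto the
    donor-side junction, creating point masses (``atoms``).  All masses are
    integer base counts so the law matches per-base enumeration exactly.
    """

    transcript: TranscriptModel
    segments: list[tuple[int, int]]      # half-open cDNA intervals, mass = width
    atoms: list[tuple[int, int]]         # (cDNA position, intron length)

    @classmethod
    def of(cls, t: TranscriptModel) -> "BreakpointLaw":
        segments = []
        for i in range(len(t.exons)):
            lo = int(t._cum[i])
            hi = int(t._cum[i + 1])
            if t.strand == "+":
                segments.append((lo, hi))
            else:
                segments.append((t.cdna_length - hi, t.cdna_length - lo))
        atoms = []
        for i in range(len(t.exons) - 1):
            intron_len = int(t._starts[i + 1] - t._ends[i])
            if intron_len == 0:
                continue
            if t.strand == "+":
                pos = int(t._cum[i + 1]) - 1
            else:
                pos = t.cdna_length - 1 - int(t._cum[i + 1])
            atoms.append((pos, intron_len))
        return cls(t, segments, atoms)

    @property
    def total_mass(self) -> int:
        return self.transcript.span_length

    def region_counts(self) -> dict[str, int]:
        """Base counts of the span mapping into each cDNA region."""
        t = self.transcript
        if not t.is_coding:
            raise ValueError(f"{t.transcript_id} is non-coding")
        bounds = (0, t.utr5_length, t.utr5_length + t.cds_length, t.cdna_length)
        counts = dict.fromkeys(REGIONS, 0)
        for lo, hi in self.segments:
            for r, (b0, b1) in zip(REGIONS, zip(bounds, bounds[1:])):
                counts[r] += max(0, min(hi, b1) - max(lo, b0))
        for pos, mass in self.atoms:
            counts[classify_cdna_region(t, pos)] += mass
        return counts

    def region_probs(self) -> np.ndarray:
        c = self.region_counts()
        return np.array([c[r] for r in REGIONS], float) / self.total_mass

    def _masses(self, region: str | None) -> tuple[list, np.ndarray]:
        """Pieces (segments then atoms) with masses, optionally region-cut."""
        t = self.transcript
        if region is None:
            lo_b, hi_b = 0, t.cdna_length
        else:
            i = REGIONS.index(region)
            bounds = (0, t.utr5_length, t.utr5_length + t.cds_length,
                      t.cdna_length)
            lo_b, hi_b = bounds[i], bounds[i + 1]
        pieces, masses = [], []
        for lo, hi in self.segments:
            l, h = max(lo, lo_b), min(hi, hi_b)
            if h > l:
                pieces.append(("seg", l, h))
                masses.append(h - l)
        for pos, mass in self.atoms:
            if lo_b <= pos < hi_b:
                pieces.append(("atom", pos, pos + 1))
                masses.append(mass)
        return pieces, np.asarray(masses, float)

    def sample_cdna(self, rng: np.random.Generator, n: int,
                    region: str | None = None) -> np.ndarray:
        """Draw cDNA positions from the law, optionally conditioned on a region."""
        pieces, masses = self._masses(region)
        if not pieces:
            raise ValueError(
                f"{self.transcript.transcript_id}: no mass in region {region}")
        idx = rng.choice(len(pieces), size=n, p=masses / masses.sum())
        out = np.empty(n, dtype=int)
        for i, (kind, lo, hi) in enumerate(pieces):
            sel = idx == i
            if kind == "seg":
                out[sel] = rng.integers(lo, hi, size=int(sel.sum()))
            else:
                out[sel] = lo
        return out

    def sample_genomic(self, rng: np.random.Generator,
                       region: str | None = None) -> int:
        """Draw one genomic breakpoint whose cDNA projection obeys the law.

        Atom outcomes are realized as a uniform base inside the corresponding
        intron (every such base projects onto the same junction).
        """
        pieces, masses = self._masses(region)
        if not pieces:
            raise ValueError(
                f"{self.transcript.transcript_id}: no mass in region {region}")
        t = self.transcript
        k = int(rng.choice(len(pieces), p=masses / masses.sum()))
        kind, lo, hi = pieces[k]
        if kind == "seg":
            return cdna_to_genomic(t, int(rng.integers(lo, hi)))
        # locate the intron whose junction is this atom
        for i in range(len(t.exons) - 1):
            if t.strand == "+":
                pos = int(t._cum[i + 1]) - 1
            else:
                pos = t.cdna_length - 1 - int(t._cum[i + 1])
            if pos == lo:
                return int(rng.integers(t._ends[i], t._starts[i + 1]))
        raise RuntimeError("atom without matching intron")  # pragma: no cover


# --------------------------------------------------------------------------- #
# GTF I/O
# --------------------------------------------------------------------------- #

def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path,
              source: str = "fusionscape") -> None:
    """Write exon and CDS features (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (f'gene_id "{t.gene}"; gene_name "{t.gene}"; '
                     f'transcript_id "{t.transcript_id}";')
            for s, e in t.exons:
                fh.write(f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                         f"{t.strand}\t.\t{attrs}\n")
            if t.is_coding:
                for s, e in t.exons:
                    cs, ce = max(s, t.cds_start), min(e, t.cds_end)
                    if ce > cs:
                        fh.write(f"{t.chrom}\t{source}\tCDS\t{cs + 1}\t{ce}\t.\t"
                                 f"{t.strand}\t.\t{attrs}\n")


def _validate_gtf_lines(path: str | Path) -> None:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}: line {i}: expected 9 tab-separated fields, "
                    f"got {len(fields)}")
            try:
                int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationError(
                    f"{path}: line {i}: non-integer coordinates") from None


def load_annotation(
    gtf_path: str | Path,
    chrom_table: ChromosomeTable,
) -> tuple[dict[str, TranscriptModel], dict[str, GeneLocus]]:
    """Load a GTF into transcript models plus one representative locus per gene.

    The representative transcript per gene has the longest CDS (tie: longest
    cDNA, tie: lexicographically smallest transcript id).  Transcripts on
    chromosomes absent from ``chrom_table`` are dropped with a warning.
    """
    import gffutils

    _validate_gtf_lines(gtf_path)
    db = gffutils.create_db(str(gtf_path), ":memory:", force=True,
                            keep_order=False, disable_infer_genes=True,
                            disable_infer_transcripts=True,
                            merge_strategy="create_unique")

    def _attr(f, *names):
        for n in names:
            if n in f.attributes:
                return f.attributes[n][0]
        return None

    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for ftype, store in (("exon", exons), ("CDS", cds)):
        for f in db.features_of_type(ftype):
            tid = _attr(f, "transcript_id")
            if tid is None:
                raise AnnotationError(f"{ftype} feature without transcript_id "
                                      f"at {f.seqid}:{f.start}")
            store.setdefault(tid, []).append((f.start - 1, f.end))
            gene = _attr(f, "gene_name", "gene_id") or tid
            meta[tid] = (gene, f.seqid, f.strand)

    transcripts: dict[str, TranscriptModel] = {}
    for tid, (gene, chrom, strand) in meta.items():
        if chrom not in chrom_table:
            logger.warning("dropping %s: unknown chromosome %s", tid, chrom)
            continue
        if tid not in exons:
            logger.warning("dropping %s: CDS but no exons", tid)
            continue
        ex = sorted(exons[tid])
        if ex[-1][1] > chrom_table.length_of(chrom):
            logger.warning("dropping %s: exons exceed chromosome %s length",
                           tid, chrom)
            continue
        cds_start = cds_end = None
        if tid in cds:
            cds_start = min(s for s, _ in cds[tid])
            cds_end = max(e for _, e in cds[tid])
        try:
            transcripts[tid] = TranscriptModel(
                tid, gene, chrom, strand, tuple(ex), cds_start, cds_end)
        except AnnotationError as exc:
            logger.warning("dropping %s: %s", tid, exc)

    loci: dict[str, GeneLocus] = {}
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts.values():
        by_gene.setdefault(t.gene, []).append(t)
    representative: dict[str, TranscriptModel] = {}
    for gene, ts in by_gene.items():
        rep = sorted(ts, key=lambda t: (-t.cds_length, -t.cdna_length,
                                        t.transcript_id))[0]
        representative[rep.transcript_id] = rep
        loci[gene] = GeneLocus(gene, rep.chrom, rep.strand,
                               rep.span[0], rep.span[1], rep.transcript_id)
    return representative, loci


def loci_from_transcripts(
    transcripts: Mapping[str, TranscriptModel]) -> dict[str, GeneLocus]:
    """Build GeneLocus records from an in-memory representative-transcript set."""
    return {t.gene: GeneLocus(t.gene, t.chrom, t.strand, t.span[0], t.span[1],
                              t.transcript_id)
            for t in transcripts.values()}
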