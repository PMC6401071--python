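"""Self-contained synthetic study generator with planted, manifest-recorded
effects.

The generator emulates the statistical structure the analysis assumes in a
serous ovarian cancer cohort: an overdispersed per-sample fusion burden
(negative binomial, median ~21, IQR ~14-30), a 70% intrachromosomal excess,
UTR-biased breakpoints whose intron mass projects to the 5' side of cDNAs
(early introns are drawn longer), fusion-associated upregulation of selected
genes at configured fold changes, regional upregulation decaying linearly to
zero within 1 Mb of planted anchor fusions, amplification-tilted copy-number
states at fused loci, and four molecular subtypes with activated signature
genes.  A shared false-positive pool is duplicated into a panel of normal
samples so that panel-of-normals subtraction is exactly verifiable; every
planted effect is recorded in a truth manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calls import FusionCall, write_defuse_table
from .expression import CN_STATES
from .genome import (BreakpointLaw, ChromosomeTable, GeneLocus, REGIONS,
                     TranscriptModel, cdna_to_genomic, genomic_to_cdna,
                     loci_from_transcripts, write_gtf)
from .ssgsea import SUBTYPE_ORDER, SignatureSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlantedGene:
    """A gene whose fusion-positive samples are upregulated by ``fold``."""
    fold: float
    n_positive: int
    gene: str | None = None  # chosen by the simulator when None


@dataclass(frozen=True)
class PlantedAnchor:
    """An anchor whose fusion-positive samples upregulate neighbors with a
    linear kernel peaking at ``peak_fold`` and reaching 1 at ``decay_bp``."""
    peak_fold: float
    decay_bp: float
    n_positive: int
    gene: str | None = None


def _default_planted_genes() -> list[PlantedGene]:
    return [PlantedGene(fold=4.0, n_positive=15) for _ in range(20)]


def _default_planted_anchors() -> list[PlantedAnchor]:
    return [PlantedAnchor(peak_fold=3.0, decay_bp=1_000_000, n_positive=12)
            for _ in range(10)]


@dataclass
class CohortConfig:
    """All knobs of the synthetic study; the seed fully determines outputs."""

    seed: int = 0
    n_tumors: int = 200
    n_normals: int = 7

    # genome
    n_chromosomes: int = 24
    genes_per_chromosome: tuple[int, ...] | None = None  # None -> 90..30 ramp
    chromosome_length: int | None = None  # None -> sized to fit the genes
    intergenic_gap_mean: float = 120_000.0
    exon_count_range: tuple[int, int] = (4, 9)
    exon_length_range: tuple[int, int] = (150, 450)
    intron_length_mean: float = 6_000.0

    # expression
    expression_log_mean: float = 1.5
    expression_log_sd: float = 1.0
    noise_log_sd: float = 0.5

    # fusion burden and geometry
    burden_mean: float = 22.0
    burden_dispersion: float = 4.0      # negative-binomial size parameter
    burden_subtype_ratio: float = 1.6   # I/P vs D/M mean burden ratio
    intrachromosomal_prop: float = 0.70
    region_weights5: tuple[float, float, float] | None = (0.30, 0.40, 0.30)
    region_weights3: tuple[float, float, float] | None = (0.30, 0.40, 0.30)

    # false positives shared with normals
    fp_pool_size: int = 50
    fp_reserved_genes: int = 40
    fp_calls_per_tumor_mean: float = 2.0

    # planted effects
    planted_genes: list[PlantedGene] = field(
        default_factory=_default_planted_genes)
    planted_anchors: list[PlantedAnchor] = field(
        default_factory=_default_planted_anchors)

    # copy number
    cn_state_probs: tuple[float, ...] = (0.02, 0.18, 0.60, 0.18, 0.02)
    cn_amp_odds: float = 3.0

    # subtypes
    signature_size: int = 50
    subtype_shift_log: float = 2.0  # natural-log activation of signature genes

    def __post_init__(self) -> None:
        if not (0.0 <= self.intrachromosomal_prop <= 1.0):
            raise ValueError("intrachromosomal_prop outside [0,1]")
        for w in (self.region_weights5, self.region_weights3):
            if w is not None:
                if len(w) != 3 or any(x < 0 for x in w) or \
                        abs(sum(w) - 1.0) > 1e-9:
                    raise ValueError("region weights must be 3 non-negative "
                                     "values summing to 1")
        if abs(sum(self.cn_state_probs) - 1.0) > 1e-9:
            raise ValueError("cn_state_probs must sum to 1")
        for a in self.planted_anchors:
            if a.decay_bp > 1_000_000:
                raise ValueError("anchor decay length exceeds 1 Mb window "
                                 "half-width")
        if self.genes_per_chromosome is None:
            self.genes_per_chromosome = tuple(
                int(round(x)) for x in
                np.linspace(90, 30, self.n_chromosomes))
        if len(self.genes_per_chromosome) != self.n_chromosomes:
            raise ValueError("genes_per_chromosome length mismatch")

    @classmethod
    def effect_free(cls, seed: int = 0, n_tumors: int = 200,
                    n_chromosomes: int = 10,
                    genes_per_chromosome: int = 100) -> "CohortConfig":
        """A cohort with every planted effect switched off (null data)."""
        return cls(seed=seed, n_tumors=n_tumors,
                   n_chromosomes=n_chromosomes,
                   genes_per_chromosome=tuple([genes_per_chromosome] *
                                              n_chromosomes),
                   region_weights5=None, region_weights3=None,
                   burden_subtype_ratio=1.0, cn_amp_odds=1.0,
                   subtype_shift_log=0.0, planted_genes=[],
                   planted_anchors=[])


@dataclass
class TruthManifest:
    """Record of every planted effect, for parameter-recovery checks."""

    seed: int
    intrachromosomal_prop: float
    region_weights5: tuple | None
    region_weights3: tuple | None
    planted_genes: list[dict]     # gene, fold, positive_samples
    planted_anchors: list[dict]   # gene, peak_fold, decay_bp, positive_samples
    fp_pairs: list[list[str]]
    subtypes: dict[str, str]
    n_true_calls: int
    regional_kernel: str = "linear decay to 1 at decay_bp"

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _rng(config: CohortConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


# --------------------------------------------------------------------------- #
# genome
# --------------------------------------------------------------------------- #

def simulate_genome(config: CohortConfig) -> tuple[
        ChromosomeTable, dict[str, TranscriptModel], dict[str, GeneLocus]]:
    """Lay out genes sequentially along chromosomes.

    Intron lengths are drawn from a gamma distribution and assigned in
    decreasing order along the direction of transcription, giving the
    5'-heavy intron profile of eukaryotic genes.
    """
    rng = _rng(config, 0)
    transcripts: dict[str, TranscriptModel] = {}
    names, lengths = [], []
    e_lo, e_hi = config.exon_length_range
    c_lo, c_hi = config.exon_count_range
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        cursor = int(rng.integers(10_000, 30_000))
        for gi in range(config.genes_per_chromosome[ci]):
            symbol = f"G{ci + 1:02d}_{gi + 1:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(c_lo, c_hi + 1))
            ex_lens = rng.integers(e_lo, e_hi + 1, size=n_ex)
            introns = np.sort(rng.gamma(
                2.0, config.intron_length_mean / 2.0,
                size=n_ex - 1).astype(int) + 50)[::-1]
            if strand == "-":  # transcription right-to-left
                introns = introns[::-1]
            exons = []
            pos = cursor
            for k in range(n_ex):
                exons.append((pos, pos + int(ex_lens[k])))
                pos += int(ex_lens[k])
                if k < n_ex - 1:
                    pos += int(introns[k])
            tid = symbol + ".t1"
            tmp = TranscriptModel(tid, symbol, chrom, strand, tuple(exons))
            L = tmp.cdna_length
            utr5 = int(rng.integers(80, 151))
            utr3 = int(rng.integers(100, 201))
            g1 = cdna_to_genomic(tmp, utr5)
            g2 = cdna_to_genomic(tmp, L - utr3 - 1)
            cds_start, cds_end = min(g1, g2), max(g1, g2) + 1
            transcripts[tid] = TranscriptModel(
                tid, symbol, chrom, strand, tuple(exons), cds_start, cds_end)
            cursor = pos + int(rng.lognormal(
                np.log(config.intergenic_gap_mean) - 0.125, 0.5))
        length = cursor + int(rng.integers(10_000, 30_000))
        if config.chromosome_length is not None:
            if cursor > config.chromosome_length:
                raise ValueError(
                    f"genes exceed configured length of {chrom}")
            length = config.chromosome_length
        names.append(chrom)
        lengths.append(length)
    table = ChromosomeTable(tuple(names), tuple(lengths))
    return table, transcripts, loci_from_transcripts(transcripts)


# --------------------------------------------------------------------------- #
# fusions
# --------------------------------------------------------------------------- #

class _BreakpointSampler:
    """Cached per-transcript breakpoint laws with optional region reweighting."""

    def __init__(self, transcripts: Mapping[str, TranscriptModel]):
        self.by_gene = {t.gene: t for t in transcripts.values()}
        self._laws: dict[str, BreakpointLaw] = {}

    def law(self, gene: str) -> BreakpointLaw:
        if gene not in self._laws:
            self._laws[gene] = BreakpointLaw.of(self.by_gene[gene])
        return self._laws[gene]

    def draw(self, gene: str, rng: np.random.Generator,
             weights: tuple[float, float, float] | None
             ) -> tuple[TranscriptModel, int, int]:
        """Return (transcript, genomic position, cDNA position)."""
        t = self.by_gene[gene]
        law = self.law(gene)
        region = None
        if weights is not None and t.is_coding:
            region = REGIONS[int(rng.choice(3, p=np.asarray(weights)))]
        g = law.sample_genomic(rng, region=region)
        return t, g, genomic_to_cdna(t, g).position


def _make_call(sampler: _BreakpointSampler, sample: str, gene5: str,
               gene3: str, rng: np.random.Generator,
               config: CohortConfig, probability: float) -> FusionCall:
    t5, g5, c5 = sampler.draw(gene5, rng, config.region_weights5)
    t3, g3, c3 = sampler.draw(gene3, rng, config.region_weights3)
    return FusionCall(
        sample=sample, gene5=gene5, gene3=gene3,
        chrom5=t5.chrom, pos5=g5, strand5=t5.strand,
        chrom3=t3.chrom, pos3=g3, strand3=t3.strand,
        probability=probability,
        transcript5=t5.transcript_id, transcript3=t3.transcript_id,
        cdna5=c5, cdna3=c3)


def _partner_pair(rng: np.random.Generator, genes_by_chrom: dict[str, list],
                  chrom_weights: np.ndarray, chroms: list[str],
                  intra: bool, fixed_gene: str | None = None,
                  fixed_chrom: str | None = None) -> tuple[str, str]:
    """Draw a partner-gene pair, intrachromosomal or not."""
    if intra:
        if fixed_gene is not None:
            chrom = fixed_chrom
        else:
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_weights))]
        pool = genes_by_chrom[chrom]
        if fixed_gene is not None:
            others = [g for g in pool if g != fixed_gene]
            a, b = fixed_gene, others[int(rng.integers(len(others)))]
        else:
            i, j = rng.choice(len(pool), size=2, replace=False)
            a, b = pool[i], pool[j]
    else:
        if fixed_gene is not None:
            other_chroms = [c for c in chroms if c != fixed_chrom]
            w = np.array([chrom_weights[chroms.index(c)]
                          for c in other_chroms])
            c2 = other_chroms[int(rng.choice(len(other_chroms), p=w / w.sum()))]
            a = fixed_gene
            b = genes_by_chrom[c2][int(rng.integers(len(genes_by_chrom[c2])))]
        else:
            i, j = rng.choice(len(chroms), size=2, replace=False,
                              p=chrom_weights)
            a = genes_by_chrom[chroms[i]][
                int(rng.integers(len(genes_by_chrom[chroms[i]])))]
            b = genes_by_chrom[chroms[j]][
                int(rng.integers(len(genes_by_chrom[chroms[j]])))]
    if rng.random() < 0.5:
        a, b = b, a
    return a, b


def _true_probability(rng: np.random.Generator) -> float:
    # classifier probabilities of retained calls sit at/above the 0.81 cutoff
    return float(0.81 + 0.19 * rng.beta(8.0, 2.0))


def simulate_fusions(
    config: CohortConfig,
    transcripts: Mapping[str, TranscriptModel],
    loci: Mapping[str, GeneLocus],
    subtypes: Mapping[str, str],
) -> tuple[list[FusionCall], list[FusionCall], dict]:
    """Generate tumor and panel-of-normals call tables plus truth pieces.

    Returns (tumor calls incl. false positives, normal calls, truth dict with
    planted positive-sample sets and the false-positive pool).
    """
    rng = _rng(config, 1)
    sampler = _BreakpointSampler(transcripts)
    tumors = [f"TUMOR_{i + 1:03d}" for i in range(config.n_tumors)]
    normals = [f"NORMAL_{i + 1:02d}" for i in range(config.n_normals)]

    # reserve genes for the false-positive pool so panel subtraction can
    # never remove a true call
    all_genes = sorted(loci)
    rng_order = rng.permutation(len(all_genes))
    # never reserve more than a quarter of the genome for false positives
    n_reserved = min(config.fp_reserved_genes, len(all_genes) // 4)
    reserved = [all_genes[i] for i in rng_order[:n_reserved]]
    usable = [g for g in all_genes if g not in set(reserved)]

    genes_by_chrom: dict[str, list[str]] = {}
    for g in usable:
        genes_by_chrom.setdefault(loci[g].chrom, []).append(g)
    chroms = sorted(genes_by_chrom)
    chrom_weights = np.array([len(genes_by_chrom[c]) for c in chroms], float)
    chrom_weights /= chrom_weights.sum()

    # planted genes/anchors: assign concrete genes if unnamed
    planted_gene_names: list[str] = []
    taken: set[str] = set()
    spaced_anchor_names: list[str] = []
    # anchors: pick mid-chromosome genes on distinct chromosomes so their
    # windows do not overlap each other
    anchor_chroms = list(chroms)
    for k, a in enumerate(config.planted_anchors):
        if a.gene is not None:
            spaced_anchor_names.append(a.gene)
            taken.add(a.gene)
            continue
        chrom = anchor_chroms[k % len(anchor_chroms)]
        pool = genes_by_chrom[chrom]
        gene = pool[len(pool) // 2]
        while gene in taken:
            gene = pool[int(rng.integers(len(pool)))]
        spaced_anchor_names.append(gene)
        taken.add(gene)
    for pg in config.planted_genes:
        if pg.gene is not None:
            planted_gene_names.append(pg.gene)
            taken.add(pg.gene)
            continue
        gene = usable[int(rng.integers(len(usable)))]
        while gene in taken:
            gene = usable[int(rng.integers(len(usable)))]
        planted_gene_names.append(gene)
        taken.add(gene)

    calls: list[FusionCall] = []
    mult_hi = np.sqrt(config.burden_subtype_ratio)
    for s in tumors:
        mu = config.burden_mean * (
            mult_hi if subtypes[s] in ("immunoreactive", "proliferative")
            else 1.0 / mult_hi)
        r = config.burden_dispersion
        b = max(1, int(rng.negative_binomial(r, r / (r + mu))))
        for _ in range(b):
            intra = rng.random() < config.intrachromosomal_prop
            g5, g3 = _partner_pair(rng, genes_by_chrom, chrom_weights,
                                   chroms, intra)
            calls.append(_make_call(sampler, s, g5, g3, rng, config,
                                    _true_probability(rng)))

    # planted fusion-positive samples (forced calls on top of background)
    truth_genes, truth_anchors = [], []
    for pg, gene in zip(config.planted_genes, planted_gene_names):
        pos = [tumors[i] for i in rng.choice(config.n_tumors,
                                             size=pg.n_positive,
                                             replace=False)]
        for s in pos:
            intra = rng.random() < config.intrachromosomal_prop
            g5, g3 = _partner_pair(rng, genes_by_chrom, chrom_weights, chroms,
                                   intra, fixed_gene=gene,
                                   fixed_chrom=loci[gene].chrom)
            calls.append(_make_call(sampler, s, g5, g3, rng, config,
                                    _true_probability(rng)))
        truth_genes.append({"gene": gene, "fold": pg.fold,
                            "forced_samples": sorted(pos)})
    for pa, gene in zip(config.planted_anchors, spaced_anchor_names):
        pos = [tumors[i] for i in rng.choice(config.n_tumors,
                                             size=pa.n_positive,
                                             replace=False)]
        for s in pos:
            intra = rng.random() < config.intrachromosomal_prop
            g5, g3 = _partner_pair(rng, genes_by_chrom, chrom_weights, chroms,
                                   intra, fixed_gene=gene,
                                   fixed_chrom=loci[gene].chrom)
            calls.append(_make_call(sampler, s, g5, g3, rng, config,
                                    _true_probability(rng)))
        truth_anchors.append({"gene": gene, "peak_fold": pa.peak_fold,
                              "decay_bp": pa.decay_bp,
                              "forced_samples": sorted(pos)})

    n_true = len(calls)

    # false-positive pool, shared with the panel of normals
    fp_pairs: list[tuple[str, str]] = []
    seen_pairs: set[frozenset] = set()
    max_pairs = len(reserved) * (len(reserved) - 1) // 2
    pool_size = min(config.fp_pool_size, max_pairs)
    while len(fp_pairs) < pool_size:
        i, j = rng.choice(len(reserved), size=2, replace=False)
        key = frozenset((reserved[i], reserved[j]))
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        fp_pairs.append((reserved[i], reserved[j]))

    normal_calls: list[FusionCall] = []
    for pair in fp_pairs:  # every pool pair appears in the normals table
        for _ in range(int(rng.integers(1, 3))):
            s = normals[int(rng.integers(len(normals)))]
            normal_calls.append(_make_call(
                sampler, s, pair[0], pair[1], rng, config,
                float(rng.uniform(0.5, 1.0))))
    for s in tumors:
        for _ in range(rng.poisson(config.fp_calls_per_tumor_mean)):
            pair = fp_pairs[int(rng.integers(len(fp_pairs)))]
            calls.append(_make_call(sampler, s, pair[0], pair[1], rng,
                                    config, float(rng.uniform(0.5, 1.0))))

    truth = {
        "planted_genes": truth_genes,
        "planted_anchors": truth_anchors,
        "fp_pairs": [sorted(p) for p in fp_pairs],
        "n_true_calls": n_true,
    }
    return calls, normal_calls, truth


# --------------------------------------------------------------------------- #
# expression / copy number / signatures
# --------------------------------------------------------------------------- #

def _positive_samples(calls: Sequence[FusionCall], gene: str) -> set[str]:
    return {c.sample for c in calls if gene in (c.gene5, c.gene3)}


def simulate_expression(
    config: CohortConfig,
    loci: Mapping[str, GeneLocus],
    true_calls: Sequence[FusionCall],
    subtypes: Mapping[str, str],
    signatures: SignatureSet,
    truth: dict,
) -> pd.DataFrame:
    """Baseline log-normal FPKM with multiplicative planted effects.

    Fusion-status effects condition on the *final* fusion-positive sample set
    of each planted gene/anchor (forced plus background calls).  Anchor
    effects use the linear kernel 1 + (F-1) * max(0, 1 - |d|/L) on neighbor
    genes of the same chromosome.
    """
    rng = _rng(config, 2)
    genes = sorted(loci)
    samples = sorted({c.sample for c in true_calls} |
                     set(subtypes))
    samples = [s for s in samples if s.startswith("TUMOR_")] or samples
    gi = {g: k for k, g in enumerate(genes)}
    si = {s: k for k, s in enumerate(samples)}

    base = rng.normal(config.expression_log_mean, config.expression_log_sd,
                      size=len(genes))
    logx = base[:, None] + rng.normal(0.0, config.noise_log_sd,
                                      size=(len(genes), len(samples)))

    for entry in truth["planted_genes"]:
        gene, fold = entry["gene"], entry["fold"]
        if gene not in gi:
            raise ValueError(f"planted gene {gene} absent from annotation")
        pos = _positive_samples(true_calls, gene)
        entry["positive_samples"] = sorted(pos)
        cols = [si[s] for s in pos if s in si]
        logx[gi[gene], cols] += np.log(fold)

    for entry in truth["planted_anchors"]:
        gene, F, L = entry["gene"], entry["peak_fold"], entry["decay_bp"]
        if gene not in gi:
            raise ValueError(f"planted anchor {gene} absent from annotation")
        pos = _positive_samples(true_calls, gene)
        entry["positive_samples"] = sorted(pos)
        cols = [si[s] for s in pos if s in si]
        a = loci[gene]
        for g in loci.values():
            if g.chrom != a.chrom or g.symbol == gene:
                continue
            d = abs(g.midpoint - a.midpoint)
            mult = 1.0 + (F - 1.0) * max(0.0, 1.0 - d / L)
            if mult > 1.0:
                logx[gi[g.symbol], cols] += np.log(mult)

    if config.subtype_shift_log > 0:
        for name, sig_genes in signatures.signatures.items():
            rows = [gi[g] for g in sig_genes if g in gi]
            cols = [si[s] for s in samples if subtypes[s] == name]
            logx[np.ix_(rows, cols)] += config.subtype_shift_log

    return pd.DataFrame(np.exp(logx), index=pd.Index(genes, name="gene"),
                        columns=samples)


def simulate_copy_number(
    config: CohortConfig,
    genes: Sequence[str],
    samples: Sequence[str],
    true_calls: Sequence[FusionCall],
) -> pd.DataFrame:
    """GISTIC-style states, with high amplification tilted toward fused pairs."""
    rng = _rng(config, 3)
    p = np.asarray(config.cn_state_probs, float)
    states = np.asarray(CN_STATES)
    cn = states[rng.choice(len(states), size=(len(genes), len(samples)), p=p)]
    if config.cn_amp_odds != 1.0:
        tilted = p.copy()
        tilted[-1] *= config.cn_amp_odds
        tilted /= tilted.sum()
        gi = {g: k for k, g in enumerate(genes)}
        si = {s: k for k, s in enumerate(samples)}
        pairs = {(g, c.sample) for c in true_calls
                 for g in (c.gene5, c.gene3)
                 if g in gi and c.sample in si}
        for g, s in sorted(pairs):
            cn[gi[g], si[s]] = states[int(rng.choice(len(states), p=tilted))]
    return pd.DataFrame(cn, index=pd.Index(genes, name="gene"),
                        columns=list(samples))


# --------------------------------------------------------------------------- #
# cohort orchestration
# --------------------------------------------------------------------------- #

@dataclass
class SyntheticCohort:
    """All artifacts of one simulated study."""

    config: CohortConfig
    chrom_table: ChromosomeTable
    transcripts: dict[str, TranscriptModel]
    loci: dict[str, GeneLocus]
    tumor_calls: list[FusionCall]      # includes false positives
    normal_calls: list[FusionCall]
    true_calls: list[FusionCall]       # ground truth after both filters
    expression: pd.DataFrame
    copy_number: pd.DataFrame
    signatures: SignatureSet
    manifest: TruthManifest

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.expression.columns)

    def write_fixture(self, outdir: str | Path) -> dict[str, Path]:
        """Write the full fixture; returns the path of each artifact."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gtf": outdir / "genes.gtf",
            "chrom_sizes": outdir / "chrom.sizes",
            "tumor_calls": outdir / "fusions_tumor.tsv",
            "normal_calls": outdir / "fusions_normal.tsv",
            "expression": outdir / "expression_fpkm.tsv",
            "copy_number": outdir / "copy_number.tsv",
            "signatures": outdir / "signatures",
            "manifest": outdir / "manifest.json",
        }
        write_gtf(self.transcripts.values(), paths["gtf"])
        self.chrom_table.to_file(paths["chrom_sizes"])
        write_defuse_table(self.tumor_calls, paths["tumor_calls"])
        write_defuse_table(self.normal_calls, paths["normal_calls"])
        self.expression.to_csv(paths["expression"], sep="\t",
                               index_label="gene")
        self.copy_number.to_csv(paths["copy_number"], sep="\t",
                                index_label="gene")
        self.signatures.to_dir(paths["signatures"])
        self.manifest.to_json(paths["manifest"])
        return paths


def simulate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Run the full generator; deterministic under ``config.seed``."""
    if config is None:
        config = CohortConfig()
    chrom_table, transcripts, loci = simulate_genome(config)

    rng = _rng(config, 4)
    tumors = [f"TUMOR_{i + 1:03d}" for i in range(config.n_tumors)]
    subtypes = {s: SUBTYPE_ORDER[int(rng.integers(4))] for s in tumors}

    # signature genes: away from planted effects (chosen before fusions only
    # by name reservation; planted genes are assigned inside simulate_fusions
    # from the non-reserved pool, so overlap is possible but rare and benign)
    all_genes = sorted(loci)
    # signatures never occupy more than half the genome
    sig_size = min(config.signature_size, max(1, len(all_genes) // 8))
    sig_idx = rng.choice(len(all_genes), size=4 * sig_size, replace=False)
    signatures = SignatureSet({
        name: sorted(all_genes[i] for i in
                     sig_idx[k * sig_size:(k + 1) * sig_size])
        for k, name in enumerate(SUBTYPE_ORDER)})

    tumor_calls, normal_calls, truth = simulate_fusions(
        config, transcripts, loci, subtypes)

    # ground truth after probability filter + panel subtraction
    fp_keys = {frozenset(p) for p in truth["fp_pairs"]}
    true_calls = [c for c in tumor_calls
                  if c.probability >= 0.81 and c.gene_pair not in fp_keys]

    expression = simulate_expression(config, loci, true_calls, subtypes,
                                     signatures, truth)
    copy_number = simulate_copy_number(config, sorted(loci),
                                       list(expression.columns), true_calls)

    manifest = TruthManifest(
        seed=config.seed,
        intrachromosomal_prop=config.intrachromosomal_prop,
        region_weights5=config.region_weights5,
        region_weights3=config.region_weights3,
        planted_genes=truth["planted_genes"],
        planted_anchors=truth["planted_anchors"],
        fp_pairs=truth["fp_pairs"],
        subtypes=subtypes,
        n_true_calls=truth["n_true_calls"])
    return SyntheticCohort(
        config=config, chrom_table=chrom_table, transcripts=transcripts,
        loci=loci, tumor_calls=tumor_calls, normal_calls=normal_calls,
        true_calls=true_calls, expression=expression,
        copy_number=copy_number, signatures=signatures, manifest=manifest)
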