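"""End-to-end pipeline: validated config, stage orchestration, reports.

Stages run in a fixed order (optional simulate -> filter -> breakage-null ->
expression association -> regional scan -> subtyping); each writes its own
TSV/JSON artifacts and the run ends with a summary JSON recording seeds,
counts and every headline statistic.  A single global seed is fanned out to
stages through a counter-based derivation so any stage can be re-run
reproducibly in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .breakage import BreakageNullConfig, BreakageNullModel
from .calls import (burden_summary, classify_rearrangements,
                    filter_by_probability, read_defuse_table,
                    subtract_panel_of_normals, write_defuse_table)
from .expression import (ExpressionMatrix, FusionExpressionModel,
                         copy_number_association)
from .genome import ChromosomeTable, load_annotation
from .regional import RegionalScanModel, chromosome_fusion_ratio
from .ssgsea import SignatureSet, SubtypeModel

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "calls", "normals", "gtf", "chrom_sizes", "expression", "copy_number",
    "signatures", "outdir", "probability_threshold", "min_positives",
    "window", "q_threshold", "n_permutations", "n_randomizations",
    "ssgsea_permutations", "seed", "simulate",
}


@dataclass
class PipelineConfig:
    """Paths, thresholds, permutation counts and the global seed."""

    calls: Path
    gtf: Path
    chrom_sizes: Path
    expression: Path
    outdir: Path
    normals: Path | None = None
    copy_number: Path | None = None
    signatures: Path | None = None
    probability_threshold: float = 0.81
    min_positives: int = 3
    window: float = 1_000_000.0
    q_threshold: float = 0.05
    n_permutations: int = 100_000
    n_randomizations: int = 200
    ssgsea_permutations: int = 1000
    seed: int = 17
    simulate: bool = False

    def __post_init__(self) -> None:
        for name in ("calls", "gtf", "chrom_sizes", "expression", "outdir",
                     "normals", "copy_number", "signatures"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, Path(v))
        if not (0.0 <= self.probability_threshold <= 1.0):
            raise ValueError("probability_threshold outside [0,1]")
        if self.min_positives < 2:
            raise ValueError("min_positives must be >= 2")
        if not self.simulate:
            for name in ("calls", "gtf", "chrom_sizes", "expression",
                         "normals", "copy_number", "signatures"):
                v = getattr(self, name)
                if v is not None and not Path(v).exists():
                    raise FileNotFoundError(f"{name}: {v} does not exist")

    def stage_seed(self, stage: int) -> int:
        """Counter-based per-stage seed derivation (independent rerun-able)."""
        return int(np.random.SeedSequence([self.seed, stage])
                   .generate_state(1)[0] % (2 ** 31))


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise ValueError(f"{path}: empty or non-mapping config")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    for key, value in raw.items():
        f = fields[key]
        if f.type in ("float", "float | None") and isinstance(value, bool):
            raise TypeError(f"{path}: key {key!r} has wrong type")
        if key in ("probability_threshold", "window", "q_threshold") and \
                not isinstance(value, (int, float)):
            raise TypeError(f"{path}: key {key!r} must be numeric")
        if key in ("min_positives", "n_permutations", "n_randomizations",
                   "ssgsea_permutations", "seed") and \
                not isinstance(value, int):
            raise TypeError(f"{path}: key {key!r} must be an integer")
    missing = {"calls", "gtf", "chrom_sizes", "expression"} - set(raw)
    if missing and not raw.get("simulate"):
        raise ValueError(f"{path}: missing required keys: {sorted(missing)}")
    return PipelineConfig(**raw)


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the summary report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.seed,
                     "stages": {}}

    stage = "simulate"
    if config.simulate:
        from .simulate import CohortConfig, simulate_cohort
        cohort = simulate_cohort(CohortConfig(seed=config.stage_seed(0)))
        paths = cohort.write_fixture(out / "fixture")
        config = dataclasses.replace(
            config, simulate=False, calls=paths["tumor_calls"],
            normals=paths["normal_calls"], gtf=paths["gtf"],
            chrom_sizes=paths["chrom_sizes"], expression=paths["expression"],
            copy_number=paths["copy_number"], signatures=paths["signatures"])
        summary["stages"][stage] = {"n_tumor_calls": len(cohort.tumor_calls),
                                    "fixture": str(out / "fixture")}

    try:
        stage = "filter"
        calls = read_defuse_table(config.calls)
        filtered = filter_by_probability(calls, config.probability_threshold)
        if config.normals is not None:
            normals = read_defuse_table(config.normals)
            filtered = subtract_panel_of_normals(filtered, normals)
        write_defuse_table(filtered, out / "filtered_calls.tsv")
        chrom_table = ChromosomeTable.from_file(config.chrom_sizes)
        transcripts, loci = load_annotation(config.gtf, chrom_table)
        burden = burden_summary(filtered)
        classes = classify_rearrangements(filtered, loci)
        classes.to_csv(out / "rearrangement_classes.tsv", sep="\t",
                       index=False)
        summary["stages"][stage] = {
            "n_raw": len(calls), "n_filtered": len(filtered),
            "burden_median": burden.median, "burden_iqr": burden.iqr,
        }

        stage = "breakage-null"
        bn = BreakageNullModel(filtered, chrom_table, transcripts).fit(
            n_permutations=config.n_permutations,
            seed=config.stage_seed(1))
        (out / "breakage_null.json").write_text(
            json.dumps(bn.to_dict(), indent=1, default=float))
        summary["stages"][stage] = {
            "intrachromosomal_fold": bn.intrachromosomal.fold_enrichment,
            "intrachromosomal_p": bn.intrachromosomal.p_value,
        }

        stage = "expr-assoc"
        expr = ExpressionMatrix.from_tsv(config.expression)
        fe = FusionExpressionModel(expr, filtered).fit(config.min_positives)
        fe.table.to_csv(out / "fusion_expression.tsv", sep="\t", index=False)
        summary["stages"][stage] = {
            "n_tested": len(fe.rows),
            "n_significant_q01": len(fe.significant(0.01)),
        }
        if config.copy_number is not None:
            import pandas as pd
            cn = pd.read_csv(config.copy_number, sep="\t", index_col=0)
            cn_res = copy_number_association(
                filtered, cn,
                BreakageNullConfig(n_permutations=1000,
                                   seed=config.stage_seed(2)))
            (out / "copy_number_association.json").write_text(
                json.dumps({str(k): dataclasses.asdict(v)
                            for k, v in cn_res.items()}, indent=1))

        stage = "regional"
        rs = RegionalScanModel(expr, filtered, loci).fit(
            half_width=config.window, min_positives=config.min_positives,
            n_randomizations=config.n_randomizations,
            seed=config.stage_seed(3), q_threshold=config.q_threshold)
        rs.pairs.to_csv(out / "regional_pairs.tsv", sep="\t", index=False)
        import pandas as pd
        pd.DataFrame({
            "distance": rs.profile.grid,
            "observed_log2_fold": rs.profile.observed_curve,
            "null_lo": rs.profile.envelope_lo,
            "null_hi": rs.profile.envelope_hi,
        }).to_csv(out / "regional_profile.tsv", sep="\t", index=False)
        rs.called.to_csv(out / "dysregulated_genes.tsv", sep="\t",
                         index=False)
        chromosome_fusion_ratio(filtered, chrom_table).to_csv(
            out / "chromosome_fusion_ratio.tsv", sep="\t", index=False)
        summary["stages"][stage] = {
            "n_pairs": len(rs.pairs),
            "n_dysregulated_genes": rs.n_dysregulated_genes,
            "n_anchor_genes": rs.n_anchor_genes,
        }

        stage = "subtype"
        if config.signatures is not None:
            sigs = SignatureSet.from_dir(config.signatures)
            st = SubtypeModel(expr, sigs).fit(
                n_permutations=config.ssgsea_permutations,
                seed=config.stage_seed(4))
            st.scores.to_frame().to_csv(out / "subtypes.tsv", sep="\t",
                                        index_label="sample")
            burden_by_sample = {s: 0 for s in expr.samples}
            for c in filtered:
                if c.sample in burden_by_sample:
                    burden_by_sample[c.sample] += 1
            fisher = st.burden_enrichment(burden_by_sample)
            summary["stages"][stage] = {
                "assignments": st.assignment.value_counts().to_dict(),
                "burden_fisher_p": fisher["p_value"],
                "burden_odds_ratio": fisher["odds_ratio"],
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 default=float))
    return summary
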