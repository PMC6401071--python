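# fusionscape

Statistical analysis of expressed gene-fusion transcripts in tumor
transcriptomes, built for cohorts of RNA-seq samples (e.g. high-grade serous
ovarian cancer) where chimeric transcripts serve as read-outs of underlying
genomic rearrangement.  The package answers four questions from fusion calls,
an expression matrix and a gene annotation alone:

1. **Is the geometry of the fusions non-random?**  Fusion formation is
   modeled as a stochastic breakage-and-rejoin process with a uniform
   breakage rate over the genome.  Under this null the expected
   same-chromosome fraction of random breakpoint pairs is the closed form

   *q* = Σᵢ Lᵢ² / (Σᵢ Lᵢ)²

   over chromosome lengths Lᵢ (≈ 0.0497 for hg19).  Observed
   intrachromosomal fractions are tested against permutation redraws, and
   the fold enrichment is observed/*q*.

2. **Where do breakpoints fall within transcripts?**  Genomic breakpoints
   are mapped into cDNA coordinates (intronic breakpoints project onto the
   donor-side exon junction, which pushes intron mass toward the 5′ end of
   the transcript), classified into 5′UTR / CDS / 3′UTR, and compared
   against the exact per-transcript distribution implied by uniform breakage
   over the transcript span — via per-region permutation tests and a
   two-sample Kolmogorov–Smirnov test on relative CDS position.

3. **Is fusion status associated with expression?**  Per gene, FPKM of
   fusion-positive vs fusion-negative samples is compared with a two-sided
   Wilcoxon rank-sum test (exact for small tie-free groups), fold change is
   the ratio of group means with a 0.01 pseudocount, and q-values are
   Benjamini–Hochberg.  Around each fused "anchor" gene, neighbors within
   ±1 Mb are scanned for fusion-status fold changes; the aggregate
   loess-smoothed profile of log₂ fold vs signed distance is judged against
   a label-randomization null envelope, and per-pair calls use a studentized
   pooled permutation null.

4. **Which molecular subtype is each sample?**  A reimplemented
   single-sample GSEA: a rank-weighted running-sum score per signature,
   normalized by the mean |score| of 1,000 size-matched random gene sets,
   with argmax assignment over the four ovarian subtypes (differentiated,
   immunoreactive, mesenchymal, proliferative) and a Fisher exact test of
   subtype enrichment in the top fusion-burden decile.

Standard inputs are consumed: defuse-style call tables (TSV), GTF
annotation, UCSC `chrom.sizes`, genes × samples FPKM TSV, GISTIC-style
copy-number states, and one-symbol-per-line signature files.  Calls are
filtered by classifier probability (≥ 0.81) and by panel-of-normals
subtraction on unordered gene pairs.

A fully self-contained synthetic cohort generator (`fusionscape.simulate`)
produces genome, annotation, calls, panel of normals, expression,
copy-number and signatures with planted, manifest-recorded effects, so every
statistical claim of the pipeline can be verified by parameter recovery.

## Worked example

```python
from fusionscape.simulate import CohortConfig, simulate_cohort
from fusionscape.calls import (filter_by_probability,
                               subtract_panel_of_normals, burden_summary)
from fusionscape.breakage import BreakageNullModel
from fusionscape.expression import FusionExpressionModel

cohort = simulate_cohort(CohortConfig(seed=1))   # 200 tumors, 24 chromosomes
calls = subtract_panel_of_normals(
    filter_by_probability(cohort.tumor_calls), cohort.normal_calls)
b = burden_summary(calls)
print(f"{len(calls)} calls retained; median burden {b.median:.0f} "
      f"(IQR {b.q25:.0f}-{b.q75:.0f})")

res = BreakageNullModel(calls, cohort.chrom_table, cohort.transcripts).fit(
    n_permutations=100_000, seed=17)
print(res.summary())

fe = FusionExpressionModel(cohort.expression, calls).fit()
print(fe.summary(top=5))
```

prints

```
4838 calls retained; median burden 21 (IQR 15-32)
Breakage-and-rejoin null model
==============================================
calls analysed:                 4838
observed intrachromosomal:      0.705
expected under uniform null:    0.0452
fold enrichment:                15.60
permutation p (n=100000):   1e-05
----------------------------------------------
region      observed  null mean  fold     p
UTR5           2928       38.5  76.00  2e-05
CDS            3793     9564.3   0.40  2e-05
UTR3           2955       73.2  40.37  2e-05
----------------------------------------------
CDS C-terminal KS: D=0.031 p=0.291 (n=1120)
Fusion-status differential expression
====================================================
genes tested (>= 3 positives): 1355
significant at q < 0.01:         20
----------------------------------------------------
gene            n+     fold     q-value
G08_058         24     4.40    5.56e-12
G10_061         24     3.71    1.19e-11
G14_045         23     4.21    5.24e-11
G16_024         25     3.77    5.24e-11
G01_078         22     4.01    5.24e-11
```

The generator planted fusions in 70% intrachromosomal pairs on a
24-chromosome genome (closed-form expectation 0.0452, hence the ~15.6-fold
excess), drew breakpoints with UTR-biased region weights (hence UTR
enrichment and CDS depletion against the span-uniform null), and upregulated
20 genes four-fold in their fusion-positive samples — exactly the 20 genes
recovered at q < 0.01.

The same stages are available from the shell:

```bash
fusionscape simulate --seed 1 --out fixture/
fusionscape filter --calls fixture/fusions_tumor.tsv \
    --normals fixture/fusions_normal.tsv --min-prob 0.81 --out filtered.tsv
fusionscape breakage-null --calls filtered.tsv --gtf fixture/genes.gtf \
    --chrom-sizes fixture/chrom.sizes --n-perm 100000 --seed 17 --out bn.json
fusionscape all --config pipeline.yaml       # every stage from one config
```

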