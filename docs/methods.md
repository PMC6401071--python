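# Methods

## The breakage-and-rejoin null

Fusion formation is modeled as two independent breakpoints drawn uniformly
over the concatenated genome, then rejoined.  The same-chromosome probability
is q = Σ Lᵢ²/(Σ Lᵢ)²; for the embedded hg19 table (chr1–22, X, Y) q =
0.0497, so an observed intrachromosomal fraction of 70.8% corresponds to a
14-fold excess.  `intrachromosomal_enrichment` permutes |calls| pairs per
permutation; because pairs are i.i.d., the per-permutation same-chromosome
count is drawn as Binomial(|calls|, q), which is distributionally identical
to drawing the pairs explicitly and allows 10⁵ permutations in milliseconds.
Empirical p-values throughout the package carry the add-one correction
p = (1 + #{null ≥ obs})/(n + 1) and therefore respect the 1/(n+1) floor.

## Breakpoint position within transcripts

All internal coordinates are 0-based half-open; GTF's 1-based closed
coordinates are converted at the reader boundary.  One representative
transcript per gene is kept (longest CDS, then longest cDNA, then smallest
transcript id) — an explicit convention, since isoform handling is otherwise
underdetermined.  Non-coding transcripts participate in adjacency and
regional analyses but are excluded from region/CDS statistics.

Intronic breakpoints map to the donor-side exon junction: the cDNA position
of the last transcribed base before the intron.  Because early introns in
eukaryotic genes are long, intron mass concentrates at 5′-proximal junctions,
which is what creates the elevated *expected* N-terminal breakpoint density.
The per-transcript law of a uniform breakpoint over the genomic span is
computed exactly in integer base counts (exon segments are uniform stretches
of cDNA; each intron is a point mass at its donor junction), so
`expected_region_distribution` equals exhaustive per-base enumeration, which
the tests exploit as an oracle.

The region permutation test conditions on the observed transcripts: each
breakpoint is redrawn within its own transcript's span, isolating positional
bias from gene-selection bias.  Redraws are realized as one multinomial per
distinct transcript per permutation.  Reported region p-values are two-sided
(2·min(upper, lower tail), capped at 1), so depletion of coding regions and
enrichment of UTRs are both detectable.  The CDS positional test is a
two-sample KS between observed relative CDS positions and a ≥10× sample from
the conditional expected law, reported overall and separately for the
N-terminal ([0, 0.5)) and C-terminal ([0.5, 1)) halves; cohort-profile
comparisons are chi-square homogeneity tests (k-sample on the full
region × cohort table, 2×2 with continuity correction for one region vs
rest).

## Fusion-status differential expression

Fold change is (mean FPKM in positives + ε)/(mean FPKM in negatives + ε)
with ε = 0.01 — the estimator and pseudocount are package conventions, since
unlogged fold changes do not pin either down.  The rank-sum p is exact when
both groups have ≤ 25 tie-free values, otherwise the normal approximation
with tie correction; a constant gene is reported with p = 1 and flagged.
Genes with fewer than 3 fusion-positive samples are skipped and excluded
from the Benjamini–Hochberg burden (2 positives produce degenerate rank
tests).  The test is two-sided throughout: downregulation is never
suppressed, only (not) observed.

Active-gene enrichment is the cumulative hypergeometric P(X ≥ k) of the
overlap between fusion genes and the top-n of a supplied expression ranking,
swept over n ∈ {200, 500, 1000, 2000} by default.  Copy-number association
compares the GISTIC-state distribution of fused (gene, sample) pairs with
equally sized uniform resamples of the matrix, two-sided per state.

## Regional dysregulation scan

Every gene involved in a retained fusion is an anchor; neighbors are genes
whose span midpoint lies within ±1 Mb on the same chromosome (midpoint
distance is symmetric under strand and requires no TSS convention).  The
aggregate profile is a loess fit (locally linear, tricube weights, span 0.3
— chosen to resolve megabase structure on the 2 Mb domain) of per-pair log₂
fold against signed distance, evaluated on an 81-point grid; statsmodels'
lowess cannot combine `delta` thinning with `xvals`, so curves are computed
with `delta` = 1% of the range and linearly interpolated onto the grid.

The null both for the envelope and for pair-level calls permutes each
anchor's fusion-status labels independently across samples (200
randomizations by default), preserving the expression correlation structure.
The envelope is the pointwise 2.5%/97.5% band of the null curves.  Pair-level
p-values studentize each pair's log₂ fold by its own permutation mean and
standard deviation and pool the standardized null across pairs.  Pooling is
essential: a strictly per-pair empirical p has a floor of 1/(n_rand+1) and
can never survive BH across ~10⁴ pairs, while raw (unstandardized) pooling
is dominated by the heavy tails of small-positive-group pairs; the
studentized pooled null makes pair statistics approximately exchangeable and
yields a p lattice of size n_rand × n_pairs.  No standard procedure exists
for calling fusion-specific neighbor dysregulation at this granularity, so
this construction is the package's own declared design.  The 90th-percentile
fold-change export uses linear interpolation and strict exceedance.

## ssGSEA subtyping

Genes are ordered by decreasing expression (average ranks for ties; ties are
then ordered stably).  With in-set weights w = rank^α (α = 0.25, the
published weighted-protocol choice; configurable), the raw score is
Σᵢ (P_in(i) − P_out(i)) over all list positions.  A closed form —
Σ_{j∈set} w_j(N+1−pos_j)/W − (T − Σ_{j∈set}(N+1−pos_j))/(N−m) with
T = N(N+1)/2 — is algebraically identical to the running sum and powers the
vectorized permutation null; tests assert the equality of both routes.
Normalization divides by the mean |score| of 1,000 size-matched random gene
sets (the mean-absolute convention keeps signs interpretable where the
source protocol is ambiguous between mean and mean-absolute).  A flat
expression vector carries no ranking information: its scores are 0 by
convention, the argmax tie resolves to the first subtype in the fixed order
and is flagged.  The burden test crosses the top fusion-burden decile
(burden ≥ 90th percentile, ties included) against membership in
{immunoreactive, proliferative} in a two-sided Fisher exact test.

## The synthetic cohort generator

The generator's defaults are the study conditions the analysis assumes:

* 24 chromosomes with a 90→30 linear ramp of genes per chromosome
  (1,440 genes), intergenic gaps log-normal around 120 kb — giving ~10–15
  window neighbors per anchor at the ±1 Mb scale;
* genes with 4–9 exons of 150–450 bp; intron lengths gamma-distributed
  (mean 6 kb) and assigned in decreasing order along transcription, the
  5′-heavy intron profile of eukaryotic genes;
* per-tumor fusion burden negative binomial (mean 22, size 4), targeting a
  cohort median of ~21 with IQR ~14–32; immunoreactive/proliferative samples
  carry √1.6-fold higher mean burden than differentiated/mesenchymal ones;
* 70% intrachromosomal partner pairs; breakpoint region weights
  (0.30, 0.40, 0.30) over (5′UTR, CDS, 3′UTR) at both ends — UTR-enriched
  relative to the span-uniform null, in which introns make the CDS dominate;
* 20 planted fusion-upregulated genes (fold 4, 15 forced positive samples)
  and 10 planted anchors (peak fold 3, linear decay to 1 at 1 Mb, 12 forced
  positives) on distinct chromosomes; the linear kernel
  1 + (F−1)·max(0, 1−|d|/L) is the simplest recoverable monotone decay —
  the aggregate smoothed profiles reported for real cohorts do not
  constrain the shape;
* expression log-normal: per-gene baseline ln-mean ~ N(1.5, 1), sample
  noise σ(ln) = 0.5; all effects are multiplicative on FPKM.  Effects
  condition on the *final* fusion-positive sample set of a gene (forced plus
  background calls);
* subtype signatures of 50 genes each, activated by +2 natural-log units in
  samples of their subtype;
* copy-number states with frequencies (0.02, 0.18, 0.60, 0.18, 0.02) and
  the +2 state tilted 3-fold at fused (gene, sample) pairs;
* a 50-pair false-positive pool drawn from 40 reserved genes that never
  appear in true calls, duplicated into the panel of normals.  True-call
  classifier probabilities are drawn as 0.81 + 0.19·Beta(8, 2) and
  false-positive probabilities as Uniform(0.5, 1.0), so the probability
  filter retains every true call and panel subtraction removes exactly the
  pool — making "post-filter calls = manifest truth" an exact invariant
  rather than a statistical one.

Everything is deterministic under the config seed (per-stage generators are
spawned from it).  What the generator does **not** emulate: read-level noise
and mapping artifacts, breakpoint-coordinate jitter between tumor and normal
calls of the same event, correlated expression programs beyond the four
subtype signatures, copy-number-driven expression dosage, overlapping genes
and isoform diversity.  Passing recovery tests therefore demonstrates the
statistical machinery, not robustness to alignment-level artifacts of real
data.

## Problem sizes in the test suite

The calibration cohort is 200 samples × 1,000 genes with every effect
switched off; the recovery cohort is the default configuration above.  The
region-test calibration uses 200 replicates of 5,000 breakpoint ends with
2,000 permutations each: with fewer ends the per-region counts are so
discrete (the null 5′UTR mass of a spliced transcript is well below 1% of
its span) that doubled two-sided empirical p-values are visibly
super-uniform and a KS-vs-uniform check rejects for lattice reasons rather
than miscalibration.  Envelope coverage on null cohorts is asserted as a
mean over three replicate cohorts because a single 95% pointwise band over
a smoothed curve has lumpy per-cohort coverage (excursions span several
correlated grid points).

## Known limitations

* Panel-of-normals matching is gene-pair-level by default (breakpoint-level
  available); real pipelines may want fuzzy breakpoint matching.
* The regional scan treats anchors independently; overlapping windows of
  nearby co-fused anchors can implicate the same neighbors twice (the
  gene-level report deduplicates by neighbor).
* ssGSEA tie handling inside tie groups is stable-order, which can move
  scores negligibly for heavily tied (e.g. zero-inflated) samples.
* The Wilcoxon screen assumes exchangeable samples; no covariate adjustment
  (purity, batch) is provided.
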