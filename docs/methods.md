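# Methods

## Model and procedure

The package treats a single-cell reference as a fixed, annotated measurement
of cell-type expression structure: each cell carries exactly one sub-cell
type label, each sub-cell type belongs to exactly one cell type, and the
expression values are non-negative counts on an arbitrary scale. No per-cell
library-size normalization is applied by default — the specificity
computation operates on raw counts, and a pre-normalization hook on
`SingleCellDataset` is available but off. Specificity `e[g, c]` is the share
of gene *g*'s total sub-cell-type mean expression falling in sub-cell type
*c*; rows sum to one, so multiplying all of one gene's raw values by a
positive constant leaves its specificity row exactly unchanged. Cell-type
specificity is the within-cell-type sum of sub-cell-type columns, which
preserves row sums.

The enrichment test is a permutation-style bootstrap: the observed summed
specificity γ(X, c) of the target list is ranked against the γ of random
lists of the same length drawn without replacement from the background.
Exceedances are counted with ties against the target (≥), which is
conservative. The default p-value estimator adds one to both the count and
the denominator, `(count + 1)/(reps + 1)`: a finite bootstrap then never
reports p = 0, and the estimator is exactly uniform on its support under
the null. The raw fraction `count/reps` is available (`continuity=False`);
writers render a raw zero as "< 1/reps". The z-score uses the sample
standard deviation (ddof = 1); at typical replicate counts this is
indistinguishable from the population form, and a zero-variance null yields
`z = NaN` with p and fold still defined.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| expression filter threshold | 0.2 | mean counts per sub-cell type | a handful of reads in one cell would otherwise fake a perfect marker; a gene is kept only if its best sub-cell-type mean is **strictly** above the threshold |
| bootstrap replicates | 100,000 | lists | p-value floor 1/(reps+1) ≈ 1e-5; smaller values are fine for exploration |
| tail size k (transcriptome mode) | 250 | probes | the most up-/down-regulated probes per direction; deduplicated to unique genes *after* selection, and the null list length follows the deduplicated count |
| property grid | 10 × 10 | deciles | empirical deciles of mean transcript length and GC fraction over the background; right-closed bins, ties to the lower bin, degenerate axes collapse with a warning |
| correction | Bonferroni (gene-set), BH (transcriptome) | — | applied over the full family of one invocation (lists × groups × directions) |

## Design choices where the design was open

* **Direction of the p-value.** The probability counts null lists with
  *higher* summed specificity than the target, so strong enrichment gives a
  small p. Ties count against the target.
* **Ortholog mapping** is filtered to strict 1:1 pairs; every symbol in a
  many-to-many relation is dropped and reported. Ambiguous mappings would
  let one specificity row stand in for several source genes.
* **Controlled-mode uniqueness.** Null lists are drawn position-by-position
  from the target genes' grid cells; duplicates within a replicate are
  re-drawn (rejection, bounded rounds) to match the without-replacement rule
  of the uncontrolled mode. If the combined cell membership cannot supply
  enough distinct genes the replicate keeps duplicates and a single warning
  is logged.
* **Transcriptome-mode null.** "Re-ranking the detected genes at random" is
  implemented as uniform sampling of k-subsets from the study-restricted
  background — operationally identical, and it reuses the one sampling
  engine. Both directions draw their null with the same seed, making the
  up/down results swap *exactly* when every t-statistic is negated.
* **Multi-study consensus** sums raw per-study null matrices and target
  gammas index-aligned; studies run with different replicate counts or group
  sets are refused rather than resampled or renormalized. Self-merge and
  merging with an all-zero study reproduce the single-study p and fold
  exactly, because the exceedance indicator and the fold ratio are invariant
  to doubling.
* **Determinism.** Each sampling run consumes a single NumPy generator
  seeded from its `seed` argument with a fixed batch size, so outputs are
  bit-identical across runs and unaffected by thread count.

## The synthetic-data generator

`simulate_sct` plants disjoint marker sets per sub-cell type: markers have
mean expression `baseline_mean × marker_effect` in their own sub-cell type
and `baseline_mean` elsewhere; non-markers are flat. Counts are Poisson or
gamma-Poisson (negative binomial, `var = μ + 0.5 μ²` by default, mimicking
UMI overdispersion; Poisson is used for closed-form checks, where a marker's
expected specificity is `f/(f + k − 1)` for effect *f* over *k* sub-cell
types). The default reference is desk-scale: 1,000 genes, six sub-cell
types in three cell types, 25 cells per sub-cell type, 5% markers per
sub-cell type, five-fold marker elevation over a baseline mean of one
count.

Companion generators produce target lists of controlled purity, DE tables
with a known shifted group (optionally with duplicated probes), ortholog
tables with configurable dropout, and gene-property tables. Property
simulation can shift marker log-lengths upward (in units of the baseline
log-length SD 0.7, around a 2 kb median) and nudge marker GC, recreating
the length/GC confounding the controlled bootstrap exists to remove. The
companion biased-list sampler weights genes by their empirical
length-decile index raised to a power, uniform within a decile — the coarse
"long genes preferred" selection effect seen in genetic studies, and the
bias class a decile-matched null can remove. A selection bias varying
steeply *within* a decile is not removable by decile matching and is a
known limitation of the grid approach, not of this implementation.

What the generator does not emulate: dropout/zero-inflation beyond the NB
noise, doublets, batch effects, library-size variation, correlated gene
modules, or graded (non-block) marker structure. Passing tests therefore
demonstrate correctness of the statistics and calibration under
exchangeable or block-structured truth, not robustness to every artifact of
real single-cell data.

## Validation experiments and problem sizes

The validation suite (mirrored by `scripts/acceptance.py`) uses these
sizes, chosen so the full battery runs in minutes on one core:

* **Enumeration oracle** — six genes with dyadic specificity rows (exact in
  binary floating point, so ties are unambiguous), lists of two, all 15
  pairs enumerated, 100,000 bootstrap replicates; agreement within three
  binomial standard errors per group.
* **Null calibration** — exchangeable reference (`marker_effect = 1`),
  1,000 random 20-gene lists, 2,000 replicates per list; KS uniformity at
  α = 0.01 and empirical size within [0.03, 0.07].
* **Power** — 200 fresh simulations at `marker_effect = 10`, pure 20-gene
  marker lists, 1,000 replicates; detection in ≥ 95% and smallest p in
  ≥ 99% of runs.
* **Confounding correction** — markers of the tested group shifted +2 SD in
  log-length, 500 decile-biased null lists (bias exponent 2), 2,000
  replicates; the uncontrolled bootstrap over-rejects (> 0.10) while the
  controlled bootstrap returns to [0.03, 0.07].

2,000 replicates per list keeps the p-value granularity (1/2001) far below
every tolerance in these checks while making thousand-list experiments
cheap; single-analysis runs should keep the 100,000 default.

## Known limitations

* Specificity is a relative measure: a gene expressed nowhere near the
  filtered threshold in any sub-cell type is removed, but a uniformly
  lowly-expressed gene that survives contributes as much structure as a
  highly expressed one. This is intentional (the statistic is expression-
  level-free) but means absolute expression differences are invisible.
* The controlled bootstrap conditions on decile cells only; residual
  within-cell selection gradients remain uncorrected.
* Consensus merging presumes index-aligned, equal-shaped bootstrap
  matrices; it does not weight studies by size or model between-study
  heterogeneity.
* Differential expression is an input (a probe/gene/t table), not a
  computation of this package.
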