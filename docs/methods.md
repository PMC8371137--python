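# Methods

## Overview

`spacecat` implements the computational side of region-encoded live-cell
tagging experiments: a sample is stained with photocaged dyes, user-drawn
regions are photoactivated with near-UV light, and tagged cells are tracked
by imaging, sorted by flow cytometry, and profiled by single-cell RNA-seq.
The package covers (i) the design arithmetic of such experiments (dye-code
combinatorics, exposure budgets, sort purity, recovery yield), (ii) the
image and flow quantification that validates tagging, and (iii) the
downstream transcriptomic analysis that turns a region label into a
continuous spatial axis. A synthetic-data module generates all inputs with
planted ground truth, so every stage is testable end to end without
external data.

## Dye-code model

Uncaging is modeled as a hard threshold: a dye uncages in a region exactly
when some exposure at or above its threshold occurs after the dye is
stained. Partial uncaging kinetics at intermediate exposures are not
modeled. Dyes persist in cells once stained, so a later high exposure also
uncages earlier-stained dyes of lower threshold; within a threshold class
this restricts a single experiment to "prefix" states (0, 1, ..., n dyes of
the class uncaged, in stain order). Classes with distinct thresholds
compose independently, giving `prod_k (n_k + 1) - 1` distinct non-empty
codes for class sizes `n_k`. One slow dye (10 s threshold) plus two fast
dyes (0.5 s) therefore encode five regions, and `max_codes` maximizes the
product over balanced splits of a dye budget. The closed form is verified
against exhaustive enumeration of stain orders and exposure sequences for
all small dye sets.

The exposure budget scales phototoxicity-limited illumination across
objectives: photon flux through an objective scales with magnification
squared (a x20 field is four times the area of a x40 field), so the safe
exposure at magnification `M` is `limit_ref * (M_ref / M)^2`, with the
reference 4 s at x40.

## Image quantification

Nuclei are segmented by robust background thresholding: the nuclear channel
is Gaussian-smoothed (sigma = `smoothing_scale`, default 1 px), pixel
intensities are trimmed by 5% at each tail, and the threshold is the
trimmed mean plus `threshold_sd_multiplier` (default 3) trimmed standard
deviations. Connected components smaller than `min_object_pixels` (default
9 px) are discarded. The default multiplier was chosen so that, on
synthetic fields with realistic pixel noise, background fluctuations do not
survive as objects while every planted nucleus does; the object count is
invariant to adding a constant offset to the image because the threshold
shifts with it.

Each cell's mean fluorescence is read under its nuclear label in the pre-
and post-photoactivation channels, and the change in fluorescence is
`dff = (F_post - F_pre) / F_pre`. Cells with non-positive baseline are
flagged and excluded rather than raising. Mask membership is decided by the
nuclear centroid (half-open rectangles, 0-based row-major pixels); compared
with propagating full cell bodies, this changes only boundary cells and
none of the per-cell statistics. Inside- vs outside-mask `dff` is compared
with a two-sample Student's t test (pooled variance; Welch available),
two-sided.

## Flow purity model

A sorted dataset of `n` cells is treated as gate-positive events drawn from
a pre-sort mixture of on-target cells (gate-positive at the sample's
measured rate `q`) and off-target cells (gate-positive at the
control-measured background false-positive rate `b`). With equal pre-sort
abundance (the default, overridable via `abundance_ratio`), the expected
number of off-target cells among the sorted `n` is `n * b / q`. Fisher's
exact test is implemented by probability ordering: with margins fixed, the
two-sided p-value sums hypergeometric probabilities of all tables no more
probable than the observed one (ties counted with a 1e-9 relative slack);
the sample odds ratio `ad/bc` is reported.

## Differential expression

Log-normalized expression of a gene in one group is modeled as a mixture of
a point mass at zero (probability `1 - pi`) and a Gaussian on the positive
values. The MLEs are closed-form: `pi` is the detection fraction, `mu` and
`sigma^2` the moments of the positive values (with a 1e-8 variance floor
against degenerate groups). The bimodal likelihood-ratio statistic is
`2 (LL_a + LL_b - LL_pooled)`, referred to chi-square with df = 3 by
default (per-group `pi`, `mu`, `sigma^2`); a shared-variance variant with
df = 2 is available. The default was validated by simulation: on 1000 null
replicates the test rejects at the 5% level at close to the nominal rate.
Two groups that are entirely zero carry no information and return
`lr = 0, p = 1`.

The rank-sum test uses midranks with tie-corrected variance; for combined
sample sizes up to 12 the two-sided p-value is computed by exhaustive
enumeration of group assignments, above that by the normal approximation
(agreement at the boundary is better than ~0.1 in absolute p). Cohen's d
pools group variances with `n - 1` weights. Multiple-testing correction
(Bonferroni, Benjamini-Hochberg) preserves input order. Cell quality
filtering removes cells strictly below `min_genes_per_cell` (default 200)
detected genes; a total-count filter for full-length libraries is off by
default (the 100,000-read convention is exposed as
`destats.SMARTSEQ2_MIN_READS`) because UMI-based data would not survive it.

## Spatial analysis

Counts are log-normalized as `e = ln(1 + s * x / T)` with scale factor
`s = 10,000` and per-cell total `T`; zeros are preserved and the transform
is invertible. The region score of a cell is the plain, unweighted sum of
log-normalized expression over a gene set (typically genes upregulated in
the photoactivated region); a z-scored variant is opt-in. Every gene's
Pearson correlation with the score is tested against a permutation null:
the score vector is shuffled across cells (equivalent to shuffling the gene
under exchangeability), all correlations recomputed, and the two-sided
p-value is `(1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1)` with `n_perm =
999` by default — the +1 estimator keeps p positive and type-I valid, with
a floor of 1/(n_perm+1). Significant genes are split by correlation sign,
yielding the opposing expression gradients along the inferred spatial axis.

Module scores subtract expression-matched controls: genes are ranked into
24 average-expression bins and 100 controls per member gene are sampled
(seeded, without replacement, excluding the set). Cell-cycle phase is the
larger of the S and G2/M module scores, or G0/1 when both are
non-positive. Composition shifts are tested per cell type with 2x2 exact
tests (type-vs-rest by condition, BH-corrected) or globally with a Pearson
chi-square without continuity correction. Cell-type dendrograms use
complete linkage over `1 - Spearman correlation` of mean expression
profiles across DE genes, exported as Newick. The power to observe at
least `k` cells of a population at frequency `f` among `n` sampled cells is
the binomial tail `P(X >= k)`, `X ~ Binomial(n, f)` — a standard stand-in,
stated as such.

## Synthetic data

`generate_counts` draws gamma-Poisson (negative-binomial) counts: per gene
and cell, rate ~ Gamma(shape = dispersion, scale = mean/dispersion), count
~ Poisson(rate) — the standard overdispersed noise model for UMI data.
Structure is planted on top of a flat baseline mean: each of 5 cell types
carries 10 disjoint marker genes whose mean is multiplied by 6 in-type, and
a border program of 250 genes (half up, half down) whose mean is scaled by
`exp(+/- effect * proximity)` along a latent border-proximity gradient.
Border-labeled cells (30%) draw proximity ~ Uniform(0,1); whole-region
cells draw Beta(1,3), skewed toward 0 — the labels overlap on the gradient,
so the signal is a smooth trend rather than a two-group step.

Defaults (800 genes x 500 cells, baseline mean 2 UMI/gene, dispersion 2,
effect amplitude 1.0 log-fold) were chosen once for testability: the
program must be detectable with high sensitivity at these sample sizes, the
non-program gene count must still exceed 500 so the permutation null can be
calibrated on the same design, and the planted-to-null gene ratio must be
high enough that a 5% false-positive rate among nulls cannot dominate the
discoveries. Real tissue data differ in ways the generator does not
emulate: no ambient RNA, doublets, batch effects or library-size
confounding, a flat baseline instead of a heavy-tailed mean distribution,
and independent genes outside the planted programs. Passing recovery tests
therefore demonstrate correctness of the machinery under the stated model,
not performance on real tumors.

`generate_fluorescence_field` renders non-overlapping discs (rejection
sampling, minimum separation 2r + 2 px) with nuclei at half radius,
multiplies in-mask cells' post image by the uncaging factor, and adds
zero-truncated Gaussian pixel noise. `generate_flow_events` draws
gate-positive flags at configured per-population rates; its defaults mirror
a measured 0.19% control false-positive rate and ~9% tagged-positive rate.

## Pipeline

`run_pipeline` chains simulate/load -> QC -> normalize -> region DE ->
region score -> gene-score correlation and writes MTX counts, CSV tables,
gene lists and a JSON report with per-artifact SHA-256 checksums. One
global seed drives everything; per-stage seeds are spawned from it via
`numpy.random.SeedSequence`, so identical configs produce byte-identical
artifacts. The default simulated run uses 1500 cells so the region DE
stage (bimod, Bonferroni-adjusted p < 0.05, matching the analysis the
score is built from) reliably yields a non-empty up-regulated gene set;
MTX indices are 1-based on disk per the Matrix Market standard and 0-based
in memory.

## Known limitations

- The dye-code model is binary (uncaged or not); intermediate exposures
  between thresholds yield no partial signal.
- The contamination model assumes the background rate measured on a control
  transfers to the sorted sample's off-target population.
- The segmenter is a deliberately small robust-threshold component; it is
  not a replacement for a full segmentation pipeline on real micrographs
  (no declumping, no propagation to cell bodies).
- Permutation p-values inherit the 1/(n_perm+1) floor; genome-scale FDR
  control at small alpha needs more permutations than the default 999.
- The protocol-facing worked examples (sort purity, yield, exposure, dye
  codes) are exact arithmetic; the statistical criteria are calibrations on
  synthetic data at the problem sizes stated above, chosen as the package's
  own study conditions.
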