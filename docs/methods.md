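# Methods

## The generative model

`picmix` treats an scATAC-seq paired-insertion count `x_ij` (cell *i*,
region *j*) as the end of a three-stage process. Chromatin at a region is
assumed binary per cell: open with probability `pi_j` (Bernoulli). Tn5
cutting then produces a latent number of insertion pairs `y_ij`, Poisson
with rate `lambda_c_j * s_j` in open cells and `lambda_c_j` in closed ones —
the background rate `lambda_c_j` absorbs region-level technical preference
(GC content being the modelled representative), and the signal-to-noise
ratio `s_j >= 1` is the fold increase cutting gains from openness. Finally,
library preparation and sequencing observe each latent pair independently
with cell-specific probability `p_i` (Binomial thinning), which is the
model's replacement for library-size scaling: depth acts on the *zero
pattern*, not multiplicatively on values, matching the empirical fact that
the non-zero mean of scATAC counts barely moves with total count.

Because Binomial thinning of a Poisson is Poisson, the marginal of each
component is `Poisson(rate * p_i)`. The posterior open probability is

    P(Z=1 | x) = pi f(x; lambda s, p) / [pi f(x; lambda s, p) + (1-pi) f(x; lambda, p)]

`marginal_pmf` evaluates `f` by the truncated latent sum (default bound 50,
extended automatically until the neglected Poisson tail is below 1e-12);
the closed form is kept alongside and the two are cross-checked to 1e-8 in
the tests. The posterior is clamped to [0, 1]; when the denominator
underflows (impossible counts at degenerate parameters) the prior is
returned.

A consequence worth naming because it drives every downstream result: the
ratio of zero-probabilities, closed over open, is `exp(lambda_c p (s-1))`.
Low-background regions therefore look *harder*, not easier — zeros from
open and closed cells are nearly indistinguishable — and state inference
improves with both `s` and `lambda_c`.

## Estimation

**Observation probability `p_i`.** Under the model the mean matrix
factorizes as `E[x_ij] = q_i mu_j`. We alternate the two moment updates
(`q_i <- rowsum_i / sum(mu)`, `mu_j <- colsum_j / sum(q)`) to convergence
(relative change < 1e-6, cap 500 iterations) and fix the scale
indeterminacy by setting `max_i q_i = 0.9` (configurable `p_max`). For
low-count data the all-or-nothing observation approximation `q_i` is a good
stand-in for the per-pair probability `p_i`.

**Background rate `lambda_c_j`.** Flank regions 500 bp up- and downstream
of peaks (flanks overlapping any peak removed) are assumed fully closed, so
the first moment gives `lambda_c_k = mean_k(x) / mean(p_hat)` per flank.
Flanks with rates above 10x the interquartile range are excluded as
outliers (read as an absolute bound; `Q3 + 10*IQR` available via
`iqr_mode`). A Gaussian GAM of rate on GC (cubic B-splines, basis dimension
10, smoothing chosen by generalized cross-validation over a log-spaced
grid; predictions clamped to the training GC range) is fitted on the
retained flanks and evaluated at each peak's GC, floored at 1e-6 because
the Gaussian error model can dip non-positive.

**Open proportion and signal-to-noise `(pi_j, s_j)`.** With cell-specific
`p` the pair is unidentifiable from single observations, so cells are
sorted by `p_hat` and pooled in groups of 100 (a trailing pool smaller than
half the pool size is dropped); within a pool the pool-mean `p` stands in
for all members. Per pool and region the empirical pmf on `{0..K}`
(`K = max count + 2`) is matched to the mixture pmf in Euclidean distance
over a grid (`pi` in 0.01..0.99 step 0.01; `s` on a 60-point log grid in
[1, 500]); the distance is quadratic in `pi` at fixed `s`, so the whole
grid is evaluated in closed form, followed by a local refinement around the
optimum. Final estimates are means over pools. Two guards: regions all-zero
in every pool return `(0, 1)` flagged; and a pool whose empirical pmf the
closed-only model already explains to within five times its expected
multinomial sampling error contributes `(0, 1)` — without this parsimony
rule the two free mixture parameters chase pure sampling noise in
signal-free regions and inflate `pi`. At the informative corner
(`pi = 0.3, s = 100, lambda_c = 0.02`, 10,000 cells) the estimator carries
a small finite-pool bias (about +0.03 on `pi` at pool size 100) that
shrinks with pool size.

## Normalization family and diagnostics

TF, CPTT, IDF and the five TF-IDF flavors follow their published formulas
with natural logs (no base is standardized in the ecosystem); binarization
defaults follow each tool's default and always precede the TF/IDF
computation. The diagnostics expose two structural facts: TF divides by
total count, so in near-binary data the denominator *is* the depth; and IDF
multiplies region variance by exactly `1/mu_j^2`, steepening the
mean-variance relationship. LSI is TF-IDF followed by SVD with a
deterministic sign convention (largest-magnitude loading positive) and an
optional drop of the first component.

Full-quantile normalization sorts each column, replaces ranks by the
cross-column median, and unsorts. Tie handling is explicit: `positional`
(default) pushes reference values through ties by row order and guarantees
identical sorted multisets across columns; `average` gives tied entries
(e.g. a sparse cell's zeros) the mean reference over their rank span. The
GC-stratified variant normalizes within 10 equal-frequency GC bins and
smooths in two ways: bin-boundary blending of the two nearest bins'
reference quantile functions (weights by the region's GC distance to the
bin midpoints; one bin reduces exactly to plain FQ), and an optional
replicate-group shrinkage in which each rank's value is a compromise
`w * reference + (1-w) * group reference` with `w` the within-group share
of the rank's variance (rolling-median smoothed) — ranks where groups
genuinely differ keep their group's quantiles.

The mock-null test randomly splits a cell type's donors into
`floor(D/2)` / `ceil(D/2)` groups (seeded; the split depends only on the
donor set, not the counts), computes per-region log2 fold changes of group
pseudobulk means with pseudocount `0.5 / group cell count` (the literature
states none; configurable), cell-level Wilcoxon rank-sum p-values
(scipy's Mann-Whitney U), GC-decile assignments, and a GAM of LFC on GC.
Under the null the GAM should be flat at zero; its shape measures residual
GC bias.

A caveat established while validating the quantile corrector: within-bin
full-quantile normalization across *cells* equalizes each cell's per-bin
distribution by construction, so it removes most of an injected across-bin
LFC trend even at 98-99% sparsity (what survives is roughly the within-bin
share of the trend, ~1/n_bins, plus tie artifacts). At pseudobulk
resolution the correction is near-total (>90% of the injected amplitude)
while cell-level application leaves a several-fold larger residual; the
cell-level residual does not, however, robustly exceed half the raw
amplitude in these synthetic conditions. Real single-cell data may behave
worse than this synthetic bound suggests (cell-type mixture, donor-specific
bias shapes, and implementation details of published correctors all push
toward less correction).

## Aggregation and embeddings

Peaks map to the gene whose TSS (strand-aware) is nearest the peak
midpoint, ties to the lower coordinate then lexicographic id; counts are
summed per gene, conserving totals over assigned peaks. Gene-level GC is
the count-weighted mean of member-peak GC. The mixture model is refitted on
the gene matrix and the posterior matrix decomposed with PCA (centering,
no scaling, full SVD, fixed sign convention; constant features dropped).
Evaluation reports Pearson correlation of leading components with library
size and mean silhouette width per cell type (exact Euclidean silhouettes;
a centroid-plus-dispersion approximation,
`d(x, C)^2 = ||x - c_C||^2 + mean_y ||y - c_C||^2`, is available for large
n and agrees with the exact means to ~0.05 on test fixtures). Multiome QC
removes cells with ATAC total >= 100,000, RNA total >= 25,000 or RNA total
<= 1,000.

## Synthetic data

The generator emulates the study conditions end to end: fixed-width 500 bp
peaks packed with room for 500 bp flanks on a random genome, per-peak and
per-flank target GC drawn from Beta(2, 2) rescaled to [0.25, 0.75] and
realized exactly by base counting; background rate
`lambda_c(GC) = 0.001 + 0.02 * GC` (spanning the sparse regime of real
peak matrices); `s` log-uniform in [10, 100]; open proportions 0.3 with
40% of peaks turned into cell-type markers (0.7 in the owning type, 0.05
elsewhere); observation probabilities Beta(2, 4)-shaped on (0, 0.9],
independent of cell type. Observed pairs become fragments with both
insertions inside the peak (length uniform in [50, width-1]); flank
regions receive background fragments at `lambda_c(GC_flank) * p_i`; and
long spanning fragments with both insertions outside peaks and flanks are
injected at low rate to exercise the PIC zero-count rule. Counting the
emitted fragment file over the peak set reproduces the generator's count
matrix exactly — the round trip is asserted in the tests.

What the generator does not emulate: sequencing errors and mapping,
doublets, mitochondrial contamination, per-donor GC-curve shapes, and any
correlation between depth and cell type. Passing tests therefore
demonstrate correctness of the algorithms under the model's own
assumptions, not performance on arbitrary real data.

## Problem sizes and numerical choices

The default test suite and the acceptance script run the simulation grid at
10,000 cells x 30 repetitions (the tests use 2,000 x 5 and verify the same
orderings with a 0.02 Monte-Carlo allowance), parameter recovery at 10,000
cells / 10,000 background regions / 5,000 peaks, and the mock-null and
embedding fixtures at roughly 1,000 cells x 2,000 regions — sizes chosen so
every check completes in minutes on one core while keeping Monte-Carlo
error well inside the asserted tolerances. All randomness flows through
explicit seeds (numpy `SeedSequence` spawning per grid point and
repetition), so every number in the README and the acceptance output is
bit-reproducible.

Known limitations: the `(pi, s)` estimator's small-sample bias at pool size
100; unidentifiability of `(pi, s)` when `lambda_c * s * p` is tiny (the
parsimony rule then prefers the closed-only explanation); the GAM is
univariate in GC (peak length, the other obvious region covariate, is held
fixed by the fixed-width design); and posterior computation is exact only
up to the stated truncation tolerance.
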