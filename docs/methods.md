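# Methods

This note records the models, estimators and numerical choices behind
`toporsa`, the assumptions they rest on, and what the bundled synthetic
generator does and does not emulate.

## Representational dissimilarity

All comparisons operate on representational dissimilarity matrices
(RDMs): for condition patterns `p_i ∈ R^F`, `d_ij = 1 − r(p_i, p_j)`
with `r` the sample Pearson correlation across the feature axis.
Entries lie in `[0, 2]`; the matrix is symmetrized exactly and its
diagonal forced to zero. A zero-variance pattern makes the correlation
undefined and is reported as an error naming the offending condition,
rather than silently producing NaN.

RDMs are compared by Spearman's ρ on the strictly-lower-triangle
entries only (diagonal always excluded), with average ranks for ties.
The comparison is therefore invariant to any strictly increasing
transform of either triangle. A constant triangle has no rank order;
the comparison returns NaN with a warning instead of an arbitrary
number, and downstream group statistics drop NaN cells subject-wise.

Group summaries are always computed on subject-level correlations,
never on an averaged RDM: averaging RDMs before comparison would
discard between-subject variability and invalidate the SEM and the
sign-flip tests.

## Multivariate noise normalization

Beta patterns are whitened as `P Σ^(−1/2)` before RDM construction.
The symmetric (eigendecomposition-based) inverse square root is used
rather than a Cholesky factor so the operation does not depend on an
arbitrary voxel ordering. Σ is estimated from GLM residuals; the
default estimator (`diag_shrink`) shrinks the sample covariance toward
its own diagonal with a data-driven intensity (the ratio of the summed
sampling variances of the off-diagonal entries to their summed
squares, floored at 1e−3). Diagonal entries are preserved exactly and
the estimate is positive definite even with more voxels than residual
timepoints. Ledoit–Wolf shrinkage toward the scaled identity and plain
sample covariance plus ridge are available as config switches; whether
a full multivariate or univariate normalization is "right" for a given
dataset is an empirical question, so the choice is exposed rather than
hidden.

## Noise ceiling

The ceiling follows the standard leave-one-out convention: the lower
bound is the mean over subjects of ρ(subject RDM, mean RDM of the
*other* subjects); the upper bound uses the mean of *all* subjects
(each subject's own RDM included, hence optimistic). The bound
ordering `lower ≤ upper` is an expectation-level property; it holds in
every simulation the test suite runs but is not enforced numerically.

## Event-related GLM

Condition events are zero-duration impulses convolved with a canonical
double-gamma HRF (response peak 6 s, undershoot 16 s, undershoot ratio
1/6, 32 s support, unit peak amplitude normalized on a fixed dense
grid so the scale is independent of the caller's sample times).
Convolution runs on a 16× oversampled grid and is read out at scan
times, so onsets need not align with the TR. No intercept is added
implicitly: run/constant regressors are passed explicitly as nuisance
columns, matching the per-run-constant convention of first-level fMRI
models; an all-zero nuisance column is rejected, never dropped. Null
trials, when present, are collapsed into a single nuisance regressor
(the alternative — leaving them implicit in the baseline — is a
config flag away via `model_nulls=False`). Estimation is ordinary
least squares; rank-deficient designs fall back to the minimum-norm
pseudo-inverse with a warning. Prewhitening, slice timing and motion
estimation are out of scope: residuals are consumed only as a noise
covariance estimate.

The pipeline's synthetic path generates residuals directly from the
specified noise covariance instead of simulating BOLD time series and
refitting; the GLM module exists so the residual-based normalization
path can be exercised on real or simulated time series through its own
interface.

## Topographical correlation maps

Coordinates are 0-based with a top-left origin; `y` indexes rows
(height), `x` indexes columns (width), everywhere in the package. At
each grid cell of a conditions × H × W × D stack, the depth vectors
form a conditions × D pattern matrix and hence a local RDM; cells
where any condition's depth vector has zero variance are flagged
invalid (NaN) and excluded from all downstream statistics — zero
filling would masquerade as "no correlation". For an H = W = 1 stack
the field collapses exactly to whole-layer RSA.

Correlation maps rank-transform each cell's triangle once and
correlate against every subject's ranked ROI triangle by vectorized
Pearson-on-ranks (identically Spearman with average ranks).

Group inference runs on the native H × W grid; upsampling to image
resolution (corner-aligned bilinear by default, nearest-neighbor
optionally) is display-only. Interpolating significance would
manufacture spatial precision the data do not contain. Invalid cells
are excluded from the interpolation support, and output pixels whose
nearest input cell is invalid stay NaN. No receptive-field geometry is
modeled: grid cells map linearly onto the image square.

## Sign-flip permutation and cluster-size inference

The group statistic is the across-subject mean at each cell (a
t-statistic would also be valid under sign symmetry; the mean is
stable for bounded ρ at these sample sizes and keeps the null exact).
The null negates whole subject maps, preserving each subject's spatial
covariance. Observed p-values follow the add-one rule, so the smallest
attainable p is `1/(B+1)` for `B` permutations.

Cluster inference pools the observed labeling with the `B` flipped
labelings into one exchangeable set of `B+1` members. Every member's
statistic map is ranked cell-wise against the pool (two-sided on the
absolute statistic), thresholded at the cluster-defining threshold,
and its maximum cluster size (over the whole map and both signs)
recorded; a cluster's p-value is the fraction of members whose maximum
size reaches the observed cluster's size. Ranking the permuted maps
against a distribution that excludes the observed member — a tempting
shortcut — is anti-conservative: simulation puts its familywise error
near 0.10 at α = 0.05, while the pooled construction measures ≈
0.03–0.06 on smooth null maps (500 datasets, 13 × 13 grid,
CDT 0.01).

Clusters are sign-homogeneous connected components (8-neighbor by
default, 4-neighbor via config) of cells with pointwise p below the
CDT. Correlations are tested untransformed (no Fisher z): the sign-flip
test is distribution-free under sign symmetry, and a monotone
transform would not change the flips' ordering at a single cell.

## Layerwise significance

Per-(layer, ROI) one-sided sign-flip tests ("correlation above zero")
are exhaustive over all `2^N` sign patterns for `N ≤ 16` subjects
(no add-one term needed; the identity labeling is part of the
enumeration) and Monte Carlo with add-one beyond that. Bonferroni
correction defaults to the layer × ROI family (5 × 4 = 20 in the
default configuration) and is configurable; a family smaller than the
number of tests run triggers a warning but proceeds.

A structural consequence worth knowing: with `N` subjects the
exhaustive floor is `2^−N`, so at family size 20 and α = 0.05
layerwise significance is attainable only for `N ≥ 9`. The reduced
default profile (8 subjects) therefore never shows layerwise stars —
expected, not a bug — while cluster inference, whose floor is
`1/(B+1)`, still resolves significance there.

## Classical MDS

Torgerson scaling: double-center the squared dissimilarities,
eigendecompose, return the top coordinates scaled by root
eigenvalues. Only positive-eigenvalue axes are meaningful; requesting
more dimensions truncates with a warning. A Euclidean distance matrix
round-trips to its generating configuration up to rotation/reflection
at machine precision.

## Synthetic data: what it emulates and what it does not

One latent category code — a prototype vector per category plus
per-condition jitter (4 latent dims per category, jitter sd 0.5) — is
derived from a dedicated code seed and injected into both the ROI
voxel patterns and the stack channel groups. Brain–model
correspondence in the synthetic study is therefore true by
construction and controllable: matched codes give positive
correlations, mismatched codes agree only through the shared
category-block structure.

Defaults follow the study design where it is stated: 156 conditions in
5 categories (near-equal 32/31/31/31/31 split — the per-category
counts are not public, so this is a declared choice, configurable),
15 subjects, 25% null trials, 0.5 s presentations with 2.5 s
inter-stimulus intervals, five convolutional layers, 1000
permutations, CDT 0.01, α 0.05. Where the design is silent the
defaults are chosen once for realism: AR(1) voxel noise covariance
(ρ = 0.3) so noise normalization is non-trivial; the voxel projection
scaled so a unit-strength category signal has voxel-level sd ≈ 1
against unit noise, which puts subject RDM reliabilities (noise
ceilings ≈ 0.5–0.8) and brain–model correlations (ρ ≈ 0.1–0.3) in the
range typical of event-related RSA studies; spatial gain profiles are
a center Gaussian of scale 0.25 in normalized image units, its
complement, or uniform; four ROI analogs differ in their category
weightings (none for the early-visual analog, face-, animate/object-
and scene-dominant for the fusiform, IT and PHC analogs).

Random streams are keyed per (seed, stream, index), so adding a
subject or a layer never perturbs earlier ones, and every generator is
bit-reproducible given its spec.

Not emulated: hemodynamics, physiological noise, head motion, retinal
or cortical magnification, real network features, image rendering.
Passing tests therefore demonstrate that the *analysis machinery* is
correct and calibrated (type-I error, FWER, recovery of injected
spatial structure), not that any particular brain–model
correspondence holds in real data.

## Problem sizes and profiles

The default (`ci`) profile runs the full pipeline at reduced scale —
40 conditions, 8 subjects, 60 voxels, 13 × 13 × 24 stacks, 200
permutations — chosen so a complete run takes a few seconds while
every statistical mechanism (shrinkage, whitening, ceilings, cluster
null) still operates away from degenerate regimes. The `paper`
profile restores 156 conditions, 15 subjects and 1000 permutations.
Calibration studies use 1000 null datasets (type-I), 500 smoothed null
datasets (FWER) and 20 replicates per gain profile (recovery).

## Known limitations

- No crossvalidated distances (crossnobis/LDC); dissimilarity is plain
  1 − Pearson on noise-normalized patterns.
- No parametric (random-field) or FDR correction; Bonferroni and
  cluster-size FWER only.
- Cluster-size inference assumes map-level exchangeability under sign
  flips; subjects with wildly different map smoothness would weaken
  the null's validity.
- The NIfTI/real-data path is limited to consuming pattern and
  residual matrices in the documented container format; no volume
  processing is included.
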