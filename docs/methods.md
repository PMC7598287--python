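# Methods

## Scope and data model

`cystex` analyzes one lesion per subject: a 3D intensity grid (arbitrary
scanner units, non-negative integers), a co-registered binary mask, and
a binary diagnosis (positive = endometrioma-like, negative = hemorrhagic
cyst-like). Arrays are indexed `(slice, row, column)`, 0-based;
"horizontal" means along columns within a slice. Volumes load from
NIfTI or single-frame grayscale DICOM series (rescale slope/intercept
applied, slices ordered along the orientation normal; mixed orientations
are rejected). Grids are analyzed natively, per slice — no resampling to
isotropic voxels is attempted, since clinical slice spacing (~4.4 mm)
dwarfs in-plane resolution (~0.75 mm) and 2D-per-slice texture matrices
accumulated across slices sidestep the anisotropy.

## Normalization and quantization

Matrix-family features are computed on quantized levels. With the
standard ("S") normalization, μ and σ are the mean and population SD of
*all* in-mask voxels of the 3D ROI (one window per lesion, not per
slice); intensities are clipped — not discarded, so the voxel count is
conserved — to [μ−3σ, μ+3σ], mapped linearly onto [0, 2^B−1] and
floored, the top edge mapping to the top level. A constant lesion (σ=0)
is a degenerate-ROI error. The map is exactly invariant under positive
affine intensity transforms, which is the purpose of normalization and
is enforced by tests. First-order histogram features deliberately use
**raw** intensities: percentile features are only meaningful in scanner
units (clinical values run to tens of thousands, implying >8-bit data).

Default bit depths are B = 6 and B = 4. B = 6 matches the "S6" encoding
in conventional result tables; computing the matrix families at a second
depth brings the default table to 511 named columns, in the "over 300
features" regime the workflow expects.

## Feature definitions and conventions

* **GLCM**: per-slice pair counting at offsets (Δrow, Δcol) =
  H (0, d), V (d, 0), Z (−d, d), N (−d, −d) for d = 1…5, both voxels
  in-mask, accumulated over slices, symmetrized by adding the
  transpose, normalized to sum 1. Haralick statistics use 1-based level
  indexing, so the sum marginal runs over k = 2…2K and SumAverg of a
  mid-gray image sits near K. All entropies use the natural logarithm
  with 0·log 0 = 0; since texture software rarely documents its log
  base, absolute entropy values are treated as convention-dependent and
  only orderings and internal identities are asserted. Correlat is
  undefined (NaN) when a marginal is degenerate. SumVarnc and DifVarnc
  are central second moments of the sum/difference marginals about
  their own means.
* **RLM**: maximal constant-level runs along H/V/Z/N, broken by mask
  gaps, accumulated over slices; ShrtREmp, LngREmph, GLevNonU, RLNonUni
  and Fraction (runs per traversed in-mask voxel) follow the classic
  run-length definitions.
* **Gradient**: magnitude √(Δr² + Δc²) from half-step central
  differences, only at voxels whose full 4-neighborhood is in-mask;
  population moments, excess kurtosis; GrNonZeros is the fraction of
  non-zero magnitudes.
* **Wavelet**: per slice, the mask bounding-box crop is mean-filled
  outside the mask, truncated to even dimensions at each scale, and
  decomposed with the orthonormal Haar filter (PyWavelets,
  periodization mode); subband energy is the mean squared coefficient,
  averaged over the slices that reach the scale (3 scales by default).
  Energy is conserved across each scale split, which tests verify.
* **Missing values**: any feature undefined for some lesion (empty
  co-occurrence offset, unreachable wavelet scale, no interior voxel)
  is dropped table-wide with a warning, keeping the table rectangular.
* Feature names follow the `<channel><direction?><distance?>S<bits><base>`
  grammar (`CV2S6Entropy`, `CHS6RLNonUni`, `CS6GrMean`) plus
  `WavEn<subband>_s-<k>` and bare histogram names; parsing and rendering
  are mutual inverses. Only the grayscale channel "C" is computed; "R"
  is accepted by the parser for compatibility with tables produced by
  older tools, where it denotes the red channel of the same grayscale
  render.

## Feature selection

* **Fisher**: F = Σ_{k<l} P_k P_l (μ_k−μ_l)² / Σ_k P_k σ_k² with class
  proportions and population variances; zero within-class variance with
  unequal means flags an infinite (trivially separating) score.
* **POE+ACC**: POE is the minimum misclassification fraction of the
  best single-threshold rule, scanning every midpoint between distinct
  sorted values plus the two trivial rules, both orientations; the
  greedy criterion at each step is POE(f) + mean |Pearson r(f, S)|.
  The underlying classifier is undocumented in common texture software;
  the optimal single threshold was chosen for determinism and exact
  testability against brute-force enumeration. The reported criterion
  typically ascends across picks, but is not mathematically monotone —
  the correlation penalty is a mean and can dip when a weakly
  correlated feature joins the selected set; the guaranteed invariant
  is that no later criterion undercuts the first pick's POE minimum.
* **MI**: features are discretized into 10 equal-width bins over their
  observed range (the main free parameter); plug-in mutual information
  with the class label, base-2 logs. Constant features score 0.
* Ties everywhere break lexicographically on the feature name, making
  selections deterministic.

## Statistical cascade

The union of the three top-10 lists plus one slot for the age covariate
sets the Bonferroni divisor m (m = 31 when the union has 30 members);
each union feature is tested with a two-sided Mann–Whitney U at α/m.
The p-value is exact by enumeration when the pooled sample is ≤ 12 and
tieless, otherwise the normal approximation with tie and continuity
corrections (accurate to ~0.01 against exact enumeration at 8 vs 8).
Reported quartiles use linear interpolation.

ROC analysis is fully empirical: the tie-corrected AUC equals
U/(n₁n₀); orientation is flipped (recorded as "≤") when the raw AUC is
below 0.5; the reported cutoff is the observed value maximizing
J = Se + Sp − 1, ties resolved toward higher sensitivity; the AUC CI is
the DeLong normal interval clipped to [0, 1] (degenerate at AUC = 1,
where the empirical DeLong variance is zero); Se/Sp carry
Clopper–Pearson exact CIs.

The multivariate step is an ordinary least-squares "enter" model of the
0/1 outcome on all significant features simultaneously — the reporting
conventions being mirrored (R², adjusted R², multiple-R, VIF, t-based
p-values) are those of a linear model, so no logistic link is used.
VIF_j = 1/(1−R²_j) from regressing predictor j on the others. Exact
duplicate columns are dropped (lexicographically first kept) before the
fit; genuinely rank-deficient designs raise an error naming the
collinear columns. When more features are significant than a cohort of
n lesions can support, the model keeps the n−2 lowest-p features so the
fit remains well-posed; this matters only for very small synthetic
cohorts. The fitted values are then scored by ROC as the combined
prediction model.

## The synthetic phantom

The phantom emulates the *statistical contrast* the analysis assumes,
not MR physics (no bias field, no relaxometry, no fluid-fluid levels).
Each lesion is an ellipsoid (default semi-axes 4 × 16 × 16 voxels in a
12 × 48 × 48 grid, i.e. a lesion spanning ~9 slices) of base intensity
16 000 units on a dark background, with per-lesion jitter of ±15% in
size and ±8% in brightness within a cohort.

Because the μ±3σ normalization erases per-lesion amplitude, the two
classes must differ in spatial *structure*:

* **heterogeneous** (endometrioma-like): Gaussian random field (white
  noise smoothed at correlation length 1.5 voxels, rescaled to SD 3200),
  plus white noise of SD 1000 (granular content), plus 3 parabolic
  hypointense inclusions of radius 2.5 voxels and depth 8000 ("dark
  spots", placed wholly inside the eroded mask);
* **smooth** (HC-like): correlation length 4 voxels, field SD 320
  (a tenth of the heterogeneous amplitude — the class invariant caps it
  at a quarter), white noise SD 50, no inclusions.

The short correlation length, extra white noise and inclusions make the
heterogeneous class genuinely more disordered after normalization:
higher co-occurrence entropy, lower angular second moment, higher raw
variance and high-frequency wavelet energy — the orderings the clinical
study reports. Effect sizes are free parameters (the study describes
heterogeneity only qualitatively); the defaults were fixed once from
these qualitative orderings and are documented here rather than tuned.
Default cohort sizes are 29 vs 14, the study's class balance. All
randomness derives from one seed via per-lesion spawned streams, so
cohorts are bit-reproducible.

What passing phantom tests does *not* show: that the pipeline separates
real endometriomas from HCs. The phantom's class gap is designed-in and
large; clinical effect sizes, scanner variation, segmentation error and
reader disagreement are outside its scope.

## Problem sizes and numerical choices

Tests run the full pipeline at reduced scale (typically 10 × 28 × 28
grids, 8–43 lesions per cohort, 200 replicate cohorts for the
null-calibration experiment) — sizes chosen so the whole suite runs in
minutes while keeping every code path identical to the default
configuration. Tolerances: brute-force oracle comparisons are exact to
1e-15; floating-point identities use relative 1e-9…1e-12; stochastic
properties use seeded generators with documented bounds. Degenerate
inputs (constant lesions, empty offsets, single-voxel masks) raise
typed errors or yield flagged NaNs as described above.

## Known limitations

* Per-slice 2D matrices accumulated over slices, not true 3D
  co-occurrence; direction codes are in-plane only.
* The null-calibration experiment shows that testing *selected*
  features at α/31 does not control the family-wise error of the whole
  select-then-test procedure (the selection examines the full feature
  table, so the effective comparison count exceeds 31); the corrected
  threshold is calibrated only for a prespecified feature set. This is
  a property of the workflow being modeled, preserved deliberately.
* Entropy magnitudes depend on the log base and, for sparse matrices,
  on ROI size; only orderings between classes are meaningful.
* The linear probability model can fit values outside [0, 1]; it is
  used for fidelity to the reporting conventions, with ROC of the
  fitted score as the operative output.
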