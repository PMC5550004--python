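# Methods

## The face space and its stimulus design

Faces are modeled as points in a D-dimensional reference space whose
origin is the norm (average) face; direction from the norm carries
identity and radial distance (eccentricity) carries distinctiveness.
Because randomly sampled points in high dimensions concentrate in a
narrow band of pairwise distances, the stimulus set is instead a polar
grid on a 2D plane through the origin: 3 eccentricity levels (30%, 100%
and 170% of a mean eccentricity `r`) crossed with 4 directions at 60°
separation spanning a half circle, i.e. 12 faces and 66 face pairs.
Each face appears at two mirror-symmetric viewpoints, giving 24
conditions.  The plane's orientation is randomized per participant
(drawn as a uniformly random orthonormal 2-frame via QR decomposition of
a Gaussian matrix), so all participants share one reference distance
matrix while their stimuli are physically distinct; group inference then
treats the stimulus as a random effect.

Defaults: `D = 50` (the reference model's dimensionality is a free
choice here) and `r = 1`; every model parameter is expressed relative to
`r`, so nothing below depends on the absolute scale.

## Encoding models

All models predict (a) a 24×24 representational distance matrix (RDM,
Euclidean distances between simulated population response vectors) and
(b) a population-mean activation profile (one number per condition).

**Sigmoidal ramp tuning.**  1000 units, each with a uniformly random
preferred direction in the stimulus plane and response
`y = 1/(1 + exp((−x + o)/s))`, where `x` is the signed position of the
stimulus along the preferred direction.  `o` (offset, face-space units)
shifts the midpoint away from the norm; `s` (saturation) interpolates
between step-like (`s → 0`) and near-linear (`s ≈ 4`) responses over the
stimulus range.

A structural note that matters for testing: at `o = 0` the sigmoid is
antisymmetric about 0.5, and under a uniform direction distribution
`E[y(x)] + E[y(−x)] = 1`, so the expected activation profile is exactly
flat at every eccentricity.  Eccentricity-dependent activation (and the
averaging-induced radial/tangential warping below) requires `o > 0`.
Qualitative checks of those phenomena therefore use offset cells such as
`(o = 1, s = 1)`.

**Exemplar tuning.**  1000 units with isotropic Gaussian tuning of full
width at half maximum `w` around preferred locations drawn from an
isotropic 2D Gaussian on the norm.  The radial distance of such a draw
is Rayleigh distributed, and the per-axis scale is set in closed form so
that the standard-normal-`Z = 2.32` quantile (cumulative probability
0.98983) of the radial distribution sits at `d` times the caricature
eccentricity.  The inverted variant reflects each radial distance `t`
to `T − t` about that quantile `T` and truncates negatives to zero;
the truncated fraction is analytically `1 − Φ(2.32) ≈ 1.017%`, which is
also what anchors the `radial` (rather than 1D-marginal) reading of the
`Z = 2.32` calibration: the marginal reading would truncate ~6.8% of
units.  Both readings are implemented behind a switch; `radial` is the
default.  Centers are drawn once at unit scale and rescaled lazily, so a
model instance is consistent across grids differing only in scale.

**Measurement-level population averaging.**  An fMRI voxel mixes many
neurons; this is modeled at the measurement level by translating each
unit's response toward the population mean,
`y_final = (y_raw − y_mean)(1 − p) + y_mean`, with `p ∈ [0, 1]`.  The
per-stimulus mean is preserved exactly and the across-unit spread scales
by `1 − p`, so averaging warps predicted RDMs (stretching the
population-mean dimension, which exaggerates radial relative to
tangential distances) without changing predicted activation profiles.

**Gabor filter model.**  An image-computable control: 5 banks of Gabor
filters at octave-spaced wavelengths (32, 16, 8, 4, 2 px for a 96-px
image, scaled proportionally with image size and validated against a
2-px sampling floor), envelope σ = half the wavelength, square center
grids with spacing equal to the wavelength (coarser for lower spatial
frequencies), 8 orientations, 2 quadrature phases.  Filters are
evaluated explicitly over the image support and made DC-free and
unit-norm, so a uniform image produces exactly zero response; center
grids are exactly symmetric about the vertical midline (offsets
`(k + 1/2)·spacing`), which makes the mirror-symmetry property below
exact.  Phase pairs collapse to contrast energy `sqrt(a² + b²)`;
energies are weighted per bank (5 free parameters) and passed through a
hemifield-specific pool (strength `p_hemi`, applied separately to
filters left and right of the midline) followed by a global pool
(`p_global`), both using the same mean-preserving averaging formula.
Because a mirrored image drives the mirrored filter set, feature means
match across symmetric views, and at `p_global = 1` mirror-pair
distances vanish identically — symmetric-view tolerance arises purely
from the measurement stage.

**Pixelwise correlation.**  Parameter-free control predictor: one minus
the Pearson correlation between raw intensity vectors.

## Cross-validated discriminant distances

Pattern discriminability for a condition pair is estimated per
leave-one-run-out fold as `w·(test-run contrast)` with
`w = Σ⁻¹·(training contrast)` normalized to unit length, averaged over
the 16 folds.  Train and test data are independent, so the estimate is
centered on zero when conditions do not differ, and may legitimately be
negative; this licenses one-sample T tests for above-chance
discriminability.  When the same data are used on both sides with a full
covariance estimator and no normalization, the statistic reduces exactly
to the squared Mahalanobis distance (asserted against an independent
brute-force oracle).

The noise covariance Σ is estimated per training split from the
concatenated training-run residuals with Schäfer–Strimmer optimal
shrinkage toward the diagonal of the sample covariance, which stays
positive definite even with more voxels than time points; a plain
`full` estimator is available when time points suffice.

The mean-removal variant strips region-mean-related effects before
contrasts are formed, in train and test alike: (1) each condition
pattern is set to zero spatial mean; (2) per pair, the linear
contribution of the pair-mean pattern is projected out (on the contrast
this removes the pair-mean direction).  Patterns related additively
(`b = a + c·1`) or multiplicatively (`b = k·a`) then yield exactly zero
distance; in the matrix-level routine such degenerate pairs contribute
zero rather than raising, since that zero is the analysis's intended
output (the scalar `cv_distance` raises instead, because a single
degenerate pair there usually indicates a data problem).

## Regression RSA

Squared Euclidean distances add over orthogonal axes, so squared
reference distances decompose exactly: for a pair with eccentricities
`(e_i, e_j)`, the eccentricity predictor is `(e_i − e_j)²` (the minimum
squared distance within the pair's eccentricity group, attained with no
direction change) and the direction predictor is the remainder.  Both
are duplicated over within- and across-viewpoint pair sets with separate
constants (6 predictors over 276 pairs; 3 over 66 pairs in the
single-viewpoint form).  Measured distances are sign-preservingly
squared before ordinary least squares, and coefficients are
sign-preservingly square-rooted back, so equal eccentricity and
direction estimates indicate an unwarped encoding and the partition's
self-check — regressing the squared reference matrix on itself — returns
eccentricity 1, direction 1, constant 0 with zero residual.  Numerics:
that identity holds to 1e−10 for the OLS coefficients and residuals; the
square-root back-transform maps ~1e−17 coefficient noise on the zero
constant to ~1e−8, so the back-transformed constant is checked at 1e−6.

## Model evaluation and inference

RDM fit is the Pearson correlation over strict lower-triangle vectors,
Fisher-Z transformed (`atanh`, clipping |r| at 1 − 1e−12 with a logged
warning) for group statistics and reverse-transformed only for
reporting.  Noise ceilings use between-participant reproducibility:
lower bound from leave-one-participant-out prediction by the mean of the
others, upper bound from in-sample prediction by the grand mean.

Grid-search fitting evaluates every parameter cell's prediction — built
from each participant's own stimuli and unit sample — against each
participant's data; per leave-one-participant-out split, the cell
maximizing the mean training Z is selected (ties break to the first cell
in row-major order) and evaluated on the left-out participant.  Group
inference uses one-sample and paired T tests on Fisher-Z values, with an
explicit degenerate path (zero-variance samples).  The 2×2
repeated-measures ANOVA on RSA parameters (metric × viewpoint) is
computed through its exact paired-contrast equivalents.

Prediction-side Monte-Carlo error matters in recovery experiments: at
high averaging strength the deviation signal in a predicted RDM shrinks
by `1 − p` while unit-sampling jitter does not, so 1000-unit predictions
systematically handicap the generating family relative to intrinsically
smooth broad-width exemplar predictions.  Recovery fits therefore build
predictions from 5000 units (model defaults are unchanged).

Default parameter grids: ramp `o ∈ {0, 0.5, 1, 2}·r`,
`s ∈ {0.1, 0.5, 1, 4}·r`; exemplar `w ∈ {0.25, 0.5, 1, 2, 4}·r`,
`d ∈ {0.1, 0.5, 1, 3}`; both with `p ∈ {0, 0.25, 0.5, 0.75, 0.9, 1}`;
Gabor bank weights in `{0, 0.25, 0.5, 1}` (all-zero excluded) with
`p_hemi, p_global ∈ {0, 0.5, 0.9, 1}`.

## Synthetic data

All generators are pure functions of their seeds.

**Images.**  Stand-ins for rendered face stimuli: each identity's image
is a participant-specific smooth base field plus D coordinate-weighted
band-limited random fields, so pixel content varies smoothly with
face-space position; the right viewpoint is the exact horizontal mirror
of the left; all 24 images are normalized to one mean intensity and RMS
contrast.  The coordinate-dependent fields are band-limited at a finer
scale (σ = resolution/24) than the base (σ = resolution/6): distinctive
faces thereby carry more fine structure, so mean contrast energy grows
with eccentricity at matched RMS contrast — the property that lets the
Gabor model predict increasing activation with distinctiveness, as it
does for contrast-equated face photographs.  These images carry no
actual facial features; conclusions about real face photographs are
outside what passing tests can show.

**Runs.**  Voxel patterns are non-negative weighted averages of the
ground-truth model's unit responses over a random subset of `n_pool`
units per voxel (uniform [0, 1] weights).  Pool size controls how
strongly the measurement itself stretches the population-mean dimension:
with dense pooling over all n units the deviation-to-mean ratio of a
voxel is `sqrt(1/(3n))` (~2% at n = 1000), every voxel is essentially
the population mean, and the generating parameters are unidentifiable
from the data.  The default `n_pool = 10` keeps the generative premise
(voxels average random subsets of neurons, non-negatively) while leaving
the generating model recoverable.  Even so, pooling adds real averaging
on top of the model's own `p`: fitted `p` lands one grid step above the
generating value, and the noiseless `cv_rdm` equals the Euclidean RDM of
the pooled voxel patterns exactly (the oracle the tests assert) rather
than the unit-level model RDM, with which it agrees in rank order only
approximately (Spearman ≈ 0.8 at V = 50).  Run noise and residual time
courses share an AR(1) spatially correlated covariance (ρ = 0.3);
`noise` scales the noise SD relative to the condition-demeaned pattern
SD.  Defaults: 16 runs, 100 voxels, 120 residual time points.

**Judgments.**  The pair-of-pairs task enumerates all 2145 pairings of
the 66 face pairs per repeat; the first pair is chosen as more
dissimilar with probability `logistic((d1 − d2)/τ)`.  At `τ = 0` the
choice is the deterministic argmax with exact ties split at chance, so
the percent-choice matrix is an exact monotone transform of the true
distances.  The logistic link is the simplest mechanism consistent with
a percent-choice dissimilarity matrix.

**Trial sequences.**  First-order counterbalanced cyclic sequences are
Eulerian circuits (Hierholzer, seed-shuffled edge order) over the
complete transition multigraph with one extra self-transition per face:
156 trials for 12 faces, every ordered face pair exactly once, every
self-transition exactly twice.  Viewpoints are then randomized under
rejection sampling until no ordered 24-condition transition occurs more
than once.

**Recovery study conditions** (chosen once): family/cell recovery uses
ramp truth `(o = 0.5, s = 0.5, p = 0.5)` with 8 participants at
`noise = 1`; the averaging-on-versus-off comparison generates with
`p = 0.75`.  At generating `p ≥ 0.75` the ramp and exemplar families
become RDM-degenerate — both reduce toward population-mean structure, so
RDM-level fits no longer separate them (activation profiles do; they
predict opposite eccentricity trends).  This mirrors the intrinsic
ambiguity that motivates adjudicating models on activation profiles as
well as distance matrices.

## Fold-dependence calibration

Leave-one-participant-out generalization estimates share training data
across splits, so fold-level T tests are not strictly independent.  The
calibration simulation generates participant distance vectors as
`s1·M1 + s2·M2 + noise` for two arbitrary models, each with a small set
of candidate variants, applies the same split/select/evaluate procedure,
and measures rejection rates of each model against zero (one-tailed) and
of the zero-difference test (paired, two-tailed).

Calibration depends strongly on how distinct the candidate variants
are.  With variants representing a fine grid near the optimum (pairwise
correlation ≈ 0.99, the regime a converged grid search operates in, and
the default `variant_scale = 0.1`), the zero-signal null rejection rate
of the difference test sits at the nominal 5%.  With strongly distinct
candidates — or the package's full default grids applied to pure-noise
data — winner selection couples the folds and the same null rejects up
to ~19%.  Matched nonzero signals (`s1 = s2 > 0`) are not null cases in
this construction: finite variant sets span the mixed signal unequally,
creating true per-simulation performance differences.  Practical
implication: fold-level difference tests are trustworthy near a
converged fit, but should not be taken at face value when candidate
models are highly distinct and signal is absent.

## Problem sizes and numerical choices

Simulated cohorts use 8–10 participants, 16 runs, 100 voxels and
1000-unit model populations (5000 for grid-search predictions);
calibration suites use 1000 simulations.  Covariance shrinkage adds a
1e−10-scaled diagonal jitter so degenerate residuals stay invertible;
discriminant folds with exactly zero training contrast contribute zero
in matrix routines; Fisher-Z clips |r| at 1 − 1e−12 with a logged
warning; grid-search ties break to the first cell in row-major order.

## Known limitations

The synthetic images are smooth random fields, not faces; image-model
conclusions transfer to real stimuli only insofar as the
smoothness-with-position and contrast-with-eccentricity properties do.
No hemodynamic convolution or GLM estimation is simulated — run-wise
pattern estimates are the entry point.  The voxel measurement model is
subset-pooling with white-plus-AR(1) noise; real fMRI noise spectra and
voxel counts differ.  Family recovery at the RDM level degrades by
construction as averaging strength grows; this is a property of the
models, not of the fitting code.
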