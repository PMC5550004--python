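# facespace

Simulation and analysis pipeline for adjudicating between face-coding
models with representational similarity analysis (RSA).

In norm-based face-space accounts, individual faces are vectors: the
direction from the origin (the average face) carries identity and the
eccentricity carries distinctiveness.  fMRI response patterns to
individual faces constrain how such a space is encoded — but only
through the measurement: a voxel averages many neurons, which stretches
the population-mean dimension of the representational space.  This
package implements the full model-comparison workflow for that problem:

- **Stimulus design** — a 12-face polar grid (3 eccentricities × 4
  directions × 2 mirror viewpoints) on a randomly oriented 2D slice
  through a D-dimensional reference space, plus first-order
  counterbalanced (De Bruijn) trial sequences and the pair-of-pairs
  perceptual judgment task.
- **Encoding models** — sigmoidal-ramp tuning
  (`y = 1/(1+exp((−x+o)/s))` along random preferred directions),
  Gaussian and inverted-Gaussian exemplar tuning, a 5-bank Gabor filter
  model on stimulus images, and a pixelwise-correlation control.  Every
  model predicts a representational distance matrix (RDM) and a
  regional-mean activation profile.
- **Measurement model** — population averaging
  `y_final = (y_raw − ȳ)(1 − p) + ȳ`, translating each model unit
  toward the population mean by strength `p` (for the Gabor model, a
  hemifield-specific pool followed by a global pool).
- **Distance estimation** — cross-validated discriminant (crossnobis)
  distances from run-wise pattern estimates with shrinkage noise
  covariance: unbiased (zero-centered) under the null, equal to the
  squared Mahalanobis distance in the same-data full-covariance limit,
  with a mean-removal control variant.
- **Inference** — multiple-regression RSA on squared distances
  (eccentricity/direction × viewpoint partition), Fisher-Z correlations,
  noise ceilings, grid-search model fitting with
  leave-one-participant-out cross-validation, group T tests / 2×2
  repeated-measures ANOVA, and a false-positive calibration of the
  fold-level tests.
- **Synthetic data** — seeded generators for participants (private
  slice orientations and stimulus images), fMRI-like run data from any
  ground-truth model via non-negative voxel pooling, and perceptual
  choices, so the whole pipeline runs end to end without external data.

See `docs/methods.md` for the models, parameters and design choices in
detail.

## Worked example

```python
import numpy as np
import facespace as fs

# Reference space: 12-face polar grid on a random 2D slice of a 50-D space
basis = fs.sample_slice(50, np.random.default_rng(0))
grid = fs.build_polar_grid(1.0, basis)
reference = fs.euclidean_rdm(grid.coords_2d, labels=grid.face_labels)

# Regression RSA self-check: the squared reference matrix regressed on
# its own eccentricity/direction partition
design = fs.build_rsa_predictors(grid, viewpoints=False)
print(fs.fit_rsa_regression(reference, design).estimates.round(6).to_string())

# Simulate one participant's cortical data from a ramp model with strong
# measurement averaging, and ask how well the model explains it
model = fs.RampModel(fs.RampParams(o=1.0, s=1.0, p=0.9), rng=1)
participant = fs.SyntheticParticipant(seed=0, basis=basis, grid=grid,
                                      images=np.zeros((24, 32, 32)))
runs = fs.simulate_runs(participant, model, seed=2)
data_rdm = fs.cv_rdm(runs)
r, z = fs.rdm_correlation(fs.model_rdm(model, grid), data_rdm)
print(f"model vs simulated cortical RDM: r = {r:.3f} (Z = {z:.3f})")
```

Output:

```
eccentricity    1.0
direction       1.0
constant        0.0
model vs simulated cortical RDM: r = 0.948 (Z = 1.809)
```

The `[1, 1, 0]` estimates confirm that the eccentricity and direction
predictors partition the squared reference distances completely (equal
estimates on real data would indicate an unwarped cortical encoding;
larger eccentricity than direction estimates indicate the radial axis is
over-represented).  The correlation line shows the generating model
recovering its own simulated data through the crossnobis estimator —
`r` is high but below 1 because the voxel measurement adds noise and its
own mean-dimension stretch.

A thin CLI mirrors the library (`facespace simulate / fit / rsa-regress
/ ceiling / compare / calibrate`); `facespace simulate --seed 1 --outdir
study/` writes per-participant directories with the grid, stimulus
images, run-wise patterns, judgment matrices and trial sequences as
plain text/PNG.

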