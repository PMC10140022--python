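# Methods

## The study design

The package reproduces, on synthetic data, a multi-cohort brain-age
generalizability analysis.  Identical 3D CNNs are trained per cohort
under stratified nested cross-validation; each cohort's best fold model
is evaluated on the full other cohorts; each cohort's apparent
performance is decomposed into confounder-unique, prediction-unique and
shared parts; and smoothed-gradient attention maps, intersected with a
labelled atlas, rank the regions each model relies on.  The scientific
question the synthetic study answers is directional: does training on a
cohort whose acquisition-site structure is entangled with age produce a
model that generalizes worse, and whose performance is largely shared
with its confounders?

## Synthetic cohorts

The generator emulates the *product* of voxel-based morphometry rather
than raw T1 images (segmentation/registration are upstream concerns):
two channels (GM, WM) of densities in [0, 1] on a fixed lattice, zero
outside an ellipsoidal brain mask, smooth at a configurable FWHM.

Per subject, voxel values inside ROI *r* are
`clip(baseline_r + slope_r (age − age_ref) + site_offset + sex_effect · male + ε, 0, 1)`
with ε ~ N(0, noise_sd) per voxel; unlabelled brain tissue follows the
channel baseline with the same site/sex/noise terms.  Choices worth
noting:

* **age_ref** is the cohort age-range midpoint, so baselines are the
  density of a mid-cohort subject.
* **WM slopes default to the negated GM slopes**, giving the model a
  genuine two-channel structure (opposing maturation trends).
* **Clipping precedes smoothing**, and smoothing is mask-normalized
  (smoothed image divided by the smoothed mask inside the mask), so
  smoothed values are convex combinations of in-mask values: the
  nonnegativity, upper-bound and zero-outside-mask invariants hold
  exactly, not approximately.
* **Site–age confounding dial** c ∈ [0, 1]: each subject's within-cohort
  age rank maps to a "block" site; with probability c the subject gets
  its block site, otherwise a uniform site.  c = 0 gives independence,
  c = 1 makes site a deterministic function of the age quantile, and the
  age-on-site η² rises monotonically in between.
* **Total brain volume** is recomputed from the rendered image
  (mask-integrated mean channel density × voxel volume) so the phenotype
  table is always consistent with the volumes; it consequently inherits
  the sex and site effects, which is exactly what makes it a usable
  confounder.
* Per-subject random streams are spawned from the cohort seed, so a
  cohort is bit-reproducible and stable under subject reordering.

What the phantoms do **not** model: scanner artifacts beyond additive
site offsets, nonlinear or spatially diffuse age effects, registration
error, partial-volume structure at tissue boundaries.  Passing tests on
phantoms therefore demonstrate the pipeline's correctness and its
directional behaviour under controlled confounding — not clinical-grade
performance on real MRI.

## Default study conditions

The two-cohort design (`pipeline.default_study_config`): n = 120
subjects per cohort, 16³ grids, ages uniform on [8, 18], two sites with
additive offsets (0, 0.04), sex effect 0.015, voxel noise sd 0.03,
smoothing FWHM 2 voxels.  Both cohorts share one 5-ROI atlas; cohort A
has dominant GM slope −0.020/yr in ROI 1, cohort B −0.020/yr in ROI 3,
with weaker shared slopes elsewhere, so the age signal transfers across
cohorts while each model can prefer its own regions.  Cohort A's
confounding dial is 0, cohort B's 0.9.  Training uses 3 outer folds,
batch 48, up to 60 epochs with patience 20 — the desk-scale net can
plateau for 10+ epochs before its loss starts falling, so the patience
must comfortably exceed the plateau.  The seeded replicates of the
clean-vs-confounded comparison use n = 90, 2 folds, batch 24 (keeping
optimizer updates per epoch comparable at the smaller split size), up
to 40 epochs with patience 15.  These sizes are the
package's desk-scale choice: the full-size reference configuration
(128³ inputs, 5 blocks, ~11k subjects, 1000 epochs / patience 75) is
expressible in the same configs but is a GPU-scale undertaking; every
property the study tests is scale-free and is asserted at the small
size.

## The CNN and its training

Blocks of conv(3³, stride 1, same padding) → ReLU → conv(3³) →
batch-norm → ReLU → max-pool(2³); width doubles per block from the base
width; one fully connected layer maps the flattened last block to a
single output.  Heads: ReLU output with MSE loss (regression), sigmoid
with binary cross-entropy (classification).  An L2 penalty
λ Σw² (λ = 10⁻³) applies to convolutional and fully connected kernels
only — not biases or batch-norm affine terms.  Adam uses lr 10⁻³,
β = (0.9, 0.999), ε = 10⁻⁸; batches are reshuffled each epoch.

Numerical/engineering decisions:

* Implemented in NumPy (im2col convolutions over BLAS matmuls) with
  hand-derived backward passes; the input gradient — the saliency
  engine — is verified against central finite differences, with probes
  that straddle a ReLU/max-pool kink excluded since the finite-difference
  oracle itself is invalid there.
* Inference preserves float64 inputs end to end, which is what makes
  10⁻³-tight gradient verification possible; training runs in float32.
* "No improvement" for early stopping means strictly lower validation
  head loss (MSE/BCE without the L2 term, inference mode) at full float
  precision; training halts `patience` epochs after the best epoch, and
  the checkpointed best weights are restored.
* Batch-norm uses batch statistics in training and running statistics
  (momentum 0.1) at inference; backprop through frozen statistics is the
  affine case.
* The regression head's output bias is initialized at the training-target
  mean: with a zero start the output ReLU can begin in its dead zone
  (all pre-activations negative ⇒ zero gradient forever).  Convolution
  biases are included; before batch-norm they are cosmetically redundant.
* Weight init is fan-in-scaled Gaussian from the run seed; two runs with
  identical data and seeds produce identical histories.

## Evaluation

Outer k-fold test sets partition each cohort; stratification uses sex ×
age-quantile bins (15 by default), with bins merged toward coarser
stratification whenever a stratum would fall below k (and, for the inner
90/10 split, degrading to sex-only or unstratified if necessary).
Quantile bins are computed on the cohort being split; boundary ties go
to the lower bin.

Prediction R² (q²) uses the evaluation-set mean as baseline — the
convention under which strongly negative cross-cohort values arise
naturally when a model's predictions are worse than the evaluation
cohort's own mean; the training-mean variant is available via
`baseline_mean`.  The classification operating point maximizes
2·sens·spec/(sens+spec) over midpoints of consecutive sorted unique
validation scores plus sentinels beyond both ends, and is frozen before
touching test data.  Permutation tests permute labels at the prediction
level (no retraining; 1000 permutations by default) and report
p = (1 + #{perm ≥ observed})/(1 + n_perm); inputs are first put in a
canonical joint order so the p-value is invariant to how the pairs were
supplied.  "Best" fold model means highest test-set r with ties broken
by lower MAE (an explicit package convention).

## Confound decomposition

For target y, predictions ŷ and confounder matrix C (sex; one-hot site
with the lexicographically first level dropped; total brain volume; plus
age for non-age targets), three auxiliary models are fitted — y~C, y~ŷ,
y~[C, ŷ] — linear for regression targets, logistic for binary ones.
Their out-of-fold R² (or D² = 1 − deviance/null deviance, probabilities
clipped to [10⁻⁶, 1−10⁻⁶]) on the same outer test folds as the main
pipeline, with fits on each fold's complement, yield
ΔPred = full − conf, ΔConf = full − pred, Shared = pred + conf − full.
The three components sum to the joint fit identically, so negative
cross-validated components are reported as computed, never floored.

At desk scale the per-fold partitions are noisy (test folds of ~40
subjects; pooled out-of-fold predictions mix fold models with slightly
different calibrations, which can push a single fold's R² strongly
negative).  The quantity the study conclusions rest on — the confounded
share (Shared + ΔConf) — is stable across folds and replicates.  Under
fully independent y, ŷ, C the cross-validated components are not exactly
zero-mean (fitting k parameters costs ~k/n_test of R²); the tolerated
calibration band is ±0.02 at n = 400.

## Saliency

SmoothGrad: mean over n noisy samples of |∂output/∂input| at
x + N(0, σ²), σ = noise_fraction × (max(x) − min(x)) per input volume;
defaults 20 % noise and 50 samples follow the method's original
recommendation (desk runs use 20 samples).  GM/WM channels are reduced
by their mean so ROI scores are channel-balanced.  Aggregation: voxel
mean within each fold's test subjects, max-normalization of each fold
map to 1, voxel mean across folds.  The ROI score is the **mean**
attention per in-ROI voxel — a sum would rank large regions above small
high-attention ones — with ties broken by ascending ROI id.

## Known limitations

* The phantom age effect is linear in ellipsoidal ROIs; it is a test
  harness for the pipeline, not a model of neurodevelopment.
* Permutation significance is computed at the prediction level;
  retraining per permutation is computationally excluded.
* The NumPy CNN is single-threaded-CPU oriented; at 128³ × 5 blocks it
  is functional but impractically slow compared to GPU frameworks.
* With strong planted signal and low noise, desk-scale cross-cohort
  correlations are much higher than anything achievable on real MRI;
  only directions and orderings, not magnitudes, are meaningful.
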