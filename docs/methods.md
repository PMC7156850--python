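# Methods

This note documents the models, conventions and numerical choices behind
`segqc`, and what its synthetic experiments do and do not demonstrate.

## Data model and conventions

All analyses operate on per-subject 3D volumes sharing one grid: a binary
brain mask, per-region binary ground-truth and predicted labels, and
per-region foreground-probability or uncertainty maps in [0, 1]. The three
hierarchical tumor regions WT ⊇ TC ⊇ ET are combined from
sub-compartment-coded label volumes (default codes 1 = NCR/NET, 2 = ED,
4 = ET, configurable); the nesting is guaranteed for combined ground truth
but never enforced or repaired for predictions, since independent
per-region foreground heads can break it — each region is evaluated
independently. Masks are stored over the full grid and every metric takes
the evaluation mask (normally the brain mask) as an explicit argument, so
brain-mask restriction is a visible, testable parameter rather than a
preprocessing step. Coordinates are 0-based voxel indices; physical spacing
(mm) enters only distance transforms and shape features.

## Uncertainty and confidence

* Normalized entropy H(p) = −[p log p + (1−p) log(1−p)] / log 2 maps a
  foreground probability to [0, 1]. Probabilities are clamped to
  [1e−12, 1−1e−12] before the logarithm; at and beyond the clamp the
  0·log 0 = 0 convention is applied exactly, so H(0) = H(1) = 0.
* Sample stacks (Monte-Carlo dropout draws, ensemble members) are combined
  by the voxel-wise arithmetic mean; the uncertainty is the entropy of the
  mean, not the variance of the samples.
* Uncertainty-native maps (variance volumes, auxiliary error
  probabilities) are min-max normalized with **cohort-global** extrema —
  the cohort context is a required argument because per-subject
  normalization would destroy cross-subject comparability. A zero-range
  cohort maps to all zeros. Which cohort supplies the extrema is the
  caller's choice; the ambiguity (training vs evaluation subjects) is
  deliberate and documented at the call site.
* For calibration analyses, uncertainty-native methods are translated to a
  foreground-probability surrogate y(1 − 0.5q) + (1 − y)0.5q with the
  predicted label y, which maps predicted-foreground voxels to [0.5, 1]
  and background to [0, 0.5].

## Calibration

The confidence axis is the foreground probability (calibration-curve
style): bin m of M = 10 equal-width bins (upper bin right-closed) carries
the mean predicted probability c_m and the empirical foreground fraction
a_m of its voxels; c_m is the in-bin mean, not the bin midpoint. ECE is the
count-weighted, ACE the unweighted, mean absolute gap |c_m − a_m| over
occupied bins; empty bins are flagged and contribute nothing.

Subject-level calibration is classified by a **folded** signed error: bins
at or above 0.5 contribute c_m − a_m, bins below 0.5 contribute a_m − c_m
(the predicted class flips at 0.5, and the predicted-class confidence error
of a background-predicted voxel is (1−c) − (1−a)). Folding is essential:
the unfolded signed sum cancels for temperature-type miscalibration, which
sharpens both tails symmetrically, and would call such subjects well
calibrated. The default classification tolerance is 0.01; the synthetic
calibration experiments pass 0.001 explicitly because the tumor phantoms'
certain background dilutes the count-weighted signed error roughly
tenfold relative to the miscalibration signal (the τ = 1 noise floor in
those cohorts is ≈ 2·10⁻⁴, so 10⁻³ still separates cleanly).

Dataset-level diagrams pool the brain voxels of all (test) subjects.
Mean-subject ECE excludes subjects with an empty brain mask with a warning.

## Error localization

The error map is pred XOR gt. U-E is the Dice overlap between E and
U = {q ≥ t} with a **closed** threshold, so the top grid value 0.95 is
attainable at q = 0.95. Conventions: U-E = 1 when both sets are empty (a
perfect segmentation with no thresholded uncertainty is perfect
localization) and 0 when exactly one is empty. The operating threshold is
selected per uncertainty method by sweeping t ∈ {0.05, …, 0.95} (19 values)
and maximizing the *mean subject* U-E on the validation split (subject-level
averaging for consistency with the rest of the subject-level reporting);
ties resolve to the lower threshold. The frozen threshold is reused on the
test split and by the automatic feature extraction. PR-AUC treats q as a
score for "voxel is misclassified" (average-precision step integration) and
is undefined (NaN) when no error voxel lies inside the mask.

## Aggregation and failure detection

* Mean aggregation: −mean(q) over the brain mask, so larger = predicted
  better.
* Prior-knowledge features: the boundary band is the predicted surface
  voxels plus their face-connected inner and outer shells (dilation by one
  minus erosion by two; a 3-voxel band). The three weightings are (w1) q
  zeroed on the band, (w2) the band-masked q multiplied by the unsigned
  Euclidean distance (mm) to the predicted surface, and (w3) q divided by
  the predicted volume in voxels; each is reduced by mean (over the brain
  mask), sum, and logsum = log(1 + sum) — the 1 keeps the reducer finite on
  empty support. The w2 features are named `distance_weighted_masked_*`:
  masking changes them only marginally (the distance weight is < 1.5 mm on
  the band) but matches the feature's established name. An empty
  prediction leaves w2/w3 undefined; they are recorded as NaN and imputed
  (0 plus a missingness-indicator column) inside the regressor.
* Automatic features describe the thresholded region {q ≥ t}: shape
  (voxel and mesh volume, mesh surface area, sphericity π^⅓(6V)^⅔/A,
  surface-to-volume ratio, PCA axis lengths, connected-component count),
  first-order statistics of q inside the region, and gray-level run-length
  features (SRE, LRE, GLN(N), RLN(N), RP, LGLRE, HGLRE, run variance and
  entropy) after fixed-bin discretization with width 0.05, averaged over
  the three axis-aligned run directions (arbitrary ±1 offset directions
  are supported; three directions keep the default panel fast and
  deterministic). The panel (~33 features) is configurable and is not a
  clone of any external package's list; the headline features — sphericity
  and run-length non-uniformity RLN = Σ_j(Σ_i R(i,j))²/N_runs — are always
  present. Surface meshes come from marching cubes after mild Gaussian
  smoothing (σ = 0.5 voxel, floored at 0.51 inside the mask): raw binary
  marching cubes overestimates curved surface areas by up to ~7%
  (staircase facets), and this choice restores the analytic sphere limit
  while keeping flat-faced solids near their closed forms and isolated
  voxels meshable.
* The Dice regressor is a scikit-learn-style estimator wrapping a
  500-tree random forest (fixed seed, all features per split, OOB score
  recorded when n ≥ 15); predictions are clipped to [0, 1]; prediction
  refuses feature tables whose columns mismatch training. Feature
  importances are compared across models by summing dense ranks
  (1 = most important, ties alphabetical).
* Failure = positive class throughout. Quality is binarized at a
  per-region Dice cutoff that must be supplied by configuration — there is
  no hidden default, because the appropriate cutoff is an inter-rater
  agreement level external to any given dataset; the synthetic experiments
  use 0.85 (a WT-like inter-rater Dice). AUC follows the probabilistic
  definition P(score_failed < score_success) + ½P(tie). The Youden
  operating point maximizes J = sensitivity − (1 − specificity) with ties
  toward higher specificity; the accuracy reported there is apparent
  accuracy (same cohort as the ROC).

## Synthetic cohort generator

The generator is the package's test bed and defines its study conditions.
Each subject is a deformed-sphere phantom: nested level sets of one shared
radial deformation field (so ET ⊆ TC ⊆ WT holds by construction) inside an
ellipsoidal brain. Defaults: 96×96×48 grid at 1 mm isotropic, brain
semi-axes 0.45 × grid extent with ±8% per-subject variation, WT radius
8-13 mm, TC/ET nested fractions 0.55-0.75 / 0.45-0.70, deformation
amplitude 0.12 at 12 mm correlation length, and a 35/10/55
train/validation/test split (the proportions of a 100/25/160-style study).

The simulated predictor blurs the ground truth (σ = 1.2 mm) into a latent
probability p\*, optionally adds smooth logit noise (amplitude drawn
per subject from U(0.25, 0.65) at 8 mm scale — subjects genuinely differ in
difficulty, which spreads both Dice and boundary-uncertainty mass), and
reports p̂ = sigmoid(logit(p\*)/τ). The temperature τ is the calibration
dial: it leaves the segmentation p̂ ≥ 0.5 unchanged while making the
probabilities over- (τ < 1) or underconfident (τ > 1). Two modes:

* **calibration** — the ground truth is redrawn voxel-wise as
  Bernoulli(p\*), making p\* perfectly calibrated by construction; τ is
  then the only miscalibration source. The redrawn labels are speckled and
  anatomically implausible, and the per-region redraws are independent (the
  label hierarchy may break) — irrelevant for calibration metrics, which is
  all this mode is used for.
* **morphology** — ground truth stays the clean phantom; noise perturbs
  the prediction. Used for localization, aggregation and failure detection.

Failure modes (with per-cohort mix fractions):

* `remote_blob` emulates multifocal spurious structures at least 10 mm
  from the tumor: a confidently predicted focus (p̂ = 0.995, hard edge) —
  the false positive that lowers the Dice — with a small fraction (4%) of
  ambivalent interior voxels (p̂ = 0.5), and an adjacent *unpredicted*
  satellite focus over which the model hesitates at p̂ = 0.04. This
  anatomy is what makes the three aggregation families behave as they do
  in practice: the structure's total entropy is small relative to the
  between-subject spread of boundary uncertainty (the brain-wide mean
  barely moves), the ambivalent voxels leave a high-entropy, shape-visible
  trace for the automatic features, and the satellite's mild uncertainty
  lies far from every predicted boundary — precisely the signal the
  distance-weighted masked weighting amplifies and the mean dilutes away.
  Blobs shrink and satellites relocate automatically when the brain
  geometry leaves no room, and the injection fails loudly when no feasible
  location exists.
* `missed_core` suppresses p̂ inside an axial fraction (default half) of a
  ground-truth subregion (default TC), with a soft edge.
* `boundary_jitter` shifts the 0.5 decision level by a smooth field,
  perturbing the predicted surface without touching the probabilities.

The cohort (including split and failure-mode assignment by largest-
remainder allocation) is a pure function of the spec and master seed, via
`numpy.random.SeedSequence` spawning.

## What the synthetic experiments show — and what they do not

The generator emulates the *structural* features the analyses depend on:
nested regions in a brain mask, boundary-localized uncertainty for good
segmentations, controllable per-subject calibration, and failure modes
that decouple mean uncertainty from quality. It does not simulate MR
intensities, real lesion morphology, inter-rater ambiguity, or the error
correlations of any particular network family. Passing tests therefore
demonstrate that the metrics and pipeline are implemented correctly and
that the qualitative phenomena (pooled calibration masking subject-level
miscalibration; mean aggregation failing on remote high-confidence errors;
distance-weighted and shape/texture aggregates recovering them) follow
from the stated mechanisms — not that any particular uncertainty method
performs well on clinical data.

## Problem sizes and experiment configurations

Chosen as the package's standing desk-scale conditions:

* Calibration experiments: 144×144×72 grid (≈ 5.7·10⁵ brain voxels),
  WT radius 14-18 mm, no brain-size jitter, M = 10 bins, classification
  tolerance 10⁻³.
* Dataset-vs-subject contrast: 20 subjects, alternating τ = 2 / τ = 0.5.
* Localization: 20-subject boundary-jitter cohort on a 64×64×32 grid
  (WT radius 5-8.5 mm), shuffled-uncertainty control with a fixed seed.
* Failure detection: 100-subject morphology cohorts at the default
  96×96×48 grid, 30% remote-blob corruption, Dice cutoff 0.85, WT region;
  regressors fitted on the 35-subject training split and scored on the
  55-subject test split; 10 master seeds.

## Known limitations

* The subject-calibration classification rule (folded signed error with a
  tolerance) is a documented stand-in; no canonical rule exists for the
  reported under-/overconfident shares, so those shares are not asserted.
* The U-E-optimal threshold on entropy-type uncertainty in these phantoms
  is consistently the top grid value (0.95), because entropy peaks exactly
  where boundary errors concentrate; methods with flatter uncertainty
  profiles would select interior thresholds.
* Run-length features default to axis-aligned directions; the 13-direction
  panel of radiomics tooling is available but slower.
* The automatic panel is deterministic and self-contained; numerical
  equality with any specific external radiomics package is out of scope.
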