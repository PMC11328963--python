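# Methods

## Problem setting

Interactive segmentation tools train a model in a feedback loop: the model
segments each training image, the user paints corrections — green strokes
on false-positive pixels, red strokes on false-negative pixels — and the
corrections feed back into training. Because the corrected segmentation
(prediction minus green plus red) can be *assumed accurate*, each training
image yields confusion counts and therefore precision, recall, dice,
accuracy and a signed area error, with no separate manually annotated
validation set. `corrseg` implements that bookkeeping, the derived
stopping criterion, per-region shape measurement, pixel→cm² scale
calibration and pooled validation statistics as a reusable library with a
thin CLI.

## Corrective metrics and their assumptions

All training-time metrics are computed over **all pixels** of an image
against the corrected mask. This encodes the assumption that the user's
correction is exhaustive; where it is not, every metric is biased
optimistically (unstroked errors silently count as correct). The package
surfaces rather than corrects this: each `MetricRecord` carries the
annotated-pixel fraction as a diagnostic, and the synthetic tests
demonstrate the bias direction (with 50% correction completeness the
corrective dice is ≥ the true dice on every tested scene).

Degenerate-count conventions: when an image has neither predicted nor
reference foreground, precision = recall = dice = 1. A model that
correctly reports "no subject present" is thereby not penalized —
pixel-overlap metrics are otherwise disproportionately harsh on images
with little or no foreground. Area error is predicted minus corrected
area, so positive = over-prediction.

## Stopping rule

`stopping_index` returns the first index at which the trailing unweighted
mean of a metric over `window_n` images **strictly exceeds** the
threshold. Defaults: dice, window 10, threshold 0.95. The comparison is
strict so that a window sitting exactly at the threshold (e.g. nine
perfect images plus one at dice 0.5 averaging exactly 0.95) does not yet
stop training; on the canonical constructed series (ten images at 0.5,
then perfect) the rule fires at index 19, the first window holding ten
perfect scores. The threshold is constrained to (0, 1]; with metrics
bounded in [0, 1] a vanishingly small threshold degenerates to firing as
soon as the window fills.

## Region measurement

Connected components are labelled under 8-connectivity by default, so
diagonally adjacent lobes of one organism count as a single individual
(4-connectivity is available). Labels are renumbered into row-major
first-pixel order so labelling is deterministic.

Per region:

- **area** — pixel count; region areas always sum exactly to the mask
  foreground area.
- **centroid** — mean pixel coordinate (sub-pixel); exported x = column,
  y = row.
- **equivalent diameter** — `2·√(area/π)`, the diameter of the
  equal-area circle ("diameter" of an irregular blob is otherwise
  ill-defined).
- **eccentricity** — from the eigenvalues λ₁ ≥ λ₂ of the second-central-
  moment matrix: `e = √(1 − λ₂/λ₁)`; 0 for a circle, → 1 for a line.
  Convention: a single pixel has e = 0; one-pixel-wide lines compute to 1
  and are capped to the largest double below 1 so the e < 1 invariant
  holds. Rasterization keeps recovered values within 0.02 of the analytic
  `√(1 − b²/a²)` for ellipses with semi-major axis ≥ 20 px at any
  rotation (verified at 0°, 30°, 45°).
- **perimeter** — length of a Moore (8-neighbour) trace of the outer
  boundary through pixel centres. Raw chain-code length (orthogonal steps
  1, diagonal √2) overestimates smooth outlines by ≈ 5–6% — a digitized
  straight edge at angle θ measures `cos θ + (√2−1)·sin θ` per unit
  length, averaging 1.055 over orientations — so steps are weighted with
  the corner-corrected Vossepoel–Smeulders coefficients (0.980 per
  orthogonal step, 1.406 per diagonal step, −0.091 per direction change),
  which bring rasterized disks of radius ≥ 20 px within ~1% of 2πr.
  Interior holes do not contribute to the perimeter. An isolated pixel
  has perimeter 0.

## Scale calibration

ROV frames are calibrated per frame from a pair of laser dots a known
5 cm apart: after discarding regions smaller than `min_region_px`
(default 3 px, a noise guard), **exactly two** surviving regions yield
`px_per_cm = centroid distance / 5`. Any other count — one laser out of
frame, or reflections splitting into extra regions — excludes the frame;
exclusion is a carried value with a reason, not an exception, and
excluded frames keep their rows in all outputs. Dot positions are
sub-pixel region centroids (robust to dot size and shape; the alternative
of brightest-pixel localization is not available from a binary mask).
Static time-lapse imagery is scaled once from a fixed reference length,
default 0.43 cm (mean coral-branch width), with the ±0.09 cm spread
optionally propagated as a relative error field. Area conversion is
`area_px · (1/px_per_cm)²` and applies identically to signed area errors.
A single factor scales the whole frame; no perspective or terrain
correction is attempted.

## Validation statistics

Pooled metrics are micro-averaged: confusion counts are summed over all
images and the formulas applied once — equivalent to overlaying every
annotation as one mega-image, and different from the mean of per-image
metrics whenever image difficulty correlates with foreground size.
Per-image area differences are summarized as mean absolute difference
± sample sd (n−1) in cm² and as a percentage of the manual area (images
with zero manual area are dropped from the percentage with a logged
count); the signed mean is reported alongside because "average
difference" is ambiguous. Area agreement fits OLS of predicted on
corrected/true areas (scipy.stats.linregress); the intercept reads as a
systematic offset when the slope is near 1, and the mean signed error is
reported as the model-free alternative. Success classification requires
all four of P ≥ 0.71, R ≥ 0.75, D ≥ 0.74, A ≥ 0.76 (inclusive,
configurable).

## Synthetic data generator

The generator emulates only what the computations consume:

- **Scenes** (default 256×256, 3 blobs, semi-axes 10–28 px): each blob is
  a union of 1–3 overlapping rasterized ellipses (a lobed body plan);
  blobs never touch each other or the border. Placement is rejection
  sampling with a 1000-try bound, so infeasible packings fail
  deterministically rather than overlap silently. The textured background
  is cosmetic; no computation reads it.
- **Corruption**: whole-blob misses (probability per blob), boundary
  dilation/erosion by a discrete disk, then false-positive speckles
  clipped to the background. The structuring element uses the inclusion
  rule x² + y² ≤ r² + r; the plain ≤ r² rule under-reaches along
  diagonals and makes morphological rings fall > 10% short of the
  analytic annulus area. Exact confusion counts versus the truth are
  returned as bookkeeping and serve as the oracle in tests.
- **Corrections**: each erroneous pixel is stroked independently with
  probability `completeness`; there is no spatial stroke model, so
  partial corrections are unbiased subsamples of the error sets.
- **Trajectories** (default 60 images, τ = 8): corruption magnitudes
  scale by exp(−i/τ), mimicking a model improving under corrective
  annotation; per-image seeds derive from the trajectory seed.
- **Laser frames**: two symmetric disks on integer centres (centroid =
  centre exactly), with the integer displacement chosen within 0.5 px of
  the requested separation; 1- and 3-dot variants exercise the exclusion
  rule.

What passing tests on this data do **not** show: robustness to real
imaging effects — turbidity, uneven lighting, boundary ambiguity,
spatially correlated user sloppiness, laser dots deformed by oblique
terrain. The generator's masks are geometrically clean; the package's
claims are about the correctness of the computations, not about any
segmentation model.

## Numerical and design choices

- Masks are immutable value objects over boolean arrays; every operation
  returns a new mask.
- Default PNG foreground rule: any non-zero colour channel, with alpha as
  a gate (fully transparent = background). This reads masks written on
  either transparent or opaque-black backgrounds identically and is
  overridable per dataset (`("channel", i, threshold)` or a callable).
- Annotation colours are matched within a Chebyshev tolerance of 30/255
  to absorb anti-aliasing; green/red overlap is impossible below
  tolerance 128 and a hard error otherwise. Redundant strokes (green
  outside the prediction, red inside) are no-ops, counted and logged.
- Sample standard deviations use n−1 throughout; with a single image the
  sd is reported as NaN rather than 0.
- Anomaly flags (zero regions, region-count change against an expected
  count, area jumps beyond a robust z of 4 on median/MAD) are heuristic
  and advisory: the reference workflow did this screening visually, so
  every threshold sits in config and flagged frames are excluded from
  summaries but never deleted from row-level output.
- Problem sizes in tests and in `scripts/acceptance.py` (192×192 scenes,
  60-image trajectories, 60-image validation sets) were chosen as
  desk-scale stand-ins for full survey datasets while keeping every run
  deterministic per seed.

## Known limitations

- Corrective metrics inherit the completeness assumption; they are upper
  bounds when corrections are partial.
- The perimeter estimator is calibrated for smooth, blob-like outlines;
  for highly tortuous or one-pixel-wide structures any boundary-walk
  estimator is scale-dependent.
- Eccentricity from moments is unstable for regions of < ~10 px.
- Laser calibration assumes the two dots lie on a plane roughly normal
  to the camera axis; oblique terrain biases the scale and is not
  modelled.
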