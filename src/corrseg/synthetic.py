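"""Seeded synthetic scenes, corrupted predictions, simulated corrections,
laser frames and training trajectories.

The generator stands in for real survey imagery so that every other module
can be exercised with a known ground truth.  It emulates the features that
matter to the computations:

* lobed foreground blobs (unions of overlapping ellipses, mimicking the
  lobed body plan of the target sponges) of varying size on a textured
  background;
* model predictions corrupted with controllable boundary error
  (dilation/erosion), whole-blob misses and false-positive speckles —
  the error modes a user corrects during interactive training;
* simulated user corrections of controllable completeness (each wrong
  pixel is stroked independently with probability = completeness);
* paired laser dots at a known pixel separation;
* training sequences whose corruption decays exponentially with image
  index, mimicking a model improving under corrective annotation.

Every operation is deterministic for a given seed.  The exact confusion
counts of each corrupted prediction against its truth are returned as
bookkeeping and serve as the oracle in tests.  The background texture is
cosmetic only; no computation ever consults it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .masks import AnnotationMask, BinaryMask, ConfusionCounts

_MAX_PLACEMENT_TRIES = 1000


@dataclass(frozen=True)
class SceneSpec:
    """Geometry of one synthetic scene.

    Defaults give a 256x256 frame with three well-separated lobed blobs
    whose semi-axes span 10-28 px — large enough for stable shape
    measurement, small enough to generate quickly.
    """

    width: int = 256
    height: int = 256
    n_blobs: int = 3
    semi_axis_range: tuple[float, float] = (10.0, 28.0)
    lobes_per_blob: tuple[int, int] = (1, 3)
    texture_amplitude: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("scene dimensions must be positive")
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be >= 0")
        lo, hi = self.semi_axis_range
        if not (0 < lo <= hi):
            raise ValueError("semi_axis_range must be non-empty and positive")
        klo, khi = self.lobes_per_blob
        if not (1 <= klo <= khi):
            raise ValueError("lobes_per_blob must be a non-empty range >= 1")
        if not (0.0 <= self.texture_amplitude <= 1.0):
            raise ValueError("texture_amplitude must be in [0, 1]")


@dataclass(frozen=True)
class CorruptionSpec:
    """Error model applied to a truth mask to fake a model prediction.

    ``boundary_radius`` > 0 dilates the truth (over-prediction), < 0
    erodes it; ``miss_probability`` drops whole blobs; speckles add
    false-positive dots on the background.
    """

    boundary_radius: int = 0
    speckle_fp_count: int = 0
    speckle_radius: int = 2
    miss_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_probability <= 1.0):
            raise ValueError("miss_probability must be in [0, 1]")
        if self.speckle_fp_count < 0 or self.speckle_radius < 1:
            raise ValueError("speckle parameters out of range")


@dataclass(frozen=True)
class TrajectorySpec:
    """A simulated interactive-training run.

    Corruption magnitudes decay as ``initial * exp(-i / decay_tau)`` with
    image index ``i``, emulating a model improving as corrections
    accumulate.  ``correction_completeness`` is the per-pixel probability
    that the simulated user strokes a wrong pixel.
    """

    n_images: int = 60
    initial: CorruptionSpec = field(
        default_factory=lambda: CorruptionSpec(
            boundary_radius=4, speckle_fp_count=6, miss_probability=0.1
        )
    )
    decay_tau: float = 8.0
    correction_completeness: float = 1.0
    scene: SceneSpec = field(default_factory=SceneSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be positive")
        if not (0.0 <= self.correction_completeness <= 1.0):
            raise ValueError("correction_completeness must be in [0, 1]")


@dataclass(frozen=True)
class TrainingItem:
    """One step of a simulated training sequence, with exact bookkeeping."""

    image: np.ndarray
    truth: BinaryMask
    prediction: BinaryMask
    annotation: AnnotationMask
    true_confusion: ConfusionCounts


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

def _ellipse_mask(
    shape: tuple[int, int], cy: float, cx: float, a: float, b: float, theta: float
) -> np.ndarray:
    """Rasterize an ellipse: pixel centres inside the analytic boundary."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dx = xx - cx
    dy = yy - cy
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _disk_offsets(radius: int) -> np.ndarray:
    """Boolean disk structuring element of the given integer radius.

    The inclusion rule ``x² + y² <= r² + r`` balances the directional
    reach of the discrete disk around the Euclidean radius (a plain
    ``<= r²`` rule under-reaches along diagonals), so morphological
    dilation/erosion by ``radius`` tracks the analytic offset band.
    """
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return xx**2 + yy**2 <= r**2 + r


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, BinaryMask]:
    """Generate a textured image and its ground-truth mask.

    Blobs are unions of a primary ellipse and smaller overlapping lobes;
    they never touch each other or the frame border.  Placement is
    rejection-sampled with a bounded retry count, so an infeasible packing
    fails loudly instead of silently overlapping.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    truth = np.zeros((h, w), dtype=bool)
    occupied_dilated = np.zeros((h, w), dtype=bool)  # truth dilated by 1
    lo, hi = spec.semi_axis_range
    for _ in range(spec.n_blobs):
        for attempt in range(_MAX_PLACEMENT_TRIES):
            a = rng.uniform(lo, hi)
            b = rng.uniform(lo, a) if a > lo else lo
            theta = rng.uniform(0.0, math.pi)
            margin = a * (1.0 + 0.8) + 2  # primary + worst-case lobe offset
            if 2 * margin >= min(h, w):
                raise ValueError("blobs too large for the frame")
            cy = rng.uniform(margin, h - 1 - margin)
            cx = rng.uniform(margin, w - 1 - margin)
            blob = _ellipse_mask((h, w), cy, cx, a, b, theta)
            n_lobes = int(rng.integers(spec.lobes_per_blob[0], spec.lobes_per_blob[1] + 1))
            for _lobe in range(n_lobes - 1):
                la = a * rng.uniform(0.4, 0.8)
                lb = b * rng.uniform(0.4, 0.8)
                lt = rng.uniform(0.0, math.pi)
                off = rng.uniform(0.3, 0.8) * a
                ang = rng.uniform(0.0, 2 * math.pi)
                blob |= _ellipse_mask(
                    (h, w),
                    cy + off * math.sin(ang),
                    cx + off * math.cos(ang),
                    la,
                    lb,
                    lt,
                )
            # reject if touching border or (even diagonally) another blob
            if blob[0, :].any() or blob[-1, :].any() or blob[:, 0].any() or blob[:, -1].any():
                continue
            if (blob & occupied_dilated).any():
                continue
            truth |= blob
            occupied_dilated |= ndimage.binary_dilation(blob, _disk_offsets(2))
            break
        else:
            raise ValueError(
                f"could not place blob after {_MAX_PLACEMENT_TRIES} tries; "
                "scene too crowded"
            )
    # cosmetic raster: textured background, brighter foreground
    noise = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=3.0)
    if noise.std() > 0:
        noise = noise / noise.std()
    img = 70.0 + spec.texture_amplitude * 60.0 * noise
    img[truth] += 90.0
    image = np.clip(img, 0, 255).astype(np.uint8)
    return image, BinaryMask(truth)


# ---------------------------------------------------------------------------
# Prediction corruption and simulated corrections
# ---------------------------------------------------------------------------

def corrupt_prediction(
    truth: BinaryMask, spec: CorruptionSpec
) -> tuple[BinaryMask, ConfusionCounts]:
    """Fake a model prediction by corrupting the truth.

    Order: whole-blob misses, then boundary dilation/erosion, then
    false-positive speckles (clipped to the background so they are pure
    false positives).  Returns the prediction and its exact confusion
    against the truth.
    """
    rng = np.random.default_rng(spec.seed)
    t = truth.data
    pred = t.copy()
    if spec.miss_probability > 0:
        lab, n = ndimage.label(t, structure=np.ones((3, 3), dtype=bool))
        for i in range(1, n + 1):
            if rng.random() < spec.miss_probability:
                pred[lab == i] = False
    if spec.boundary_radius > 0:
        pred = ndimage.binary_dilation(pred, _disk_offsets(spec.boundary_radius))
    elif spec.boundary_radius < 0:
        pred = ndimage.binary_erosion(pred, _disk_offsets(-spec.boundary_radius))
    if spec.speckle_fp_count > 0:
        h, w = t.shape
        r = spec.speckle_radius
        disk = _disk_offsets(r)
        for _ in range(spec.speckle_fp_count):
            cy = int(rng.integers(r, h - r))
            cx = int(rng.integers(r, w - r))
            window = pred[cy - r : cy + r + 1, cx - r : cx + r + 1]
            t_window = t[cy - r : cy + r + 1, cx - r : cx + r + 1]
            window |= disk & ~t_window
    tp = int(np.count_nonzero(pred & t))
    fp = int(np.count_nonzero(pred & ~t))
    fn = int(np.count_nonzero(~pred & t))
    tn = t.size - tp - fp - fn
    return BinaryMask(pred), ConfusionCounts(tp, fp, fn, tn)


def derive_annotation(
    pred: BinaryMask,
    truth: BinaryMask,
    completeness: float = 1.0,
    seed: int = 0,
) -> AnnotationMask:
    """Simulate a user correcting a prediction.

    Each false-positive pixel receives a green stroke, and each
    false-negative a red stroke, independently with probability
    ``completeness``.  At 1.0 the correction is exhaustive and applying it
    reproduces the truth; there is no spatial stroke model.
    """
    if not (0.0 <= completeness <= 1.0):
        raise ValueError("completeness must be in [0, 1]")
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth dimensions differ")
    rng = np.random.default_rng(seed)
    fp = pred.data & ~truth.data
    fn = truth.data & ~pred.data
    keep = rng.random(pred.shape) < completeness
    return AnnotationMask(fp & keep, fn & keep)


# ---------------------------------------------------------------------------
# Training trajectories
# ---------------------------------------------------------------------------

def generate_training_sequence(tspec: TrajectorySpec) -> list[TrainingItem]:
    """Simulate an interactive-training run of ``n_images`` steps.

    Step ``i`` draws a fresh scene, corrupts it with magnitudes scaled by
    ``exp(-i / decay_tau)`` and derives the user's correction.  All
    per-step seeds are drawn once from the trajectory seed, so the whole
    sequence is reproducible.
    """
    rng = np.random.default_rng(tspec.seed)
    seeds = rng.integers(0, 2**31 - 1, size=(tspec.n_images, 3))
    items = []
    for i in range(tspec.n_images):
        decay = math.exp(-i / tspec.decay_tau)
        cspec = CorruptionSpec(
            boundary_radius=int(round(tspec.initial.boundary_radius * decay)),
            speckle_fp_count=int(round(tspec.initial.speckle_fp_count * decay)),
            speckle_radius=tspec.initial.speckle_radius,
            miss_probability=tspec.initial.miss_probability * decay,
            seed=int(seeds[i, 1]),
        )
        scene = replace(tspec.scene, seed=int(seeds[i, 0]))
        image, truth = generate_scene(scene)
        pred, cc = corrupt_prediction(truth, cspec)
        ann = derive_annotation(
            pred, truth, tspec.correction_completeness, seed=int(seeds[i, 2])
        )
        items.append(
            TrainingItem(
                image=image,
                truth=truth,
                prediction=pred,
                annotation=ann,
                true_confusion=cc,
            )
        )
    return items


# ---------------------------------------------------------------------------
# Laser frames
# ---------------------------------------------------------------------------

def generate_laser_frame(
    px_per_cm: float,
    separation_cm: float = 5.0,
    dot_radius: int = 3,
    width: Optional[int] = None,
    height: Optional[int] = None,
    n_dots: int = 2,
    seed: int = 0,
) -> BinaryMask:
    """Rasterize a laser-dot mask with known scale.

    Dots are symmetric disks on integer centres, so each centroid is its
    centre exactly; the integer centre pair is chosen so the separation
    matches ``px_per_cm * separation_cm`` within 0.5 px.  ``n_dots`` of 1
    or 3 produce the frames the exclusion rule must reject.
    """
    if px_per_cm <= 0 or separation_cm <= 0:
        raise ValueError("px_per_cm and separation_cm must be positive")
    if n_dots not in (1, 2, 3):
        raise ValueError("n_dots must be 1, 2 or 3")
    rng = np.random.default_rng(seed)
    target = px_per_cm * separation_cm
    r = int(dot_radius)
    if r < 1:
        raise ValueError("dot_radius must be >= 1")
    pad = r + 2
    side = int(math.ceil(target)) + 4 * pad + 8
    w = side if width is None else width
    h = side if height is None else height
    if min(h, w) < 2 * pad + 1 or math.hypot(w - 2 * pad, h - 2 * pad) < target:
        raise ValueError("frame too small for the requested separation")

    def best_integer_displacement(theta: float):
        """Integer (dx, dy) closest to the target separation at this angle."""
        best = None
        for ddx in range(-3, 4):
            dx = int(round(target * math.cos(theta))) + ddx
            if abs(dx) > target:
                continue
            dy = int(round(math.sqrt(max(target**2 - dx**2, 0.0))))
            for ddy in (-1, 0, 1):
                cand = (dx, dy + ddy)
                err = abs(math.hypot(*cand) - target)
                if best is None or err < best[0]:
                    best = (err, cand)
        return best

    # sample angles until the displacement fits the frame with its margins;
    # in a tight frame only near-diagonal orientations are feasible
    placement = None
    for _ in range(_MAX_PLACEMENT_TRIES):
        best = best_integer_displacement(rng.uniform(0.0, 2 * math.pi))
        if best is None or best[0] > 0.5:
            continue
        dx, dy = best[1]
        x_lo = pad - min(dx, 0)
        x_hi = w - pad - max(dx, 0)
        y_lo = pad - min(dy, 0)
        y_hi = h - pad - max(dy, 0)
        if x_lo < x_hi and y_lo < y_hi:
            x1 = int(rng.integers(x_lo, x_hi))
            y1 = int(rng.integers(y_lo, y_hi))
            placement = (x1, y1, x1 + dx, y1 + dy)
            break
    if placement is None:
        raise ValueError("could not place the laser pair inside the frame")
    x1, y1, x2, y2 = placement

    mask = np.zeros((h, w), dtype=bool)
    disk = _disk_offsets(r)

    def place(cy: int, cx: int) -> None:
        mask[cy - r : cy + r + 1, cx - r : cx + r + 1] |= disk

    place(y1, x1)
    if n_dots >= 2:
        place(y2, x2)
    if n_dots == 3:
        for _ in range(_MAX_PLACEMENT_TRIES):
            x3 = int(rng.integers(pad, w - pad))
            y3 = int(rng.integers(pad, h - pad))
            if min(math.hypot(x3 - x1, y3 - y1), math.hypot(x3 - x2, y3 - y2)) > 2 * r + 3:
                place(y3, x3)
                break
        else:
            raise ValueError("could not place a third dot")
    return BinaryMask(mask)
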