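"""Pixel-to-physical scale calibration.

Frames from a moving camera (ROV) change scale continuously, so each frame
is calibrated independently from a pair of laser dots projected a known
distance apart (5 cm here): the pixel distance between the dot centroids
divided by the true separation gives pixels per cm.  Frames where anything
other than exactly two laser regions survive a small-noise filter are
*excluded* — exclusion is a value carried through the pipeline, not an
exception.

Static time-lapse imagery with no lasers is instead scaled once from a
fixed reference of known physical size (here the mean width of a coral
branch, 0.43 cm) measured in pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .masks import BinaryMask
from .regions import label_components, region_properties

#: true separation of the laser pair, cm
DEFAULT_LASER_SEPARATION_CM = 5.0
#: physical width of the fixed reference (coral branch), cm, and its spread
DEFAULT_REFERENCE_CM = 0.43
DEFAULT_REFERENCE_CM_SD = 0.09
#: laser regions smaller than this many pixels are treated as noise
DEFAULT_MIN_REGION_PX = 3


@dataclass(frozen=True)
class ScaleFactor:
    """Pixels-per-cm conversion for one frame or dataset."""

    px_per_cm: float
    source: str = "fixed_reference"  # "lasers" | "fixed_reference"
    relative_error: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.px_per_cm > 0 and math.isfinite(self.px_per_cm)):
            raise ValueError(f"px_per_cm must be positive, got {self.px_per_cm}")

    @property
    def cm2_per_px(self) -> float:
        return (1.0 / self.px_per_cm) ** 2


@dataclass(frozen=True)
class LaserDetection:
    """Outcome of locating the laser pair in one frame."""

    n_regions: int
    status: str  # "ok" | "excluded"
    centroid_1: Optional[tuple[float, float]] = None  # (x, y) pixels
    centroid_2: Optional[tuple[float, float]] = None
    pixel_distance: Optional[float] = None
    reason: Optional[str] = None


def laser_distance(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Euclidean pixel distance between two (x, y) points."""
    x1, y1 = p1
    x2, y2 = p2
    for v in (x1, y1, x2, y2):
        if not math.isfinite(v):
            raise ValueError("laser coordinates must be finite")
    return math.hypot(x1 - x2, y1 - y2)


def calibrate_from_lasers(
    laser_mask: BinaryMask,
    true_separation_cm: float = DEFAULT_LASER_SEPARATION_CM,
    min_region_px: int = DEFAULT_MIN_REGION_PX,
    connectivity: int = 8,
) -> tuple[LaserDetection, Optional[ScaleFactor]]:
    """Calibrate one frame from its segmented laser mask.

    Regions below ``min_region_px`` are discarded as noise.  Exactly two
    surviving regions yield a scale; any other count (a hidden laser, or
    reflections splitting into extra regions) excludes the frame.
    Dot positions are sub-pixel region centroids, which are robust to dot
    size and shape.
    """
    if true_separation_cm <= 0:
        raise ValueError("true_separation_cm must be positive")
    regions = region_properties(label_components(laser_mask, connectivity))
    survivors = [r for r in regions if r.area >= min_region_px]
    n = len(survivors)
    if n != 2:
        word = "region" if n == 1 else "regions"
        detection = LaserDetection(
            n_regions=n,
            status="excluded",
            reason=f"{n} laser {word} detected, need exactly 2",
        )
        return detection, None
    c1 = (survivors[0].centroid_x, survivors[0].centroid_y)
    c2 = (survivors[1].centroid_x, survivors[1].centroid_y)
    dist = laser_distance(c1, c2)
    detection = LaserDetection(
        n_regions=2, status="ok", centroid_1=c1, centroid_2=c2, pixel_distance=dist
    )
    scale = ScaleFactor(px_per_cm=dist / true_separation_cm, source="lasers")
    return detection, scale


def fixed_reference_scale(
    reference_px: float,
    reference_cm: float = DEFAULT_REFERENCE_CM,
    reference_cm_sd: Optional[float] = None,
) -> ScaleFactor:
    """Scale from a reference object of known physical size.

    If the spread of the reference size is given (e.g. the ±0.09 cm spread
    of branch widths), it is propagated as a relative error on the scale,
    not as a distribution.
    """
    if reference_px <= 0 or reference_cm <= 0:
        raise ValueError("reference_px and reference_cm must be positive")
    rel = None if reference_cm_sd is None else reference_cm_sd / reference_cm
    return ScaleFactor(
        px_per_cm=reference_px / reference_cm,
        source="fixed_reference",
        relative_error=rel,
    )


def area_to_cm2(area_px, scale: ScaleFactor):
    """Convert a pixel area (or signed pixel area error, or an array of
    either) to cm².  Exactly linear: f(a+b) == f(a)+f(b)."""
    arr = np.asarray(area_px, dtype=float) * scale.cm2_per_px
    return float(arr) if arr.ndim == 0 else arr


def relative_areas(series) -> np.ndarray:
    """Each area divided by the series maximum; the largest value maps to 1.

    Scale-invariant, so it is insensitive to the calibration factor —
    useful for tracking relative size change (contraction) over time.
    """
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValueError("empty area series")
    m = arr.max()
    if m <= 0:
        raise ValueError("all-zero (or negative) area series")
    return arr / m
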