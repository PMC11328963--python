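"""Binary segmentation masks, corrective annotations and pixel confusion counts.

A segmentation assigns every pixel of an image to foreground (the subject of
interest, e.g. a sponge) or background.  During interactive training a user
*corrects* a model's prediction by painting green strokes on false-positive
pixels (predicted foreground that should be background) and red strokes on
false-negative pixels (missed foreground).  The prediction minus green plus
red is the *corrected* segmentation, which downstream modules treat as ground
truth.

Coordinates are 0-based ``(row, col)``; exported ``x`` is the column and ``y``
the row, following the usual image convention.  Masks are value objects: no
operation mutates its inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Union

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

#: RGB of a pure green / pure red annotation stroke.
GREEN = (0, 255, 0)
RED = (255, 0, 0)

#: Default Chebyshev tolerance when classifying annotation colours; absorbs
#: anti-aliasing at stroke edges.  Must stay < 128 so that green and red can
#: never both match one pixel.
DEFAULT_COLOUR_TOLERANCE = 30

ForegroundRule = Union[None, str, tuple, Callable[[np.ndarray], np.ndarray]]


class DimensionMismatchError(ValueError):
    """Raised when two rasters that must share a pixel grid do not."""


def _require_same_shape(a, b) -> None:
    if (a.height, a.width) != (b.height, b.width):
        raise DimensionMismatchError(
            f"raster dimensions differ: {a.height}x{a.width} vs {b.height}x{b.width}"
        )


class BinaryMask:
    """A foreground/background pixel raster.

    Parameters
    ----------
    data
        2-D boolean (or boolean-convertible) array, ``True`` = foreground.
        The array is copied and frozen.
    """

    __slots__ = ("_data",)

    def __init__(self, data) -> None:
        arr = np.array(data, dtype=bool)
        if arr.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
        if arr.shape[0] == 0 or arr.shape[1] == 0:
            raise ValueError("zero-sized mask")
        arr.setflags(write=False)
        self._data = arr

    # -- constructors ------------------------------------------------------
    @classmethod
    def empty(cls, height: int, width: int) -> "BinaryMask":
        return cls(np.zeros((height, width), dtype=bool))

    @classmethod
    def full(cls, height: int, width: int) -> "BinaryMask":
        return cls(np.ones((height, width), dtype=bool))

    @classmethod
    def from_foreground(
        cls, height: int, width: int, pixels: Iterable[tuple[int, int]]
    ) -> "BinaryMask":
        """Build a mask from explicit ``(row, col)`` foreground coordinates."""
        arr = np.zeros((height, width), dtype=bool)
        for r, c in pixels:
            if not (0 <= r < height and 0 <= c < width):
                raise ValueError(f"pixel {(r, c)} outside {height}x{width} raster")
            arr[r, c] = True
        return cls(arr)

    # -- accessors ---------------------------------------------------------
    @property
    def data(self) -> np.ndarray:
        """Read-only boolean array view, shape ``(height, width)``."""
        return self._data

    @property
    def height(self) -> int:
        return self._data.shape[0]

    @property
    def width(self) -> int:
        return self._data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    @property
    def foreground(self) -> frozenset:
        """Foreground coordinates as a frozen set of ``(row, col)`` tuples."""
        rs, cs = np.nonzero(self._data)
        return frozenset(zip(rs.tolist(), cs.tolist()))

    def foreground_area(self) -> int:
        """Number of foreground pixels."""
        return int(self._data.sum())

    # -- value semantics ---------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.shape == other.shape and bool(
            np.array_equal(self._data, other._data)
        )

    def __repr__(self) -> str:
        return (
            f"BinaryMask({self.height}x{self.width}, "
            f"foreground={self.foreground_area()})"
        )


class AnnotationMask:
    """User corrections for one prediction.

    ``green`` marks pixels that should be background (false positives),
    ``red`` marks pixels that should be foreground (false negatives).
    The two sets are disjoint by construction.
    """

    __slots__ = ("_green", "_red")

    def __init__(self, green, red) -> None:
        g = np.array(green, dtype=bool)
        r = np.array(red, dtype=bool)
        if g.ndim != 2 or g.shape != r.shape:
            raise ValueError("green and red layers must be 2-D and congruent")
        if g.shape[0] == 0 or g.shape[1] == 0:
            raise ValueError("zero-sized annotation")
        if np.any(g & r):
            n = int(np.count_nonzero(g & r))
            raise ValueError(f"{n} pixel(s) annotated both green and red")
        g.setflags(write=False)
        r.setflags(write=False)
        self._green = g
        self._red = r

    @classmethod
    def empty(cls, height: int, width: int) -> "AnnotationMask":
        z = np.zeros((height, width), dtype=bool)
        return cls(z, z)

    @property
    def green(self) -> np.ndarray:
        return self._green

    @property
    def red(self) -> np.ndarray:
        return self._red

    @property
    def height(self) -> int:
        return self._green.shape[0]

    @property
    def width(self) -> int:
        return self._green.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self._green.shape

    def annotated_fraction(self) -> float:
        """Fraction of pixels carrying any stroke; a diagnostic of how
        thorough the user's correction was."""
        total = self._green.size
        return float((self._green.sum() + self._red.sum()) / total)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationMask):
            return NotImplemented
        return bool(
            np.array_equal(self._green, other._green)
            and np.array_equal(self._red, other._red)
        )

    def __repr__(self) -> str:
        return (
            f"AnnotationMask({self.height}x{self.width}, "
            f"green={int(self._green.sum())}, red={int(self._red.sum())})"
        )


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of one prediction against one reference mask."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


# ---------------------------------------------------------------------------
# PNG I/O
# ---------------------------------------------------------------------------

def _resolve_foreground_rule(rule: ForegroundRule) -> Callable[[np.ndarray], np.ndarray]:
    """Turn a foreground-rule spec into ``array -> bool array``.

    ``None`` / ``"nonzero"``: a pixel is foreground iff any colour channel
    is non-zero — robust to the various palettes segmentation overlays come
    in.  When an alpha channel is present it acts as a gate (fully
    transparent pixels are background) rather than as a signal, so masks
    written on either transparent or opaque-black backgrounds read back
    identically.  ``("channel", i, t)``: channel ``i`` at or above
    threshold ``t``.  A callable is used as-is.
    """
    if rule is None or rule == "nonzero":
        def any_nonzero(arr: np.ndarray) -> np.ndarray:
            if arr.ndim == 2:
                return arr > 0
            if arr.shape[2] in (2, 4):  # LA / RGBA: last channel is alpha
                return (arr[..., :-1].max(axis=2) > 0) & (arr[..., -1] > 0)
            return arr.max(axis=2) > 0

        return any_nonzero
    if callable(rule):
        return rule
    if isinstance(rule, tuple) and len(rule) == 3 and rule[0] == "channel":
        _, idx, thresh = rule

        def channel_rule(arr: np.ndarray) -> np.ndarray:
            if arr.ndim == 2:
                if idx != 0:
                    raise ValueError("grayscale image has a single channel")
                return arr >= thresh
            return arr[..., idx] >= thresh

        return channel_rule
    raise ValueError(f"unrecognized foreground rule: {rule!r}")


def read_mask(path, foreground_rule: ForegroundRule = None) -> BinaryMask:
    """Read a PNG (or any raster) as a binary mask.

    By default any pixel with a non-zero value in any channel is foreground;
    see :func:`_resolve_foreground_rule` for alternatives.
    """
    with Image.open(path) as img:
        arr = np.asarray(img)
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    fg = _resolve_foreground_rule(foreground_rule)(arr)
    return BinaryMask(fg)


def write_mask(
    mask: BinaryMask,
    path,
    colour: tuple[int, int, int] = (50, 130, 250),
    background: str = "transparent",
) -> None:
    """Write a mask as an 8-bit RGBA PNG.

    Foreground pixels are opaque ``colour``; background pixels are fully
    transparent (``background="transparent"``) or opaque black
    (``background="black"``).
    """
    if background not in ("transparent", "black"):
        raise ValueError("background must be 'transparent' or 'black'")
    h, w = mask.shape
    out = np.zeros((h, w, 4), dtype=np.uint8)
    if background == "black":
        out[..., 3] = 255
    out[mask.data] = (*colour, 255)
    Image.fromarray(out, mode="RGBA").save(Path(path), format="PNG")


def read_annotation(
    path, colour_tolerance: int = DEFAULT_COLOUR_TOLERANCE
) -> AnnotationMask:
    """Read a correction layer: green and red strokes on a transparent PNG.

    A pixel counts as a stroke when its RGB is within ``colour_tolerance``
    (Chebyshev distance) of pure green or pure red and its alpha is non-zero.
    """
    if colour_tolerance < 0:
        raise ValueError("colour_tolerance must be >= 0")
    with Image.open(path) as img:
        arr = np.asarray(img.convert("RGBA")).astype(np.int16)
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    opaque = arr[..., 3] > 0

    def within(target: tuple[int, int, int]) -> np.ndarray:
        diff = np.abs(arr[..., :3] - np.array(target, dtype=np.int16))
        return opaque & (diff.max(axis=2) <= colour_tolerance)

    green = within(GREEN)
    red = within(RED)
    if np.any(green & red):
        n = int(np.count_nonzero(green & red))
        raise ValueError(
            f"{n} pixel(s) match both green and red at tolerance {colour_tolerance}"
        )
    return AnnotationMask(green, red)


def write_annotation(ann: AnnotationMask, path) -> None:
    """Write an annotation as an RGBA PNG: opaque pure-green / pure-red
    strokes on a fully transparent background."""
    h, w = ann.shape
    out = np.zeros((h, w, 4), dtype=np.uint8)
    out[ann.green] = (*GREEN, 255)
    out[ann.red] = (*RED, 255)
    Image.fromarray(out, mode="RGBA").save(Path(path), format="PNG")


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def apply_correction(pred: BinaryMask, ann: AnnotationMask) -> BinaryMask:
    """Apply user corrections: prediction minus green plus red.

    Green strokes outside the prediction and red strokes inside it are
    no-ops; they are counted and logged, not errors — corrective strokes
    are allowed to be sloppy.
    """
    _require_same_shape(pred, ann)
    redundant_green = int(np.count_nonzero(ann.green & ~pred.data))
    redundant_red = int(np.count_nonzero(ann.red & pred.data))
    if redundant_green or redundant_red:
        logger.debug(
            "redundant corrections: %d green outside prediction, %d red inside",
            redundant_green,
            redundant_red,
        )
    corrected = (pred.data & ~ann.green) | ann.red
    return BinaryMask(corrected)


def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Per-pixel confusion counts of a prediction against a reference mask."""
    _require_same_shape(pred, truth)
    p = pred.data
    t = truth.data
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)
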