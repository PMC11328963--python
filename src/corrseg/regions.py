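"""Connected-component labelling and per-region shape measurements.

For every discrete foreground region the pipeline reports the six
measurements used in benthic image surveys: pixel area, perimeter,
equivalent-circle diameter, eccentricity, and the x,y centroid.

Definitions
-----------
area
    Pixel count.
centroid
    Mean of the pixel coordinates (sub-pixel); ``centroid_x`` is the mean
    column, ``centroid_y`` the mean row.
equivalent diameter
    Diameter of the circle with the same area, ``2*sqrt(area/pi)``.
eccentricity
    Of the ellipse sharing the region's second central moments: with
    covariance eigenvalues ``l1 >= l2``, ``e = sqrt(1 - l2/l1)``; 0 is a
    circle, values near 1 a line.  A single pixel has eccentricity 0 by
    convention; one-pixel-wide lines are capped just below 1.
perimeter
    Length of the traced outer boundary through pixel centres.  Raw
    chain-code length (orthogonal steps 1, diagonal sqrt(2)) systematically
    overestimates smooth outlines by ~5%, so steps are weighted with the
    corner-corrected coefficients of Vossepoel & Smeulders
    (0.980 / 1.406 / -0.091 per corner), which land within ~1% of the true
    circumference for disks of radius >= 20 px.

Default connectivity is 8 so that diagonally adjacent lobes of one
organism count as a single individual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .masks import BinaryMask

#: Chain-code step weights after Vossepoel & Smeulders: orthogonal step,
#: diagonal step, and a correction subtracted per direction change.
_W_ORTHO = 0.980
_W_DIAG = 1.406
_W_CORNER = 0.091

#: eccentricity is reported strictly below 1 even for perfect lines
_ECC_CAP = float(np.nextafter(1.0, 0.0))

REGION_CSV_COLUMNS = [
    "image_id",
    "label",
    "area_px",
    "perimeter_px",
    "diameter_px",
    "eccentricity",
    "centroid_x",
    "centroid_y",
]


@dataclass(frozen=True)
class Region:
    """Measurements for one connected foreground region."""

    label: int
    area: int
    perimeter: float
    equivalent_diameter: float
    eccentricity: float
    centroid_x: float
    centroid_y: float


class LabeledRegions:
    """Per-pixel integer labels, 0 = background, regions 1..n_regions.

    Labels are assigned in row-major order of each region's first pixel,
    so labelling is deterministic for a given mask and connectivity.
    """

    def __init__(self, labels, n_regions: int) -> None:
        arr = np.array(labels, dtype=np.int32)
        if arr.ndim != 2:
            raise ValueError("labels must be 2-D")
        present = np.unique(arr)
        expected = np.arange(0, n_regions + 1)
        nonbg = present[present > 0]
        if not np.array_equal(nonbg, np.arange(1, n_regions + 1)):
            raise ValueError(
                f"labels must be contiguous 1..{n_regions}, found {nonbg.tolist()}"
            )
        arr.setflags(write=False)
        self.labels = arr
        self.n_regions = int(n_regions)

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]


def label_components(mask: BinaryMask, connectivity: int = 8) -> LabeledRegions:
    """Label connected foreground components under 4- or 8-adjacency."""
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=bool)
    elif connectivity == 4:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    else:
        raise ValueError("connectivity must be 4 or 8")
    raw, n = ndimage.label(mask.data, structure=structure)
    if n == 0:
        return LabeledRegions(raw, 0)
    # renumber by row-major order of each region's first pixel
    flat = raw.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.nonzero(flat)[0]
    # reversed so earlier indices overwrite later ones
    first[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1 + order] = np.arange(1, n + 1)
    return LabeledRegions(remap[raw], n)


def eccentricity_from_moments(mu20: float, mu02: float, mu11: float) -> float:
    """Eccentricity of the ellipse with the given second central moments.

    Eigenvalues of ``[[mu20, mu11], [mu11, mu02]]`` give the squared
    semi-axes up to a common factor; ``e = sqrt(1 - l2/l1)``.  Returns 0
    when both moments vanish (a point) and exactly 0 iff the eigenvalues
    coincide.
    """
    if mu20 < 0 or mu02 < 0:
        raise ValueError("diagonal second moments must be non-negative")
    tr = mu20 + mu02
    if tr == 0:
        return 0.0
    s = math.hypot((mu20 - mu02) / 2.0, mu11)
    l1 = tr / 2.0 + s
    l2 = tr / 2.0 - s
    if l1 <= 0:
        return 0.0
    ratio = max(l2, 0.0) / l1
    e = math.sqrt(max(0.0, 1.0 - ratio))
    return min(e, _ECC_CAP)


# ---------------------------------------------------------------------------
# Boundary tracing perimeter
# ---------------------------------------------------------------------------

# Moore neighbourhood in clockwise order starting west.
_NBRS = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))


def _boundary_chain(region: np.ndarray) -> list[int]:
    """Freeman chain code of the outer boundary (Moore tracing).

    Returns the step directions of one full clockwise circuit; an isolated
    pixel yields an empty chain.  Termination is by state repetition
    ((position, backtrack) pairs), which is robust for one-pixel-wide
    appendages where the contour passes a pixel twice.
    """
    pad = np.pad(region, 1)
    rs, cs = np.nonzero(pad)
    cur = (int(rs[0]), int(cs[0]))
    b = 0  # search starts at the backtrack neighbour (west of the start)
    steps: list[int] = []
    seen: dict[tuple, int] = {}
    limit = 8 * pad.size
    while len(steps) < limit:
        for k in range(8):
            idx = (b + k) % 8
            dr, dc = _NBRS[idx]
            nxt = (cur[0] + dr, cur[1] + dc)
            if pad[nxt]:
                steps.append(idx)
                b = (idx + 5) % 8 if idx % 2 == 0 else (idx + 6) % 8
                cur = nxt
                break
        else:
            return []  # no neighbours: single pixel
        state = (cur, b)
        if state in seen:
            return steps[seen[state]:]
        seen[state] = len(steps)
    raise RuntimeError("boundary trace failed to close")  # pragma: no cover


def _chain_length(steps: Sequence[int]) -> float:
    if not steps:
        return 0.0
    n_ortho = sum(1 for s in steps if s % 2 == 0)
    n_diag = len(steps) - n_ortho
    # corners: direction changes around the closed circuit
    n_corner = sum(1 for a, b in zip(steps, list(steps[1:]) + [steps[0]]) if a != b)
    return _W_ORTHO * n_ortho + _W_DIAG * n_diag - _W_CORNER * n_corner


def _region_perimeter(region: np.ndarray) -> float:
    return _chain_length(_boundary_chain(region))


# ---------------------------------------------------------------------------
# Region measurement
# ---------------------------------------------------------------------------

def region_properties(labeled: LabeledRegions) -> list[Region]:
    """Measure every labelled region; returned in label order."""
    regions = []
    lab = labeled.labels
    slices = ndimage.find_objects(lab, max_label=labeled.n_regions)
    for i, sl in enumerate(slices, start=1):
        if sl is None:
            raise ValueError(f"label {i} missing from label image")
        local = lab[sl] == i
        rs, cs = np.nonzero(local)
        rs = rs + sl[0].start
        cs = cs + sl[1].start
        area = rs.size
        cy = float(rs.mean())
        cx = float(cs.mean())
        if area == 1:
            ecc = 0.0
        else:
            dr = rs - cy
            dc = cs - cx
            mu20 = float(np.dot(dc, dc))  # x-axis second moment
            mu02 = float(np.dot(dr, dr))
            mu11 = float(np.dot(dc, dr))
            ecc = eccentricity_from_moments(mu20, mu02, mu11)
        regions.append(
            Region(
                label=i,
                area=int(area),
                perimeter=_region_perimeter(local),
                equivalent_diameter=2.0 * math.sqrt(area / math.pi),
                eccentricity=ecc,
                centroid_x=cx,
                centroid_y=cy,
            )
        )
    return regions


def measure_mask(mask: BinaryMask, connectivity: int = 8) -> list[Region]:
    """Label a mask and measure its regions in one call."""
    return region_properties(label_components(mask, connectivity))


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------

def regions_to_frame(tables: Mapping[str, Sequence[Region]]) -> pd.DataFrame:
    """Flatten per-image region lists to one table.

    Images with no regions emit a single sentinel row with label 0 and
    area 0, so every analysed image appears in the output.
    """
    if not tables:
        raise ValueError("no images to export")
    rows = []
    for image_id, regions in tables.items():
        if not regions:
            rows.append(
                dict(
                    image_id=image_id,
                    label=0,
                    area_px=0,
                    perimeter_px=0.0,
                    diameter_px=0.0,
                    eccentricity=0.0,
                    centroid_x=np.nan,
                    centroid_y=np.nan,
                )
            )
            continue
        for reg in regions:
            rows.append(
                dict(
                    image_id=image_id,
                    label=reg.label,
                    area_px=reg.area,
                    perimeter_px=reg.perimeter,
                    diameter_px=reg.equivalent_diameter,
                    eccentricity=reg.eccentricity,
                    centroid_x=reg.centroid_x,
                    centroid_y=reg.centroid_y,
                )
            )
    return pd.DataFrame(rows, columns=REGION_CSV_COLUMNS)


def export_region_csv(tables: Mapping[str, Sequence[Region]], path) -> None:
    """Write the per-region table as CSV (schema :data:`REGION_CSV_COLUMNS`)."""
    regions_to_frame(tables).to_csv(Path(path), index=False)


def read_region_csv(path) -> dict[str, list[Region]]:
    """Parse an exported region CSV back to per-image region lists;
    sentinel rows (label 0) become empty lists."""
    df = pd.read_csv(path)
    out: dict[str, list[Region]] = {}
    for _, row in df.iterrows():
        image_id = str(row["image_id"])
        out.setdefault(image_id, [])
        if int(row["label"]) == 0:
            continue
        out[image_id].append(
            Region(
                label=int(row["label"]),
                area=int(row["area_px"]),
                perimeter=float(row["perimeter_px"]),
                equivalent_diameter=float(row["diameter_px"]),
                eccentricity=float(row["eccentricity"]),
                centroid_x=float(row["centroid_x"]),
                centroid_y=float(row["centroid_y"]),
            )
        )
    return out
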