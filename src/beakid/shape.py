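"""Morphological shape descriptors (MSD) of the segmented beak contour.

Ten scalars computed from the region-of-interest contour polygon
(sub-pixel, pixel-centre coordinates):

==================  =====================================================
area                enclosed area (shoelace), px^2 — the beak size
perimeter           contour arc length, px
aspect_ratio        bounding-box width / height (axis-aligned box)
extent              area / bounding-box area
solidity            area / convex-hull area
equivalent_diameter (4 * area) / pi  — see note below
circularity         (4 * pi * area) / convex_perimeter^2
rectangularity      area / bounding-box area (axis-aligned box)
form_factor         (4 * pi * area) / perimeter^2
narrow_factor       equivalent_diameter / bounding-box height
==================  =====================================================

Note: ``equivalent_diameter`` follows the study's printed formula
(4*area)/pi, which has units of px^2 and equals 4 r^2 for a disc of radius
r — not the conventional diameter-of-equal-area-circle
sqrt(4*area/pi).  ``standard_equivalent_diameter=True`` switches to the
conventional square-root form (narrow_factor changes accordingly).

With an axis-aligned bounding box, rectangularity coincides with extent;
both are kept as separate entries of the ten-value vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import DegenerateContourError, DegenerateHullError
from .imaging import contour_area, contour_perimeter

MSD_NAMES = (
    "area",
    "perimeter",
    "aspect_ratio",
    "extent",
    "solidity",
    "equivalent_diameter",
    "circularity",
    "rectangularity",
    "form_factor",
    "narrow_factor",
)


@dataclass(frozen=True)
class MsdVector:
    area: float
    perimeter: float
    aspect_ratio: float
    extent: float
    solidity: float
    equivalent_diameter: float
    circularity: float
    rectangularity: float
    form_factor: float
    narrow_factor: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in MSD_NAMES])


def convex_hull(contour: np.ndarray) -> np.ndarray:
    """Convex hull polygon of the contour points, counter-clockwise,
    not closed.  Collinear input raises :class:`DegenerateHullError`."""
    pts = np.asarray(contour, dtype=float)
    if len(pts) < 3:
        raise DegenerateHullError("need at least 3 points for a hull")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateHullError(f"degenerate (collinear) hull input: {exc}") from exc
    return pts[hull.vertices]


def msd_features(contour: np.ndarray, standard_equivalent_diameter: bool = False) -> MsdVector:
    """Compute the ten shape descriptors from one closed ROI contour."""
    pts = np.asarray(contour, dtype=float)
    if len(pts) < 3:
        raise DegenerateContourError("contour needs at least 3 points")
    area = contour_area(pts)
    if area <= 0:
        raise DegenerateContourError("contour encloses zero area")
    perimeter = contour_perimeter(pts)

    hull = convex_hull(pts)
    hull_area = contour_area(hull)
    hull_perimeter = contour_perimeter(hull)

    x, y = pts[:, 0], pts[:, 1]
    w = float(x.max() - x.min())
    h = float(y.max() - y.min())
    if w <= 0 or h <= 0:
        raise DegenerateContourError("contour bounding box is degenerate")
    bbox_area = w * h

    if standard_equivalent_diameter:
        equiv_diameter = float(np.sqrt(4.0 * area / np.pi))
    else:
        equiv_diameter = 4.0 * area / np.pi

    return MsdVector(
        area=area,
        perimeter=perimeter,
        aspect_ratio=w / h,
        extent=area / bbox_area,
        solidity=area / hull_area,
        equivalent_diameter=equiv_diameter,
        circularity=4.0 * np.pi * area / hull_perimeter**2,
        rectangularity=area / bbox_area,
        form_factor=4.0 * np.pi * area / perimeter**2,
        narrow_factor=equiv_diameter / h,
    )


def hybrid_concat(hog: np.ndarray, msd: MsdVector) -> np.ndarray:
    """Hybrid descriptor: HOG block first, then the ten MSD values
    (108 + 10 = 118 at the study geometry)."""
    return np.concatenate([np.asarray(hog, dtype=float), msd.as_array()])
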