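"""Morphological shape descriptors (MSD).

Twenty scalar geometry features of a leaf silhouette: five basic measures
(diameter, major/minor ellipse axis, area, chain-code perimeter) and
fifteen derived ratios. The derived formulas follow standard
leaf-morphometry conventions and live in a registry (``FORMULAS``) so an
alternative reading of a descriptor name can be swapped in without
touching callers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure as skmeasure

from .errors import DegenerateShapeError
from .preprocess import BinaryRoi, chain_perimeter

#: fixed output order; CSV columns are msd_01 ... msd_20 in this order
MSD_NAMES = [
    "diameter",
    "major_axis",
    "minor_axis",
    "area",
    "perimeter",
    "aspect_ratio",
    "form_factor",
    "rectangularity",
    "solidity",
    "eccentricity",
    "narrow_factor",
    "convex_area",
    "irrectangularity",
    "entirety",
    "equivalent_diameter",
    "perim_ratio_LW",
    "perim_convexity",
    "perim_area",
    "perim_ratio_D",
    "perim_ratio_L",
]


@dataclass
class BasicShape:
    """Five primary measurements of a silhouette.

    diameter: max pairwise distance between contour points (px).
    major_axis / minor_axis: axes of the ellipse with the same normalized
    second central moments as the region (px).
    area: foreground pixel count (px^2). perimeter: 8-connected chain-code
    length, sqrt(2) per diagonal step (px).
    """

    diameter: float
    major_axis: float
    minor_axis: float
    area: float
    perimeter: float

    @property
    def degenerate(self) -> bool:
        return (
            self.diameter <= 0
            or self.minor_axis <= 0
            or self.perimeter <= 0
            or self.area <= 0
        )


def _max_pairwise_distance(points: np.ndarray) -> float:
    """Shape diameter. Uses the convex hull when it helps; the hull vertex
    set contains the farthest pair, so this equals the brute-force answer."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 400:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear input etc. -> brute force
            pass
    return float(pdist(pts).max())


def _region(roi: BinaryRoi):
    props = skmeasure.regionprops(roi.mask.astype(np.uint8))
    if not props:
        raise DegenerateShapeError("empty region")
    return props[0]


def basic_shape(roi: BinaryRoi) -> BasicShape:
    """Measure the five basic shape descriptors of an ROI."""
    props = _region(roi)
    return BasicShape(
        diameter=_max_pairwise_distance(roi.contour),
        major_axis=float(props.axis_major_length),
        minor_axis=float(props.axis_minor_length),
        area=float(roi.mask.sum()),
        perimeter=chain_perimeter(roi.contour),
    )


def _hull_geometry(roi: BinaryRoi) -> tuple[float, float]:
    """(convex area, convex perimeter) from the hull of the contour points.

    Area is measured in the same pixel-count convention as the region area:
    polygon area of the hull through pixel centres plus the half-pixel rim
    correction P/2 + 1 (Pick-style), so a convex mask has solidity ~= 1.
    """
    pts = roi.contour.astype(float)
    if len(pts) < 3:
        raise DegenerateShapeError("contour too short for a convex hull")
    hull = ConvexHull(pts)
    poly_area = float(hull.volume)  # 2-D ConvexHull: volume == area
    perim = float(hull.area)  # and area == perimeter
    return poly_area + perim / 2.0 + 1.0, perim


# formula registry: name -> f(basic, aux) where aux carries hull/bbox values
FORMULAS = {
    "aspect_ratio": lambda b, aux: b.major_axis / b.minor_axis,
    "form_factor": lambda b, aux: 4.0 * np.pi * b.area / b.perimeter**2,
    "rectangularity": lambda b, aux: b.area / (b.major_axis * b.minor_axis),
    "solidity": lambda b, aux: b.area / aux["convex_area"],
    "eccentricity": lambda b, aux: float(
        np.sqrt(max(0.0, 1.0 - (b.minor_axis / b.major_axis) ** 2))
    ),
    "narrow_factor": lambda b, aux: b.diameter / b.major_axis,
    "convex_area": lambda b, aux: aux["convex_area"],
    "irrectangularity": lambda b, aux: 1.0 - b.area / (b.major_axis * b.minor_axis),
    "entirety": lambda b, aux: b.area / aux["bbox_area"],
    "equivalent_diameter": lambda b, aux: float(np.sqrt(4.0 * b.area / np.pi)),
    "perim_ratio_LW": lambda b, aux: b.perimeter / (b.major_axis + b.minor_axis),
    "perim_convexity": lambda b, aux: aux["convex_perimeter"] / b.perimeter,
    "perim_area": lambda b, aux: b.perimeter / b.area,
    "perim_ratio_D": lambda b, aux: b.perimeter / b.diameter,
    "perim_ratio_L": lambda b, aux: b.perimeter / b.major_axis,
}


def msd_vector(roi: BinaryRoi) -> dict[str, float]:
    """The 20 morphological shape descriptors, in ``MSD_NAMES`` order.

    Raises :class:`DegenerateShapeError` when a basic measure that appears
    in a denominator is zero (e.g. a single-pixel region).
    """
    b = basic_shape(roi)
    if b.degenerate:
        raise DegenerateShapeError(
            f"degenerate region (D={b.diameter}, W={b.minor_axis}, "
            f"P={b.perimeter}): ratio descriptors undefined"
        )
    convex_area, convex_perimeter = _hull_geometry(roi)
    rows, cols = np.nonzero(roi.mask)
    bbox_area = float(
        (rows.max() - rows.min() + 1) * (cols.max() - cols.min() + 1)
    )
    aux = {
        "convex_area": convex_area,
        "convex_perimeter": convex_perimeter,
        "bbox_area": bbox_area,
    }
    out = {
        "diameter": b.diameter,
        "major_axis": b.major_axis,
        "minor_axis": b.minor_axis,
        "area": b.area,
        "perimeter": b.perimeter,
    }
    for name in MSD_NAMES[5:]:
        out[name] = float(FORMULAS[name](b, aux))
    return out
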