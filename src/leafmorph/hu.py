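"""Hu invariant moments of a binary silhouette.

Seven algebraic combinations of normalized central moments up to order 3,
invariant to translation, rotation and scale. Moments are taken over the
foreground pixels with unit weight. Two variants are provided: the
canonical 1962 formulas (default) and a literal transcription variant
(``paper_literal``) that differs in Hu4 (uses (eta30 + 3*eta12)^2) and in
one factor of Hu7 ((3*eta21 - eta30) in place of (3*eta12 - eta30)); the
two agree on fully symmetric shapes.

Because the raw invariants span ~10 orders of magnitude, the feature
vector is log-compressed by default: h -> sign(h) * log10(|h|).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateShapeError

HU_NAMES = [f"hu_{i}" for i in range(1, 8)]


@dataclass
class MomentSet:
    """Raw (m), central (mu) and normalized central (eta) moments.

    Keys are (p, q) with p the x (column) order and q the y (row) order.
    eta_pq = mu_pq / mu_00^((p+q)/2 + 1) for p+q in {2, 3}.
    """

    m: dict = field(default_factory=dict)
    mu: dict = field(default_factory=dict)
    eta: dict = field(default_factory=dict)


def moment_set(mask: np.ndarray) -> MomentSet:
    """Compute moments through order 3 over the foreground of ``mask``.

    ``mask`` may be boolean (unit weight per foreground pixel) or a float
    coverage/intensity map in [0, 1], e.g. an anti-aliased silhouette; the
    pixel values are then the weights.
    """
    arr = np.asarray(mask, dtype=float)
    rows, cols = np.nonzero(arr)
    if len(rows) == 0:
        raise DegenerateShapeError("empty mask has no moments")
    w = arr[rows, cols]
    x = cols.astype(float)
    y = rows.astype(float)
    ms = MomentSet()
    for p in range(4):
        for q in range(4):
            if p + q <= 3:
                ms.m[(p, q)] = float(np.sum(w * x**p * y**q))
    m00 = ms.m[(0, 0)]
    xb = ms.m[(1, 0)] / m00
    yb = ms.m[(0, 1)] / m00
    xc = x - xb
    yc = y - yb
    for p in range(4):
        for q in range(4):
            if p + q <= 3:
                ms.mu[(p, q)] = float(np.sum(w * xc**p * yc**q))
    for (p, q), mu in ms.mu.items():
        if 2 <= p + q <= 3:
            ms.eta[(p, q)] = mu / m00 ** ((p + q) / 2.0 + 1.0)
    return ms


def hu_vector(moments: MomentSet, variant: str = "standard") -> np.ndarray:
    """The seven Hu invariants from a :class:`MomentSet`."""
    e = moments.eta
    n20, n02, n11 = e[(2, 0)], e[(0, 2)], e[(1, 1)]
    n30, n03, n21, n12 = e[(3, 0)], e[(0, 3)], e[(2, 1)], e[(1, 2)]
    hu1 = n20 + n02
    hu2 = (n20 - n02) ** 2 + 4 * n11**2
    hu3 = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    hu5 = (n30 - 3 * n12) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
    ) + (3 * n21 - n03) * (n21 + n03) * (
        3 * (n30 + n12) ** 2 - (n21 + n03) ** 2
    )
    hu6 = (n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2) + 4 * n11 * (
        n30 + n12
    ) * (n21 + n03)
    if variant == "standard":
        hu4 = (n30 + n12) ** 2 + (n21 + n03) ** 2
        hu7 = (3 * n21 - n03) * (n30 + n12) * (
            (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
        ) - (n30 - 3 * n12) * (n21 + n03) * (
            3 * (n30 + n12) ** 2 - (n21 + n03) ** 2
        )
    elif variant == "paper_literal":
        # literal transcription: Hu3/Hu4 use (eta03 - 3*eta21) / (eta30 +
        # 3*eta12)^2 and Hu7's second product keeps a + sign with a
        # (3*eta21 - eta30) factor
        hu3 = (n30 - 3 * n12) ** 2 + (n03 - 3 * n21) ** 2
        hu4 = (n30 + 3 * n12) ** 2 + (n03 + n21) ** 2
        hu7 = (3 * n21 - n03) * (n30 + n12) * (
            (n30 + n12) ** 2 - 3 * (n03 + n21) ** 2
        ) + (3 * n21 - n30) * (n21 + n03) * (
            3 * (n30 + n12) ** 2 - (n03 + n21) ** 2
        )
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return np.array([hu1, hu2, hu3, hu4, hu5, hu6, hu7])


def log_compress(values: np.ndarray, floor: float = 1e-30) -> np.ndarray:
    """sign(h) * log10(|h|), with |h| floored to keep zeros finite."""
    v = np.asarray(values, dtype=float)
    return np.sign(v) * np.log10(np.maximum(np.abs(v), floor))


def hu_from_mask(
    mask: np.ndarray, variant: str = "standard", log: bool = True
) -> np.ndarray:
    """Convenience: moments -> Hu invariants (log-compressed by default)."""
    hu = hu_vector(moment_set(mask), variant=variant)
    return log_compress(hu) if log else hu
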