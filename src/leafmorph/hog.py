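"""Histogram of oriented gradients (HOG), 81-dimensional.

The leaf crop is letterboxed into a fixed square window, per-pixel image
gradients are computed with centred differences, and each foreground pixel
votes its gradient magnitude into one of nine unsigned orientation bins
(20 degrees wide). The window is a single block of 3 x 3 cells, giving a
3 x 3 x 9 = 81 vector after block normalization.

Orientation is the angle of the gradient vector (Gx, Gy) folded to
[0, 180). Block normalization defaults to V / sqrt(||V||^2 + eps^2); the
scale-inconsistent literal variant V / (||V||^2 + eps^2) is available as
``norm="paper"``.
"""

from __future__ import annotations

import numpy as np
from skimage import transform as sktransform

from .errors import InvalidInputError

#: CSV column names hog_01 ... hog_81
HOG_NAMES = [f"hog_{i:02d}" for i in range(1, 82)]

DEFAULT_WINDOW = 128
DEFAULT_BINS = 9
DEFAULT_GRID = 3
DEFAULT_EPS = 1e-5  # relative to the unit intensity range of the window


def gradient_field(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Centred-difference gradients of a grayscale image.

    Returns (Gx, Gy, magnitude, orientation_deg). Gx is the half-difference
    along columns, Gy along rows (replicated edges); orientation is the
    unsigned gradient angle in [0, 180), with 0 at zero gradient.
    """
    g = np.asarray(img, dtype=float)
    if g.ndim != 2 or g.shape[0] < 3 or g.shape[1] < 3:
        raise InvalidInputError("gradient_field needs a grayscale image >= 3x3")
    pad = np.pad(g, 1, mode="edge")
    gx = (pad[1:-1, 2:] - pad[1:-1, :-2]) / 2.0
    gy = (pad[2:, 1:-1] - pad[:-2, 1:-1]) / 2.0
    mag = np.hypot(gx, gy)
    theta = np.degrees(np.arctan2(gy, gx)) % 180.0
    theta[mag == 0] = 0.0
    return gx, gy, mag, theta


def _letterbox(gray: np.ndarray, mask: np.ndarray, window: int, bg: float):
    """Aspect-preserving resize of (gray, mask) into a window x window
    canvas; unused border filled with the background level."""
    h, w = gray.shape
    scale = window / max(h, w)
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    gsmall = sktransform.resize(gray, (nh, nw), order=1, anti_aliasing=True)
    msmall = sktransform.resize(mask.astype(float), (nh, nw), order=1) > 0.5
    canvas = np.full((window, window), bg, dtype=float)
    mcanvas = np.zeros((window, window), dtype=bool)
    r0 = (window - nh) // 2
    c0 = (window - nw) // 2
    canvas[r0 : r0 + nh, c0 : c0 + nw] = np.where(msmall, gsmall, bg)
    mcanvas[r0 : r0 + nh, c0 : c0 + nw] = msmall
    return canvas, mcanvas


def hog_descriptor(
    roi_gray: np.ndarray,
    mask: np.ndarray,
    bins: int = DEFAULT_BINS,
    grid: int = DEFAULT_GRID,
    window: int = DEFAULT_WINDOW,
    norm: str = "standard",
    eps: float = DEFAULT_EPS,
    on_mask: bool = False,
    background: float = 1.0,
) -> np.ndarray:
    """Compute the block-normalized HOG vector of a masked leaf crop.

    ``roi_gray`` is the grayscale crop aligned with ``mask``; intensities
    are rescaled to [0, 1] and background pixels forced to ``background``.
    With ``on_mask=True`` the binary silhouette itself is the input image.
    Votes are cast only by foreground pixels, with hard bin assignment.
    Returns a flat vector of length grid*grid*bins in (cell-row, cell-col,
    bin) order.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise InvalidInputError("empty mask")
    if mask.shape != np.shape(roi_gray)[:2]:
        raise InvalidInputError("gray crop and mask shapes differ")
    if on_mask:
        gray = np.where(mask, 0.0, background)
    else:
        g = np.asarray(roi_gray, dtype=float)
        lo, hi = g.min(), g.max()
        gray = (g - lo) / (hi - lo) if hi > lo else np.zeros_like(g)
    canvas, mcanvas = _letterbox(gray, mask, window, bg=background)
    _, _, mag, theta = gradient_field(canvas)
    bin_width = 180.0 / bins
    bin_idx = np.minimum((theta // bin_width).astype(int), bins - 1)
    rr, cc = np.nonzero(mcanvas)
    cell_r = np.minimum(rr * grid // window, grid - 1)
    cell_c = np.minimum(cc * grid // window, grid - 1)
    flat = (cell_r * grid + cell_c) * bins + bin_idx[rr, cc]
    hist = np.bincount(flat, weights=mag[rr, cc], minlength=grid * grid * bins)
    if norm == "standard":
        return hist / np.sqrt(np.sum(hist**2) + eps**2)
    if norm == "paper":
        return hist / (np.sum(hist**2) + eps**2)
    if norm == "none":  # raw votes, e.g. for conservation checks
        return hist
    raise InvalidInputError(f"unknown norm {norm!r}")
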