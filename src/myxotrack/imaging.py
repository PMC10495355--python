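"""Acquisition-side preprocessing: offset estimation, focus selection and
diffraction-limited focus (spot) detection.

``estimate_offset`` provides the pixel-resolution normalized
cross-correlation used both for mosaic tile registration and for temporal
drift correction against stationary landmarks. ``select_focus`` rebuilds a
2D image from a defocused z-stack by choosing, per ROI tile, the sharpest
plane. ``detect_foci`` locates intracellular motility-complex clusters as
diffraction-limited spots in a band-passed, locally normalized sum of the
four central z-planes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

__all__ = ["OffsetEstimate", "Spot", "estimate_offset", "select_focus",
           "detect_foci"]


@dataclass
class OffsetEstimate:
    dy: int
    dx: int
    peak_correlation: float
    low_confidence: bool = False


def _norm_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equal-shaped patches; 0 when degenerate."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def estimate_offset(image_a: np.ndarray, image_b: np.ndarray,
                    max_shift: int = 20,
                    confidence_threshold: float = 0.3) -> OffsetEstimate:
    """Integer shift (dy, dx) maximizing normalized cross-correlation.

    The returned shift is the translation by which ``image_b`` is displaced
    relative to ``image_a`` (content at a[p] appears at b[p + (dy, dx)]):
    correlation is evaluated between overlapping regions for every integer
    shift within ``max_shift``. Constant images, or a best peak below
    ``confidence_threshold``, are flagged low confidence.
    """
    a = np.asarray(image_a, float)
    b = np.asarray(image_b, float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if max_shift >= min(a.shape) / 2:
        raise ValueError("max_shift must be below half the smallest dimension")
    if a.std() == 0 or b.std() == 0:
        return OffsetEstimate(0, 0, 0.0, low_confidence=True)
    best = (-2.0, 0, 0)
    h, w = a.shape
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            a_sl = a[max(-dy, 0):h + min(-dy, 0), max(-dx, 0):w + min(-dx, 0)]
            b_sl = b[max(dy, 0):h + min(dy, 0), max(dx, 0):w + min(dx, 0)]
            c = _norm_corr(a_sl, b_sl)
            # strict > keeps the smallest (dy, dx) among exact ties
            if c > best[0] + 1e-12:
                best = (c, dy, dx)
    peak, dy, dx = best
    return OffsetEstimate(dy, dx, peak, low_confidence=peak < confidence_threshold)


def _sharpness(img: np.ndarray, sigma: float = 2.0) -> float:
    """Variance of the high-pass residual; a standard focus proxy."""
    hp = img - ndimage.gaussian_filter(img, sigma)
    return float(hp.var())


def select_focus(z_stack: np.ndarray, roi_grid: int = 4) -> np.ndarray:
    """Restitch the in-focus plane per ROI tile of a z-stack.

    The image is divided into an ``roi_grid`` x ``roi_grid`` grid of equal
    tiles (padded by edge replication when not divisible); for each tile the
    plane with the highest high-pass variance is selected, ties going to the
    lowest plane index, and the chosen tiles are restitched.
    """
    stack = np.asarray(z_stack, float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("z_stack must be a nonempty (Z, H, W) array")
    nz, h, w = stack.shape
    if nz == 1:
        return stack[0].copy()
    ph = (-h) % roi_grid
    pw = (-w) % roi_grid
    padded = np.pad(stack, ((0, 0), (0, ph), (0, pw)), mode="edge")
    th, tw = padded.shape[1] // roi_grid, padded.shape[2] // roi_grid
    out = np.empty(padded.shape[1:])
    for i in range(roi_grid):
        for j in range(roi_grid):
            sl = (slice(i * th, (i + 1) * th), slice(j * tw, (j + 1) * tw))
            scores = [_sharpness(padded[z][sl]) for z in range(nz)]
            z_best = int(np.argmax(scores))     # argmax takes the first tie
            out[sl] = padded[z_best][sl]
    return out[:h, :w]


@dataclass
class Spot:
    row: float
    col: float
    intensity: float


def detect_foci(z_stack: np.ndarray, band_sigmas: tuple[float, float] = (1.0, 5.0),
                detection_threshold: float = 10.0,
                local_norm_window: int = 32,
                min_distance: int = 3) -> list[Spot]:
    """Detect diffraction-limited spots in the four central z-planes.

    Each plane is band-pass filtered (difference of Gaussians with
    ``band_sigmas``), locally normalized ((pixel - local mean) / local sd
    over a ``local_norm_window`` px window), then the four central planes
    are summed and local maxima above ``detection_threshold`` are reported
    with intensity-weighted subpixel centroids (5x5 neighbourhood), sorted
    by peak intensity descending.
    """
    stack = np.asarray(z_stack, float)
    if stack.ndim != 3 or stack.shape[0] < 4:
        raise ValueError("z_stack must have at least 4 planes")
    lo, hi = band_sigmas
    if not 0 < lo < hi:
        raise ValueError("band_sigmas must satisfy 0 < low < high")
    nz = stack.shape[0]
    mid = nz // 2
    planes = range(mid - 2, mid + 2)
    acc = np.zeros(stack.shape[1:])
    size = local_norm_window
    for z in planes:
        bp = ndimage.gaussian_filter(stack[z], lo) - ndimage.gaussian_filter(stack[z], hi)
        mean = ndimage.uniform_filter(bp, size)
        sq = ndimage.uniform_filter(bp * bp, size)
        sd = np.sqrt(np.maximum(sq - mean * mean, 1e-12))
        acc += (bp - mean) / sd
    coords = peak_local_max(acc, min_distance=min_distance,
                            threshold_abs=detection_threshold, exclude_border=2)
    spots = []
    h, w = acc.shape
    for r, c in coords:
        r0, r1 = max(r - 2, 0), min(r + 3, h)
        c0, c1 = max(c - 2, 0), min(c + 3, w)
        patch = acc[r0:r1, c0:c1]
        weights = np.clip(patch, 0.0, None)
        if weights.sum() == 0:
            rr, cc = float(r), float(c)
        else:
            gy, gx = np.mgrid[r0:r1, c0:c1]
            rr = float((gy * weights).sum() / weights.sum())
            cc = float((gx * weights).sum() / weights.sum())
        spots.append(Spot(rr, cc, float(acc[r, c])))
    spots.sort(key=lambda s: -s.intensity)
    return spots
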