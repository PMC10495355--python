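"""Per-track kinematics: instantaneous speed, gyration radius, MSD and the
power-law directionality exponent alpha.

The MSD exponent classifies motion regimes: alpha < 1 confined, alpha = 1
Brownian, alpha > 1 directed (2 = ballistic). It is the slope of an ordinary
least-squares line fit to log MSD versus log lag over the first five lags,
with the MSD time-averaged over all overlapping start points of each lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["msd", "directionality_alpha", "instantaneous_speed",
           "speed_series", "gyration_radius", "MSDCurve", "DirectionalityResult"]


@dataclass
class MSDCurve:
    lags: np.ndarray        # frames, starting at 0
    values: np.ndarray      # px^2; values[0] == 0
    n_intervals: np.ndarray  # contributing interval count per lag


@dataclass
class DirectionalityResult:
    alpha: float | None
    intercept: float | None
    n_lags: int

    @property
    def defined(self) -> bool:
        return self.alpha is not None and np.isfinite(self.alpha)


def _as_xy(track) -> np.ndarray:
    arr = np.asarray(track, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("track must be an (n, 2) array of (row, col) positions")
    return arr


def msd(track, max_lag: int | None = None) -> MSDCurve:
    """Time-averaged mean squared displacement over overlapping intervals.

    MSD(tau) = mean over t of |x(t + tau) - x(t)|^2.
    """
    xy = _as_xy(track)
    n = len(xy)
    if max_lag is None:
        max_lag = n - 1
    max_lag = min(max_lag, n - 1)
    lags = np.arange(max_lag + 1)
    values = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=int)
    counts[0] = n
    for lag in range(1, max_lag + 1):
        d = xy[lag:] - xy[:-lag]
        sq = np.einsum("ij,ij->i", d, d)
        values[lag] = sq.mean()
        counts[lag] = len(sq)
    return MSDCurve(lags, values, counts)


def directionality_alpha(track, n_lags: int = 5) -> DirectionalityResult:
    """Power-law exponent of the MSD over its first ``n_lags`` lags.

    Fits log MSD = alpha * log tau + c by ordinary least squares. A zero MSD
    at any fitted lag (a revisited position at every interval of that lag)
    makes the log undefined; the result is then reported as missing rather
    than extrapolated, since such exponents are artifacts of stalled or
    mis-linked tracks rather than of motion.
    """
    xy = _as_xy(track)
    if len(xy) <= n_lags:
        raise ValueError(f"track must be longer than n_lags={n_lags}")
    curve = msd(xy, max_lag=n_lags)
    vals = curve.values[1:n_lags + 1]
    if np.any(vals <= 0):
        return DirectionalityResult(None, None, n_lags)
    slope, intercept = np.polyfit(np.log(curve.lags[1:n_lags + 1]), np.log(vals), 1)
    return DirectionalityResult(float(slope), float(intercept), n_lags)


def instantaneous_speed(track, t: int, half_window: int = 5,
                        dt: float = 1.0) -> float:
    """Speed at frame ``t``: straight-line distance between the positions
    ``half_window`` frames before and after, divided by the elapsed time
    (``2 * half_window * dt``).

    Raises IndexError when the window does not fit inside the track; callers
    skip those frames rather than zero-filling them.
    """
    xy = _as_xy(track)
    if t - half_window < 0 or t + half_window >= len(xy):
        raise IndexError(f"window of +-{half_window} frames does not fit at t={t}")
    d = xy[t + half_window] - xy[t - half_window]
    return float(np.hypot(*d) / (2 * half_window * dt))


def speed_series(track, half_window: int = 5, dt: float = 1.0) -> np.ndarray:
    """Speeds at every interior frame; frames within ``half_window`` of either
    end are skipped (the returned array has ``n - 2*half_window`` entries)."""
    xy = _as_xy(track)
    n = len(xy)
    if n <= 2 * half_window:
        return np.empty(0)
    d = xy[2 * half_window:] - xy[:-2 * half_window]
    return np.hypot(d[:, 0], d[:, 1]) / (2 * half_window * dt)


def gyration_radius(track) -> float:
    """Mean (not RMS) distance of trajectory points from their centroid."""
    xy = _as_xy(track)
    if len(xy) == 0:
        raise ValueError("track must contain at least one point")
    center = xy.mean(axis=0)
    return float(np.hypot(*(xy - center).T).mean())
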