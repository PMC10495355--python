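"""Prey-lysis quantification from the prey fluorescence channel.

The field of view is normalized by the Gaussian excitation profile, split
into three equal bands along the invasion direction — the invaded band
(predation zone), an unused middle band, and the not-yet-reached band (safe
zone) — and the per-frame mean intensity of each band is tracked. Dividing
the predation series by the safe series cancels photobleaching exactly
(both decay by the same exp(-b t)); a single-exponential fit to the
corrected series gives the lysis decay time tau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, least_squares

__all__ = ["IntensitySeries", "DecayFit", "fit_illumination_profile",
           "normalize_illumination", "zone_intensity_series", "decay_time"]


@dataclass
class IntensitySeries:
    zone: str                 # "predation" | "middle" | "safe"
    values: np.ndarray        # per-frame mean intensity, values[0] == 1
    normalization: str = "first-frame"


@dataclass
class DecayFit:
    tau: float | None         # decay time, frames (or seconds if dt applied)
    amplitude: float | None
    baseline: float
    residual: float
    non_decaying: bool = False
    half_life: float | None = None


def fit_illumination_profile(image: np.ndarray) -> tuple[np.ndarray, float]:
    """Fit a centred 2D Gaussian (amplitude and sigma free) to an image.

    Intended for the temporal median of a prey stack, where lawn structure
    averages out and the excitation profile dominates. Returns the profile
    normalized to peak 1 and the fitted sigma.
    """
    img = np.asarray(image, float)
    h, w = img.shape
    r = np.arange(h) - (h - 1) / 2.0
    c = np.arange(w) - (w - 1) / 2.0
    r2 = r[:, None] ** 2 + c[None, :] ** 2

    def residuals(p):
        amp, sigma = p
        return (amp * np.exp(-r2 / (2 * sigma ** 2)) - img).ravel()

    sigma0 = min(h, w) / 4.0
    res = least_squares(residuals, x0=[float(img.max()), sigma0],
                        bounds=([0.0, 1.0], [np.inf, 10.0 * max(h, w)]))
    amp, sigma = res.x
    profile = np.exp(-r2 / (2 * sigma ** 2))
    return profile, float(sigma)


def normalize_illumination(image: np.ndarray,
                           profile: np.ndarray | None = None) -> np.ndarray:
    """Divide an image (or stack) by the excitation profile.

    With no profile given, a centred 2D Gaussian fitted to the temporal
    median of the stack is used. The profile must be strictly positive.
    """
    image = np.asarray(image, float)
    if profile is None:
        ref = np.median(image, axis=0) if image.ndim == 3 else image
        profile, _ = fit_illumination_profile(ref)
    profile = np.asarray(profile, float)
    if np.any(profile <= 0):
        raise ValueError("illumination profile must be strictly positive")
    if profile.shape != image.shape[-2:]:
        raise ValueError("profile shape must match the image")
    return image / profile


def zone_intensity_series(stack: np.ndarray, invasion_axis: str = "rows",
                          invaded_end: str = "start"
                          ) -> dict[str, IntensitySeries]:
    """Mean intensity per frame in three equal bands along the invasion axis.

    The field is projected perpendicular to the invasion direction and cut
    into three equal parts: the band at ``invaded_end`` is the predation
    zone, the opposite band the safe zone, the central band is kept but
    conventionally unused. Any remainder rows go to the middle band. Each
    series is normalized to its first frame.
    """
    stack = np.asarray(stack, float)
    if stack.ndim != 3:
        raise ValueError("stack must be (T, H, W)")
    if invasion_axis == "cols":
        stack = np.swapaxes(stack, 1, 2)
    elif invasion_axis != "rows":
        raise ValueError("invasion_axis must be 'rows' or 'cols'")
    T, H, _ = stack.shape
    third = H // 3
    first = stack[:, :third, :]
    middle = stack[:, third:H - third, :]
    last = stack[:, H - third:, :]
    if invaded_end == "start":
        bands = {"predation": first, "middle": middle, "safe": last}
    elif invaded_end == "end":
        bands = {"predation": last, "middle": middle, "safe": first}
    else:
        raise ValueError("invaded_end must be 'start' or 'end'")
    out = {}
    for zone, band in bands.items():
        means = band.mean(axis=(1, 2))
        if means[0] == 0:
            raise ValueError(f"zone {zone!r} has zero first-frame intensity")
        out[zone] = IntensitySeries(zone, means / means[0])
    return out


def decay_time(series: np.ndarray | IntensitySeries,
               reference: np.ndarray | IntensitySeries | None = None,
               dt: float = 1.0, estimator: str = "exponential") -> DecayFit:
    """Decay time of a zone intensity series.

    The series is divided by the safe-zone ``reference`` (cancelling
    photobleaching) and fitted with ``a * exp(-t / tau)``; tau is reported
    in units of ``dt``. A series whose fit does not decrease (or whose
    best-fit tau is effectively infinite) is flagged non-decaying. The
    ``half-life`` estimator instead reports the first time the corrected
    series falls below 0.5.
    """
    y = np.asarray(series.values if isinstance(series, IntensitySeries)
                   else series, float)
    if len(y) < 5:
        raise ValueError("series must have at least 5 frames")
    if reference is not None:
        ref = np.asarray(reference.values if isinstance(reference, IntensitySeries)
                         else reference, float)
        if len(ref) != len(y):
            raise ValueError("series and reference must have equal length")
        y = y / ref
    y = y / y[0]
    t = np.arange(len(y), dtype=float) * dt

    if estimator == "half-life":
        below = np.nonzero(y < 0.5)[0]
        if len(below) == 0:
            return DecayFit(None, None, 0.0, 0.0, non_decaying=True)
        k = below[0]
        # linear interpolation to the 0.5 crossing
        t_half = t[k] if k == 0 else \
            t[k - 1] + (0.5 - y[k - 1]) * (t[k] - t[k - 1]) / (y[k] - y[k - 1])
        return DecayFit(None, None, 0.0, 0.0, half_life=float(t_half))
    if estimator != "exponential":
        raise ValueError("estimator must be 'exponential' or 'half-life'")

    tau_max = 1e6 * (t[-1] if t[-1] > 0 else 1.0)
    try:
        popt, _ = curve_fit(lambda tt, a, tau: a * np.exp(-tt / tau), t, y,
                            p0=[1.0, max(t[-1] / 2.0, dt)],
                            bounds=([0.0, 1e-9], [np.inf, tau_max]),
                            maxfev=10000)
    except RuntimeError:
        return DecayFit(None, None, 0.0, float(np.var(y)), non_decaying=True)
    a, tau = popt
    resid = float(np.sqrt(np.mean((a * np.exp(-t / tau) - y) ** 2)))
    total_drop = 1.0 - np.exp(-t[-1] / tau)
    if total_drop < 0.02:        # < 2% decay over the whole series
        return DecayFit(None, float(a), 0.0, resid, non_decaying=True)
    return DecayFit(float(tau), float(a), 0.0, resid)
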