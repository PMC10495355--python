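"""Class-series smoothing, transition statistics and the triangle embedding.

Raw per-frame class labels flicker at decision boundaries; a rolling modal
filter over a 10-frame window removes spurious single-frame transitions
before events are counted. Transition probabilities are estimated over
change events only (self-transitions excluded), matching the between-class
arrows of a state diagram; a per-frame variant that includes dwell is
available by flag. The triangle embedding replaces a cell's coordinates by
the corner of an equilateral triangle assigned to its current class (plus
Gaussian jitter) so that class trajectories can be rendered as 2D paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CLASSES

__all__ = ["smooth_classes", "transition_matrix", "triangle_embedding",
           "TransitionMatrix", "TRIANGLE_CORNERS"]

#: tie-break priority for the modal filter (earlier wins)
_PRIORITY = {c: i for i, c in enumerate(CLASSES)}

#: unit-side equilateral triangle, corners ordered scout/loner/swarm
#: counterclockwise in (x, y)
TRIANGLE_CORNERS = {
    "scout": np.array([0.0, 0.0]),
    "loner": np.array([1.0, 0.0]),
    "swarm": np.array([0.5, np.sqrt(3) / 2.0]),
}


def smooth_classes(series: list[str], window: int = 10) -> list[str]:
    """Rolling modal filter: each frame takes the most frequent label of its
    centred window (truncated at the series ends, no padding).

    For an even window the centre is offset left: frame t sees
    [t - window//2, t + (window-1)//2]. Ties go to the class earliest in
    the fixed priority order scout < loner < swarm.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(series)
    if n == 0:
        return []
    lo_off = window // 2
    hi_off = (window - 1) // 2
    out = []
    for t in range(n):
        lo = max(0, t - lo_off)
        hi = min(n, t + hi_off + 1)
        win = series[lo:hi]
        counts: dict[str, int] = {}
        for c in win:
            counts[c] = counts.get(c, 0) + 1
        best = max(counts, key=lambda c: (counts[c], -_PRIORITY.get(c, 99)))
        out.append(best)
    return out


@dataclass
class TransitionMatrix:
    """Counts and row-normalized probabilities over (scout, loner, swarm)."""

    counts: np.ndarray          # (3, 3) change-event counts; diagonal is dwell
    probabilities: np.ndarray   # rows with events sum to 1; others zero-flagged
    n_tracks: int
    n_events: int
    per_frame: bool = False     # True when dwell (diagonal) is included
    empty_rows: tuple[int, ...] = ()

    def p(self, frm: str, to: str) -> float:
        return float(self.probabilities[CLASSES.index(frm), CLASSES.index(to)])


def transition_matrix(series_list: list[list[str]],
                      include_dwell: bool = False
                      ) -> tuple[TransitionMatrix, list[int]]:
    """Accumulate class-change statistics over smoothed per-track series.

    Returns the matrix plus per-track change-event counts. An event is any
    frame where the label differs from the previous frame. By default rows
    are normalized over change events only; with ``include_dwell`` the
    diagonal (no-change frames) enters the normalization.
    """
    counts = np.zeros((3, 3))
    per_track = []
    for series in series_list:
        ev = 0
        for a, b in zip(series[:-1], series[1:]):
            i, j = CLASSES.index(a), CLASSES.index(b)
            counts[i, j] += 1
            if i != j:
                ev += 1
        per_track.append(ev)
    used = counts.copy()
    if not include_dwell:
        np.fill_diagonal(used, 0.0)
    row_sums = used.sum(axis=1)
    probs = np.zeros_like(used)
    empty = tuple(int(i) for i in np.nonzero(row_sums == 0)[0])
    nz = row_sums > 0
    probs[nz] = used[nz] / row_sums[nz, None]
    return (TransitionMatrix(counts, probs, len(series_list),
                             int(sum(per_track)), include_dwell, empty),
            per_track)


def triangle_embedding(series: list[str], noise_sd: float = 0.05,
                       seed=0) -> np.ndarray:
    """Map a class series to a 2D path on the triangle corners with jitter.

    Returns an (n, 2) array; with ``noise_sd`` 0 each point sits exactly on
    its class corner. Jitter is isotropic Gaussian, reproducible by seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    pts = np.array([TRIANGLE_CORNERS[c] for c in series], float) \
        if series else np.empty((0, 2))
    if noise_sd > 0 and len(pts):
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    return pts
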