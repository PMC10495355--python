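"""Population classes from local density and cluster size.

A cell at one time point is characterized by two numbers: the area V of its
Voronoi polygon (px^2, inverse local density) and the size N of its dilation
cluster (cells per cluster, possibly non-integer). The decision rules:

* loner:  log10(V) <= 4.5 and N <= 2   (crowded neighbourhood, no group)
* scout:  log10(V) >= 4.5 and N <= 20  (isolated cell or small group)
* swarm:  log10(V) <= 4.5 and N > 2    (dense multicellular cluster)

The boundary log10(V) = 4.5 with N <= 2 satisfies both the loner and the
scout rule; the tie is broken in favour of scout (isolation is the marked
condition). The region log10(V) > 4.5 with N > 20 is covered by no rule and
is labelled ``unclassified`` rather than silently assigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["classify", "motile_filter", "Histogram2D", "histogram2d",
           "difference", "mean_histogram", "LOG10V_BOUNDARY",
           "LONER_MAX_N", "SCOUT_MAX_N"]

LOG10V_BOUNDARY = 4.5
LONER_MAX_N = 2.0
SCOUT_MAX_N = 20.0


def classify(log10V: float, N: float, *,
             log10v_boundary: float = LOG10V_BOUNDARY,
             loner_max_n: float = LONER_MAX_N,
             scout_max_n: float = SCOUT_MAX_N) -> str:
    """Class label for one (log10 Voronoi area, cluster size) pair.

    Total and deterministic: exactly one of {scout, loner, swarm,
    unclassified} for any finite input with N > 0.
    """
    if not np.isfinite(log10V) or not np.isfinite(N):
        raise ValueError("log10V and N must be finite")
    if N <= 0:
        raise ValueError("N must be > 0")
    if log10V >= log10v_boundary:
        return "scout" if N <= scout_max_n else "unclassified"
    return "loner" if N <= loner_max_n else "swarm"


def motile_filter(track, threshold_px: float = 2.0,
                  normalized: bool = False) -> bool:
    """True iff the track's end-to-end displacement exceeds the threshold.

    The comparison is strict: a displacement exactly at the threshold is
    rejected. With ``normalized=True`` the displacement is divided by the
    track length in frames before comparison (the per-frame variant used for
    some motile-only histograms).
    """
    xy = np.asarray(track, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("track must be an (n, 2) array")
    if len(xy) < 2:
        return False
    disp = float(np.hypot(*(xy[-1] - xy[0])))
    if normalized:
        disp = disp / len(xy)
    return disp > threshold_px


@dataclass
class Histogram2D:
    """Normalized 2D histogram over (log10V, N) with shared bin edges."""

    counts: np.ndarray           # (n_v_bins, n_n_bins), sums to 1 (or ~0 for diffs)
    log10v_edges: np.ndarray
    n_edges: np.ndarray
    meta: dict | None = None

    def _check_compatible(self, other: "Histogram2D") -> None:
        if (self.counts.shape != other.counts.shape
                or not np.allclose(self.log10v_edges, other.log10v_edges)
                or not np.allclose(self.n_edges, other.n_edges)):
            raise ValueError("histograms have mismatched bin edges")


def default_edges(n_bins: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Default binning: linear over log10V in [2, 7], log-spaced over N in [1, 1e3]."""
    return np.linspace(2.0, 7.0, n_bins + 1), np.logspace(0.0, 3.0, n_bins + 1)


def histogram2d(log10V, N, log10v_edges=None, n_edges=None,
                meta: dict | None = None) -> Histogram2D:
    """Unit-mass 2D histogram of per-cell (log10V, N) observations."""
    if log10v_edges is None or n_edges is None:
        d_v, d_n = default_edges()
        log10v_edges = d_v if log10v_edges is None else np.asarray(log10v_edges)
        n_edges = d_n if n_edges is None else np.asarray(n_edges)
    counts, _, _ = np.histogram2d(np.asarray(log10V, float), np.asarray(N, float),
                                  bins=[log10v_edges, n_edges])
    total = counts.sum()
    if total > 0:
        counts = counts / total
    return Histogram2D(counts, np.asarray(log10v_edges), np.asarray(n_edges), meta)


def mean_histogram(histograms: list[Histogram2D]) -> Histogram2D:
    """Mean of per-replicate normalized histograms (each already unit mass)."""
    if not histograms:
        raise ValueError("need at least one histogram")
    first = histograms[0]
    for h in histograms[1:]:
        first._check_compatible(h)
    counts = np.mean([h.counts for h in histograms], axis=0)
    return Histogram2D(counts, first.log10v_edges, first.n_edges,
                       {"n_replicates": len(histograms)})


def difference(h_a: Histogram2D, h_b: Histogram2D) -> Histogram2D:
    """Bin-wise difference of two normalized histograms (sums to ~0)."""
    h_a._check_compatible(h_b)
    return Histogram2D(h_a.counts - h_b.counts, h_a.log10v_edges, h_a.n_edges,
                       {"difference": True})
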