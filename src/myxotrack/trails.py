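"""Trail maps and structural-similarity overlap between trail populations.

Trajectories are rasterized onto a pixel grid by 8-connected line segments;
each touched pixel aggregates the frame times of its visits by mean,
yielding a time-coloured trail map. To quantify trail sharing between two
populations (scouts versus the rest), their binarized occupancy maps are
compared with the structural similarity index (SSIM) over a 3-px sliding
window; thresholding the SSIM map and taking connected components gives the
shared trail segments and their areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.metrics import structural_similarity

__all__ = ["TrailMap", "SimilarityMap", "rasterize_trails",
           "similarity_index_map", "shared_trail_lengths", "split_by_class"]


@dataclass
class TrailMap:
    """Raster of trajectory occupancy; values are mean visit times (frames).

    ``values`` holds the time-mean on visited pixels and ``background``
    (default NaN) elsewhere; ``occupancy`` is the boolean visited mask.
    """

    values: np.ndarray
    occupancy: np.ndarray
    background: float = np.nan


def rasterize_trails(tracks: list[np.ndarray],
                     grid_shape: tuple[int, int],
                     frames: list[np.ndarray] | None = None,
                     background: float = np.nan) -> TrailMap:
    """Rasterize trajectories onto a grid, aggregating visit times by mean.

    ``tracks`` are (n, 2) arrays of (row, col) positions already expressed
    in grid coordinates; ``frames`` optionally gives per-point frame times
    (defaults to 0..n-1 per track). Consecutive points are joined by
    8-connected discrete segments; every pixel a segment touches records
    the time of the segment's starting point. Aggregation by mean makes the
    result independent of track input order.
    """
    h, w = grid_shape
    total = np.zeros((h, w))
    count = np.zeros((h, w), dtype=int)
    for k, xy in enumerate(tracks):
        xy = np.asarray(xy, float)
        if xy.ndim != 2 or xy.shape[1] != 2 or len(xy) == 0:
            raise ValueError("each track must be a nonempty (n, 2) array")
        tt = (np.arange(len(xy), dtype=float) if frames is None
              else np.asarray(frames[k], float))
        ri = np.clip(np.rint(xy[:, 0]).astype(int), 0, h - 1)
        ci = np.clip(np.rint(xy[:, 1]).astype(int), 0, w - 1)
        if len(xy) == 1:
            total[ri[0], ci[0]] += tt[0]
            count[ri[0], ci[0]] += 1
            continue
        for i in range(len(xy) - 1):
            rr, cc = draw_line(ri[i], ci[i], ri[i + 1], ci[i + 1])
            if i < len(xy) - 2:       # avoid double-counting shared vertices
                rr, cc = rr[:-1], cc[:-1]
            total[rr, cc] += tt[i]
            count[rr, cc] += 1
    occupancy = count > 0
    values = np.full((h, w), background, dtype=float)
    values[occupancy] = total[occupancy] / count[occupancy]
    return TrailMap(values, occupancy, background)


@dataclass
class SimilarityMap:
    """Per-pixel structural similarity of two binary occupancy maps."""

    values: np.ndarray       # in [-1, 1]
    window: int


def similarity_index_map(map_a, map_b, window: int = 3) -> SimilarityMap:
    """SSIM map between two binarized trail maps (3-px sliding window).

    Accepts TrailMap objects or arrays; arrays are binarized as "> 0 and
    finite" first. Uses the standard stabilizing constants
    C1 = (0.01 L)^2, C2 = (0.03 L)^2 with dynamic range L = 1.
    """
    a = _binarize(map_a)
    b = _binarize(map_b)
    if a.shape != b.shape:
        raise ValueError("maps must share a shape")
    if window % 2 != 1 or window > min(a.shape):
        raise ValueError("window must be odd and fit inside the maps")
    _, smap = structural_similarity(a.astype(float), b.astype(float),
                                    win_size=window, data_range=1.0,
                                    gaussian_weights=False, full=True)
    return SimilarityMap(smap, window)


def _binarize(m) -> np.ndarray:
    if isinstance(m, TrailMap):
        return m.occupancy
    arr = np.asarray(m, float)
    return np.isfinite(arr) & (arr > 0)


def shared_trail_lengths(sim_map: SimilarityMap | np.ndarray,
                         threshold: float = 0.5,
                         restrict_to=None) -> tuple[list[int], np.ndarray]:
    """Areas of connected shared-trail segments in a similarity map.

    The map is thresholded at ``threshold``; when ``restrict_to`` (a binary
    occupancy map) is given, only pixels that actually carry trail are kept,
    so that featureless background (similar by vacuity) does not count.
    Returns per-component pixel areas (descending) and the labeled
    component image.
    """
    vals = sim_map.values if isinstance(sim_map, SimilarityMap) else np.asarray(sim_map)
    mask = vals >= threshold
    if restrict_to is not None:
        mask = mask & _binarize(restrict_to)
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
    areas = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
    return sorted((int(a) for a in areas), reverse=True), lab


def split_by_class(tracks_xy: list[np.ndarray],
                   tracks_classes: list[list[str]],
                   scout_class: str = "scout"
                   ) -> tuple[list[np.ndarray], list[np.ndarray],
                              list[np.ndarray], list[np.ndarray]]:
    """Partition trajectory segments framewise into scout versus the rest.

    Cells change class mid-track, so a track contributes each contiguous
    run of frames to the population of the class it holds during that run.
    Returns (scout_tracks, scout_frames, rest_tracks, rest_frames).
    """
    s_xy, s_fr, r_xy, r_fr = [], [], [], []
    for xy, classes in zip(tracks_xy, tracks_classes):
        xy = np.asarray(xy, float)
        if len(xy) != len(classes):
            raise ValueError("track and class series lengths differ")
        start = 0
        for i in range(1, len(classes) + 1):
            scouty = classes[start] == scout_class
            if i == len(classes) or (classes[i] == scout_class) != scouty:
                seg = xy[start:i]
                fr = np.arange(start, i, dtype=float)
                if scouty:
                    s_xy.append(seg); s_fr.append(fr)
                else:
                    r_xy.append(seg); r_fr.append(fr)
                start = i
    return s_xy, s_fr, r_xy, r_fr
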