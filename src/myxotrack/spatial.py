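"""Per-frame spatial descriptors for segmented cells.

Three quantities feed the population classifier:

* mask backbones — topological skeletons; masks whose skeleton contains a
  branchpoint (a likely segmentation fusion) are split at the branchpoint
  and each resulting segment contributes its own midpoint;
* Voronoi polygon areas V at the backbone midpoints, clipped to the field
  rectangle — 1/V is the local cell density;
* long-range clusters from morphological dilation of the binary masks with
  a square kernel (default 10 px ~ 1 um); cluster size N = summed
  non-dilated member area / mean single-cell area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box
from skimage.morphology import skeletonize

__all__ = ["Backbone", "DensityRecord", "Cluster", "extract_backbone",
           "voronoi_areas", "cluster_cells", "dilation_offsets"]


@dataclass
class Backbone:
    """Skeleton of one mask, split at branchpoints into simple segments."""

    segments: list[np.ndarray]        # ordered (n, 2) pixel paths
    lengths: list[float]              # geodesic length per segment, px
    midpoints: list[tuple[float, float]]
    tortuosities: list[float]         # path length / end-to-end distance
    branchpoint_count: int

    @property
    def total_length(self) -> float:
        return float(sum(self.lengths))


_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(pixels: set[tuple[int, int]]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(pixels)
    for (r, c) in pixels:
        for dr, dc in _NBRS:
            q = (r + dr, c + dc)
            if q in pixels and (r, c) < q:
                g.add_edge((r, c), q, weight=float(np.hypot(dr, dc)))
    return g


def _geodesic_path(g: nx.Graph, nodes: list) -> tuple[list, float]:
    """Longest shortest path (geodesic diameter) within one component."""
    if len(nodes) == 1:
        return list(nodes), 0.0
    # two-sweep heuristic is exact on trees; skeleton segments are near-trees
    src = min(nodes)
    dist = nx.single_source_dijkstra_path_length(g, src, weight="weight")
    far1 = max(sorted(dist), key=lambda n: dist[n])
    dist1, paths1 = nx.single_source_dijkstra(g, far1, weight="weight")
    far2 = max(sorted(dist1), key=lambda n: dist1[n])
    return paths1[far2], float(dist1[far2])


def _path_midpoint(path: list, length: float) -> tuple[float, float]:
    """Point on the polyline path at half of its arc length."""
    if len(path) == 1 or length == 0.0:
        return tuple(map(float, path[0]))
    half = length / 2.0
    acc = 0.0
    for a, b in zip(path[:-1], path[1:]):
        step = float(np.hypot(b[0] - a[0], b[1] - a[1]))
        if acc + step >= half:
            frac = (half - acc) / step
            return (a[0] + frac * (b[0] - a[0]), a[1] + frac * (b[1] - a[1]))
        acc += step
    return tuple(map(float, path[-1]))


def extract_backbone(mask: np.ndarray) -> Backbone:
    """Skeletonize a binary mask and split the skeleton at branchpoints.

    Branchpoints (skeleton pixels with three or more skeleton neighbours)
    are deleted; each remaining connected piece is reported as a segment
    with its geodesic length, midpoint and tortuosity (path length over
    end-to-end distance; 1 for a straight segment, inf for a closed loop).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    skel = skeletonize(mask)
    pixels = set(zip(*np.nonzero(skel)))
    # neighbour counts on the full skeleton
    branchpoints = set()
    for p in pixels:
        deg = sum((p[0] + dr, p[1] + dc) in pixels for dr, dc in _NBRS)
        if deg >= 3:
            branchpoints.add(p)
    kept = pixels - branchpoints
    if not kept:                       # degenerate: all pixels are branchpoints
        kept = pixels
        branchpoints = set()
    g = _skeleton_graph(kept)
    segments, lengths, midpoints, torts = [], [], [], []
    for comp in sorted(nx.connected_components(g), key=min):
        sub = g.subgraph(comp)
        path, length = _geodesic_path(sub, list(comp))
        segments.append(np.asarray(path, float))
        lengths.append(length)
        midpoints.append(_path_midpoint(path, length))
        e2e = float(np.hypot(path[-1][0] - path[0][0], path[-1][1] - path[0][1]))
        torts.append(length / e2e if e2e > 0 else (1.0 if length == 0 else np.inf))
    return Backbone(segments, lengths, midpoints, torts, len(branchpoints))


@dataclass
class DensityRecord:
    """Voronoi polygon area of one seed, clipped to the field rectangle."""

    index: int                 # position in the input seed list
    area_px2: float

    @property
    def density(self) -> float:
        return 1.0 / self.area_px2


def voronoi_areas(points, bounds: tuple[int, int]) -> list[DensityRecord]:
    """Areas of the Voronoi cells of ``points``, clipped to ``bounds`` (H, W).

    Unbounded border cells are closed exactly by tessellating the seeds
    together with their mirror images across the four field edges: the
    resulting polygons, intersected with the field rectangle, are identical
    to the clipped cells of the original tessellation. Duplicate seeds are
    perturbed by a deterministic epsilon with a warning.
    """
    pts = np.asarray(points, float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("need at least one seed point")
    h, w = bounds
    if len(pts) == 1:
        return [DensityRecord(0, float(h) * float(w))]

    seen: dict[tuple[float, float], int] = {}
    pts = pts.copy()
    for i, p in enumerate(pts):
        key = (round(p[0], 9), round(p[1], 9))
        if key in seen:
            warnings.warn("duplicate Voronoi seed perturbed by epsilon")
            pts[i] += 1e-6 * (1 + i)
        else:
            seen[key] = i

    mirrored = np.concatenate([
        pts,
        pts * [-1, 1],                     # across row = 0
        pts * [1, -1],                     # across col = 0
        [2 * h, 0] + pts * [-1, 1],        # across row = h
        [0, 2 * w] + pts * [1, -1],        # across col = w
    ])
    vor = Voronoi(mirrored)
    rect = box(0.0, 0.0, float(h), float(w))
    out = []
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region])
        clipped = poly.intersection(rect)
        out.append(DensityRecord(i, float(clipped.area)))
    return out


@dataclass
class Cluster:
    """Cells whose dilated masks merge into one connected component."""

    cluster_id: int
    members: list[int] = field(default_factory=list)
    area_px2: float = 0.0      # summed NON-dilated member pixel area
    N: float = 0.0             # area_px2 / mean single-cell area


def dilation_offsets(kernel_px: int) -> np.ndarray:
    """Offsets of the square dilation kernel around its anchor.

    Even kernels have no exact centre; the anchor is fixed at the top-left
    element of the 2x2 centre block (index k//2 - 1), so a 10-px kernel
    reaches 4 px up/left and 5 px down/right.
    """
    a = (kernel_px - 1) // 2
    return np.arange(kernel_px) - a


def _dilate(binary: np.ndarray, kernel_px: int) -> np.ndarray:
    if kernel_px == 1:
        return binary.copy()
    structure = np.ones((kernel_px, kernel_px), bool)
    # scipy anchors at k//2; shift origin to our k//2-1 anchor for even k
    origin = -1 if kernel_px % 2 == 0 else 0
    return ndimage.binary_dilation(binary, structure=structure,
                                   origin=(origin, origin))


def cluster_cells(label_image: np.ndarray, kernel_px: int = 10,
                  mean_cell_area: float | None = None,
                  fallback_cell_area: float = 200.0) -> list[Cluster]:
    """Group cells into long-range clusters by square-kernel dilation.

    Connected components (8-connectivity) of the dilated binary union define
    the clusters; each cluster's area is the summed area of its non-dilated
    member masks and N = area / mean single-cell area. When
    ``mean_cell_area`` is not given it is estimated as the median area of
    masks that form single-member clusters in this frame, falling back to
    ``fallback_cell_area`` when every mask is clustered.
    """
    label_image = np.asarray(label_image)
    if kernel_px < 1:
        raise ValueError("kernel_px must be >= 1")
    ids = np.unique(label_image)
    ids = ids[ids > 0]
    if len(ids) == 0:
        return []
    binary = label_image > 0
    dilated = _dilate(binary, kernel_px)
    comp, _ = ndimage.label(dilated, structure=np.ones((3, 3), bool))
    areas = ndimage.sum_labels(np.ones_like(label_image), label_image, ids)
    # each mask lies inside exactly one dilated component
    first_idx = {}
    rows, cols = np.nonzero(label_image)
    vals = label_image[rows, cols]
    for lab in ids:
        k = np.argmax(vals == lab)
        first_idx[int(lab)] = (rows[k], cols[k])
    membership: dict[int, list[int]] = {}
    for lab, area in zip(ids, areas):
        cid = int(comp[first_idx[int(lab)]])
        membership.setdefault(cid, []).append(int(lab))
    clusters = []
    area_of = {int(lab): float(a) for lab, a in zip(ids, areas)}
    if mean_cell_area is None:
        singles = [area_of[m[0]] for m in membership.values() if len(m) == 1]
        mean_cell_area = float(np.median(singles)) if singles else fallback_cell_area
    if mean_cell_area <= 0:
        raise ValueError("mean_cell_area must be > 0")
    for new_id, cid in enumerate(sorted(membership)):
        members = sorted(membership[cid])
        total = sum(area_of[m] for m in members)
        clusters.append(Cluster(new_id, members, total, total / mean_cell_area))
    return clusters
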