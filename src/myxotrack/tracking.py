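"""Frame-to-frame linking of segmented cell masks into trajectories.

Candidate links between consecutive frames are scored by a weighted
combination of three similarity criteria — mask overlap, area and backbone
length — with weights derived from a pairwise-comparison matrix by the
Analytic Hierarchy Process (AHP): the weight vector is the normalized
principal eigenvector of the positive reciprocal matrix. The default matrix
ranks overlap above area above length (3:1 and 2:1), which is what
disambiguates links in densely packed regions. One-to-one assignments per
frame pair are found with the Hungarian algorithm and chained into maximal
tracks; a mask that absorbs two predecessors (a segmentation fusion)
terminates the incoming tracks rather than merging them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage.measure import regionprops

from .spatial import extract_backbone

__all__ = ["CellMask", "LinkCandidate", "FrameLinks", "Track",
           "ahp_weights", "consistency_ratio", "DEFAULT_AHP_MATRIX",
           "masks_from_labels", "score_links", "link_frames",
           "assemble_tracks", "track_label_stack"]

#: overlap : area : length at 3:1 and 2:1 (perfectly consistent)
DEFAULT_AHP_MATRIX = np.array([[1.0, 3.0, 6.0],
                               [1 / 3, 1.0, 2.0],
                               [1 / 6, 1 / 2, 1.0]])

_AHP_RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.9, 5: 1.12}


def _check_reciprocal(m: np.ndarray) -> None:
    m = np.asarray(m, float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("AHP matrix must be square")
    if np.any(m <= 0):
        raise ValueError("AHP matrix must be positive")
    if not np.allclose(m * m.T, 1.0, rtol=1e-6):
        raise ValueError("AHP matrix must be reciprocal (a_ij = 1/a_ji)")


def ahp_weights(matrix: np.ndarray = DEFAULT_AHP_MATRIX) -> np.ndarray:
    """Criterion weights: normalized principal eigenvector of the matrix."""
    _check_reciprocal(matrix)
    vals, vecs = np.linalg.eig(np.asarray(matrix, float))
    k = int(np.argmax(vals.real))
    w = np.abs(vecs[:, k].real)
    return w / w.sum()


def consistency_ratio(matrix: np.ndarray) -> float:
    """Saaty consistency ratio; < 0.1 is conventionally acceptable."""
    _check_reciprocal(matrix)
    m = np.asarray(matrix, float)
    n = m.shape[0]
    lam = float(np.max(np.linalg.eigvals(m).real))
    if n <= 2:
        return 0.0
    ci = (lam - n) / (n - 1)
    return ci / _AHP_RANDOM_INDEX[n]


@dataclass
class CellMask:
    frame: int
    label: int
    area_px2: int
    length_px: float                 # backbone (skeleton) length
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    pixels: np.ndarray = field(repr=False, default=None)  # sorted linear indices


def masks_from_labels(label_image: np.ndarray, frame: int,
                      compute_length: bool = True) -> list[CellMask]:
    """Extract per-cell mask descriptors from one label image."""
    label_image = np.asarray(label_image)
    _, w = label_image.shape
    out = []
    for rp in regionprops(label_image):
        rows, cols = np.nonzero(label_image == rp.label)
        lin = np.sort(rows * w + cols)
        if compute_length:
            sub = label_image[rp.bbox[0]:rp.bbox[2], rp.bbox[1]:rp.bbox[3]] == rp.label
            length = extract_backbone(sub).total_length
        else:
            length = float(rp.axis_major_length)
        out.append(CellMask(frame, int(rp.label), int(rp.area), float(length),
                            tuple(rp.centroid), tuple(rp.bbox), lin))
    return out


@dataclass
class LinkCandidate:
    mask_t: CellMask
    mask_t1: CellMask
    overlap_px2: int
    area_ratio: float      # min/max, in (0, 1]
    length_ratio: float
    score: float           # AHP-weighted similarity, in [0, 1]


def _overlap(a: CellMask, b: CellMask) -> int:
    if (a.bbox[2] <= b.bbox[0] or b.bbox[2] <= a.bbox[0]
            or a.bbox[3] <= b.bbox[1] or b.bbox[3] <= a.bbox[1]):
        return 0
    return len(np.intersect1d(a.pixels, b.pixels, assume_unique=True))


def score_links(masks_t: list[CellMask], masks_t1: list[CellMask],
                search_radius: float = 30.0,
                ahp_matrix: np.ndarray = DEFAULT_AHP_MATRIX) -> list[LinkCandidate]:
    """Score all admissible links between two consecutive frames.

    A pair is admissible when the centroids are within ``search_radius`` px
    or the masks overlap. Criterion similarities, each in [0, 1]:
    overlap / min(areas); min/max of areas; min/max of lengths. The
    composite score is their AHP-weighted sum.
    """
    w = ahp_weights(ahp_matrix)
    out = []
    for a in masks_t:
        for b in masks_t1:
            dist = np.hypot(a.centroid[0] - b.centroid[0],
                            a.centroid[1] - b.centroid[1])
            ov = _overlap(a, b)
            if dist > search_radius and ov == 0:
                continue
            s_overlap = ov / min(a.area_px2, b.area_px2)
            s_area = min(a.area_px2, b.area_px2) / max(a.area_px2, b.area_px2)
            mx = max(a.length_px, b.length_px)
            s_len = 1.0 if mx == 0 else min(a.length_px, b.length_px) / mx
            score = float(w @ [s_overlap, s_area, s_len])
            out.append(LinkCandidate(a, b, ov, s_area, s_len, score))
    return out


@dataclass
class FrameLinks:
    """One-to-one assignment between two consecutive frames."""

    pairs: list[tuple[int, int, float]]   # (label_t, label_t1, score)
    unmatched_t: list[int]
    unmatched_t1: list[int]
    ambiguous_t: set[int] = field(default_factory=set)
    ambiguous_t1: set[int] = field(default_factory=set)
    fused_t1: set[int] = field(default_factory=set)

    @property
    def total_score(self) -> float:
        return sum(s for _, _, s in self.pairs)


def link_frames(candidates: list[LinkCandidate],
                min_score: float = 0.1) -> FrameLinks:
    """Globally optimal one-to-one assignment among admissible candidates.

    Maximizes the total composite score over candidates with
    score >= ``min_score`` (Hungarian method; ties broken toward smaller
    label pairs). Masks with several admissible partners are flagged
    ambiguous; masks at t+1 overlapping two or more predecessors are
    flagged as fusions.
    """
    adm = [c for c in candidates if c.score >= min_score]
    labels_t = sorted({c.mask_t.label for c in candidates})
    labels_t1 = sorted({c.mask_t1.label for c in candidates})
    if not adm:
        return FrameLinks([], labels_t, labels_t1)

    idx_t = {lab: i for i, lab in enumerate(labels_t)}
    idx_t1 = {lab: j for j, lab in enumerate(labels_t1)}
    n, m = len(labels_t), len(labels_t1)
    BIG = 1e6
    size = n + m
    cost = np.zeros((size, size))
    cost[:n, :m] = BIG
    for c in adm:
        i, j = idx_t[c.mask_t.label], idx_t1[c.mask_t1.label]
        # epsilon steers equal-score optima toward smaller label pairs
        cost[i, j] = -c.score + 1e-9 * (i * m + j) / (n * m + 1)
    rows, cols = linear_sum_assignment(cost)
    pairs = []
    matched_t, matched_t1 = set(), set()
    score_of = {(idx_t[c.mask_t.label], idx_t1[c.mask_t1.label]): c.score
                for c in adm}
    for i, j in zip(rows, cols):
        if i < n and j < m and (i, j) in score_of:
            pairs.append((labels_t[i], labels_t1[j], score_of[(i, j)]))
            matched_t.add(labels_t[i])
            matched_t1.add(labels_t1[j])
    pairs.sort()

    links = FrameLinks(pairs,
                       [l for l in labels_t if l not in matched_t],
                       [l for l in labels_t1 if l not in matched_t1])
    succ: dict[int, int] = {}
    pred_overlap: dict[int, int] = {}
    for c in adm:
        succ[c.mask_t.label] = succ.get(c.mask_t.label, 0) + 1
        if c.overlap_px2 > 0:
            lab = c.mask_t1.label
            pred_overlap[lab] = pred_overlap.get(lab, 0) + 1
    pred_adm: dict[int, int] = {}
    for c in adm:
        pred_adm[c.mask_t1.label] = pred_adm.get(c.mask_t1.label, 0) + 1
    links.ambiguous_t = {l for l, k in succ.items() if k >= 2}
    links.ambiguous_t1 = {l for l, k in pred_adm.items() if k >= 2}
    links.fused_t1 = {l for l, k in pred_overlap.items() if k >= 2}
    return links


@dataclass
class Track:
    track_id: int
    items: list[tuple[int, int, tuple[float, float]]]  # (frame, label, centroid)
    flags: set[str] = field(default_factory=set)

    @property
    def frames(self) -> list[int]:
        return [f for f, _, _ in self.items]

    @property
    def coords(self) -> np.ndarray:
        return np.array([c for _, _, c in self.items], float)

    @property
    def duration(self) -> int:
        return len(self.items)

    @property
    def displacement_px(self) -> float:
        xy = self.coords
        return float(np.hypot(*(xy[-1] - xy[0]))) if len(xy) > 1 else 0.0

    @property
    def path_length_px(self) -> float:
        xy = self.coords
        if len(xy) < 2:
            return 0.0
        d = np.diff(xy, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


def assemble_tracks(frame_links: list[FrameLinks],
                    masks_per_frame: list[list[CellMask]],
                    break_at_fusion: bool = True) -> list[Track]:
    """Chain per-pair assignments into maximal tracks.

    ``frame_links[t]`` links frame t to t+1. A missing link terminates the
    track; the next appearance of the mask chain starts a new id. With
    ``break_at_fusion`` (default), a link into a fusion-flagged mask is cut
    so that fused masks start fresh tracks instead of inheriting one
    predecessor's identity.
    """
    n_frames = len(masks_per_frame)
    centroid = {}
    for t, masks in enumerate(masks_per_frame):
        for mk in masks:
            centroid[(t, mk.label)] = mk.centroid

    succ: dict[tuple[int, int], tuple[int, int]] = {}
    fused_flags: set[tuple[int, int]] = set()
    ambiguous: set[tuple[int, int]] = set()
    for t, links in enumerate(frame_links):
        for lab_t, lab_t1, _ in links.pairs:
            if break_at_fusion and lab_t1 in links.fused_t1:
                fused_flags.add((t + 1, lab_t1))
                continue
            key = (t, lab_t)
            assert key not in succ, "mask linked twice"
            succ[key] = (t + 1, lab_t1)
        for lab in links.ambiguous_t:
            ambiguous.add((t, lab))
        for lab in links.fused_t1:
            fused_flags.add((t + 1, lab))

    has_pred = set(succ.values())
    tracks: list[Track] = []
    starts = sorted(k for k in centroid if k not in has_pred)
    for start in starts:
        items = []
        node = start
        flags = set()
        while True:
            items.append((node[0], node[1], centroid[node]))
            if node in ambiguous:
                flags.add("ambiguous")
            if node in fused_flags:
                flags.add("fusion")
            if node not in succ:
                break
            node = succ[node]
        tracks.append(Track(len(tracks), items, flags))

    seen: set[tuple[int, int]] = set()
    for tr in tracks:
        fcount: dict[int, int] = {}
        for f, lab, _ in tr.items:
            assert (f, lab) not in seen, "mask appears in two tracks"
            seen.add((f, lab))
            fcount[f] = fcount.get(f, 0) + 1
        assert all(v == 1 for v in fcount.values()), "two masks in one frame"
    assert n_frames >= 0
    return tracks


def track_label_stack(labels: np.ndarray, search_radius: float = 30.0,
                      min_score: float = 0.1,
                      ahp_matrix: np.ndarray = DEFAULT_AHP_MATRIX,
                      compute_length: bool = True) -> list[Track]:
    """Full tracking of a (T, H, W) label stack."""
    masks = [masks_from_labels(labels[t], t, compute_length)
             for t in range(labels.shape[0])]
    links = [link_frames(score_links(masks[t], masks[t + 1],
                                     search_radius, ahp_matrix), min_score)
             for t in range(labels.shape[0] - 1)]
    return assemble_tracks(links, masks)
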