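"""Synthetic predation-scene generator.

Produces per-frame predator label masks, a prey fluorescence stack and full
ground truth with the statistical structure the analysis stages assume:

* rod-shaped (capsule) cells rendered into integer label images;
* three motion regimes — directed (persistent heading), Brownian and
  confined (reflecting disk) — matching the sub-/super-diffusive signatures
  the mean-squared-displacement analysis distinguishes;
* cohesive multi-cell swarm groups plus isolated scouts and loners, with
  stochastic class transitions at configured per-frame rates;
* a prey lawn whose fluorescence decays behind an advancing invasion front;
* Gaussian excitation illumination, exponential photobleaching and additive
  noise on the prey channel.

Coordinates are (row, col), 0-based, origin top-left; frames are 0-based.
All randomness flows from a single seed, split per cell by id, so output is
bit-identical across reruns and independent of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CLASSES, SimConfig

__all__ = [
    "GroundTruth",
    "simulate_motion",
    "simulate_scene",
    "render_fluorescence",
    "gaussian_profile",
    "build_prey_field",
]


@dataclass
class GroundTruth:
    """True per-cell state of a simulated scene.

    ``positions`` has one row per (cell_id, frame): true centroid (row, col),
    orientation (radians) and true class label. ``events`` lists class
    changes as dicts with keys cell_id, frame, from, to, where ``frame`` is
    the first frame holding the new class.
    """

    positions: pd.DataFrame
    events: list[dict] = field(default_factory=list)
    prey_field: np.ndarray | None = None     # (T, H, W) noiseless prey truth
    config: SimConfig | None = None
    group_paths: np.ndarray | None = None    # (n_groups, T, 2) latent centroids

    def track_of(self, cell_id: int) -> np.ndarray:
        sel = self.positions[self.positions.cell_id == cell_id].sort_values("frame")
        return sel[["row", "col"]].to_numpy(float)

    def class_series_of(self, cell_id: int) -> list[str]:
        sel = self.positions[self.positions.cell_id == cell_id].sort_values("frame")
        return sel["class"].tolist()

    def validate(self) -> None:
        """Assert internal consistency (one class per cell-frame; events match)."""
        dup = self.positions.duplicated(["cell_id", "frame"]).any()
        if dup:
            raise AssertionError("duplicate (cell_id, frame) in ground truth")
        for ev in self.events:
            sel = self.positions[(self.positions.cell_id == ev["cell_id"])
                                 & (self.positions.frame == ev["frame"])]
            if len(sel) != 1 or sel["class"].iloc[0] != ev["to"]:
                raise AssertionError(f"event inconsistent with labels: {ev}")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_motion(mode: str, n_steps: int, params: dict | None = None,
                    seed=0) -> np.ndarray:
    """Simulate one trajectory; returns ``n_steps + 1`` (row, col) positions.

    Modes
    -----
    ``directed``
        Constant ``speed`` (px/frame) along a heading performing a random
        walk with standard deviation ``heading_sd`` (rad/frame). With zero
        heading noise this is ballistic motion (MSD exponent 2).
    ``brownian``
        Independent Gaussian displacements with per-axis ``step_sd`` (px).
        MSD exponent 1.
    ``confined``
        Brownian steps reflected at a disk of ``radius`` px centred on the
        start point; the walker never leaves the disk, and the MSD saturates
        (fitted exponent below 1).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    params = params or {}
    rng = _rng(seed)
    pos = np.zeros((n_steps + 1, 2))
    start = np.asarray(params.get("start", (0.0, 0.0)), float)
    pos[0] = start

    if mode == "directed":
        speed = float(params.get("speed", 1.0))
        heading_sd = float(params.get("heading_sd", 0.0))
        if speed < 0:
            raise ValueError("directed speed must be >= 0")
        if heading_sd < 0:
            raise ValueError("heading_sd must be >= 0")
        theta = float(params.get("heading", rng.uniform(0, 2 * np.pi)))
        for t in range(n_steps):
            theta += rng.normal(0.0, heading_sd) if heading_sd > 0 else 0.0
            pos[t + 1] = pos[t] + speed * np.array([np.cos(theta), np.sin(theta)])
    elif mode == "brownian":
        step_sd = float(params.get("step_sd", 1.0))
        if step_sd <= 0:
            raise ValueError("brownian step_sd must be > 0")
        steps = rng.normal(0.0, step_sd, size=(n_steps, 2))
        pos[1:] = pos[0] + np.cumsum(steps, axis=0)
    elif mode == "confined":
        step_sd = float(params.get("step_sd", 1.0))
        radius = float(params.get("radius", 5.0))
        if step_sd <= 0:
            raise ValueError("confined step_sd must be > 0")
        if radius <= 0:
            raise ValueError("confinement radius must be > 0")
        center = pos[0].copy()
        for t in range(n_steps):
            nxt = pos[t] + rng.normal(0.0, step_sd, size=2)
            nxt = _reflect_into_disk(nxt, center, radius)
            pos[t + 1] = nxt
    else:
        raise ValueError(f"unknown motion mode: {mode!r}")
    return pos


def _reflect_into_disk(p: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Radially reflect a point back into the disk; clamp pathological jumps."""
    d = p - center
    r = float(np.hypot(*d))
    if r <= radius or r == 0.0:
        return p
    reflected = 2 * radius - r
    if reflected < 0:          # step longer than 2R: land on the boundary
        reflected = radius
    return center + d * (reflected / r)


# ---------------------------------------------------------------------------
# scene simulation


def _markov_class_series(initial: str, n_frames: int, rate: float,
                         rng: np.random.Generator) -> list[str]:
    """Per-frame class labels; each frame switches to each other class w.p. rate."""
    series = [initial]
    idx = CLASSES.index(initial)
    for _ in range(n_frames - 1):
        u = rng.uniform()
        others = [i for i in range(3) if i != idx]
        if u < rate:
            idx = others[0]
        elif u < 2 * rate:
            idx = others[1]
        series.append(CLASSES[idx])
    return series


def _place_positions(n: int, shape: tuple[int, int], margin: float,
                     min_dist: float, rng: np.random.Generator,
                     existing: list[np.ndarray], max_tries: int = 200) -> list[np.ndarray]:
    """Uniform non-overlapping placements; raises after bounded retries."""
    placed: list[np.ndarray] = []
    h, w = shape
    for _ in range(n):
        for _try in range(max_tries):
            p = np.array([rng.uniform(margin, h - margin),
                          rng.uniform(margin, w - margin)])
            all_pts = existing + placed
            if all(np.hypot(*(p - q)) >= min_dist for q in all_pts):
                placed.append(p)
                break
        else:
            raise RuntimeError("could not place cells without overlap "
                               "after bounded retries")
    return placed


def _clamp_margin(p: np.ndarray, shape: tuple[int, int], margin: float) -> np.ndarray:
    h, w = shape
    return np.array([min(max(p[0], margin), h - margin),
                     min(max(p[1], margin), w - margin)])


def paint_capsule(img: np.ndarray, row: float, col: float, theta: float,
                  length: float, width: float, label: int) -> None:
    """Rasterize an axis-capsule (rectangle + semicircular caps) into ``img``.

    Pixels within ``width/2`` of the central segment get ``label``; later
    calls overwrite earlier ones (z-order by call order).
    """
    h, w = img.shape
    half = max(0.0, (length - width) / 2.0)
    u = np.array([np.cos(theta), np.sin(theta)])
    a = np.array([row, col]) - half * u
    b = np.array([row, col]) + half * u
    rad = width / 2.0
    r0 = int(np.floor(min(a[0], b[0]) - rad - 1)); r1 = int(np.ceil(max(a[0], b[0]) + rad + 1))
    c0 = int(np.floor(min(a[1], b[1]) - rad - 1)); c1 = int(np.ceil(max(a[1], b[1]) + rad + 1))
    r0, r1 = max(r0, 0), min(r1, h - 1)
    c0, c1 = max(c0, 0), min(c1, w - 1)
    if r0 > r1 or c0 > c1:
        return
    rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    pts = np.stack([rr, cc], axis=-1).astype(float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        dist = np.linalg.norm(pts - a, axis=-1)
    else:
        tt = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
        proj = a + tt[..., None] * ab
        dist = np.linalg.norm(pts - proj, axis=-1)
    mask = dist <= rad
    img[r0:r1 + 1, c0:c1 + 1][mask] = label


def gaussian_profile(shape: tuple[int, int], sigma: float | None) -> np.ndarray:
    """Centred 2D Gaussian excitation profile with peak 1; flat if sigma is None."""
    h, w = shape
    if sigma is None:
        return np.ones((h, w))
    if sigma <= 0:
        raise ValueError("illumination sigma must be > 0")
    r = np.arange(h) - (h - 1) / 2.0
    c = np.arange(w) - (w - 1) / 2.0
    return np.exp(-(r[:, None] ** 2 + c[None, :] ** 2) / (2.0 * sigma ** 2))


def build_prey_field(config: SimConfig) -> np.ndarray:
    """Noiseless prey-lawn truth: intensity decays at the lysis rate behind
    a front that starts at ``prey_front_row0`` and advances down the rows."""
    h, w = config.field_size_px
    t = np.arange(config.n_frames, dtype=float)
    rows = np.arange(h, dtype=float)
    if config.prey_front_speed_px > 0:
        arrival = np.maximum(0.0, (rows - config.prey_front_row0)
                             / config.prey_front_speed_px)
    else:
        arrival = np.where(rows <= config.prey_front_row0, 0.0, np.inf)
    # exposure(row, t): frames spent behind the front
    exposure = np.maximum(0.0, t[:, None] - arrival[None, :])     # (T, H)
    decay = np.exp(-config.prey_lysis_rate * exposure)
    field3d = (config.prey_lawn_intensity
               * np.broadcast_to(decay[:, :, None], (config.n_frames, h, w)))
    return field3d.astype(np.float32)


def render_fluorescence(prey_field: np.ndarray,
                        illumination_sigma: float | None = None,
                        bleach_rate: float = 0.0,
                        noise_sd: float = 0.0,
                        seed=0) -> np.ndarray:
    """Apply optics to a noiseless prey field.

    pixel = truth * Gaussian excitation profile * exp(-bleach_rate * t)
    + Gaussian noise, clipped at zero.
    """
    if bleach_rate < 0:
        raise ValueError("bleach_rate must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed)
    n_frames, h, w = prey_field.shape
    profile = gaussian_profile((h, w), illumination_sigma)
    t = np.arange(n_frames, dtype=float)
    bleach = np.exp(-bleach_rate * t)
    out = prey_field * profile[None, :, :] * bleach[:, None, None]
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return np.clip(out, 0.0, None).astype(np.float32)


class _Cell:
    __slots__ = ("cid", "pos", "theta", "anchor", "group", "rng", "offset")

    def __init__(self, cid, pos, theta, rng):
        self.cid = cid
        self.pos = np.asarray(pos, float)
        self.theta = float(theta)
        self.anchor = self.pos.copy()
        self.group = None
        self.offset = np.zeros(2)
        self.rng = rng


def simulate_scene(config: SimConfig) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Simulate a full predation scene.

    Returns ``(labels, prey, truth)`` where ``labels`` is a (T, H, W) uint16
    stack of predator cell instances (0 = background), ``prey`` a (T, H, W)
    float32 fluorescence stack, and ``truth`` the :class:`GroundTruth`.
    """
    h, w = config.field_size_px
    T = config.n_frames
    margin = config.cell_length_px / 2.0 + 2.0
    master = np.random.default_rng(config.seed)

    n_cells = config.n_cells
    labels = np.zeros((T, h, w), dtype=np.uint16)
    if n_cells == 0:
        prey = render_fluorescence(build_prey_field(config),
                                   config.illumination_sigma_px,
                                   config.bleach_rate, config.noise_sd,
                                   np.random.default_rng([config.seed, 2 ** 20]))
        truth = GroundTruth(pd.DataFrame(columns=["cell_id", "frame", "row", "col",
                                                  "orientation", "class", "group"]),
                            [], build_prey_field(config), config)
        return labels, prey, truth

    # --- initial placement -------------------------------------------------
    placement_rng = np.random.default_rng([config.seed, 1])
    min_dist = config.cell_length_px
    scout_pos = _place_positions(config.n_scouts, (h, w), margin, min_dist,
                                 placement_rng, [])
    loner_pos = _place_positions(config.n_loners, (h, w), margin, min_dist,
                                 placement_rng, scout_pos)
    group_margin = margin + config.swarm_cohesion_radius_px
    group_centers = _place_positions(
        config.n_swarms, (h, w), min(group_margin, min(h, w) / 2.0),
        2 * config.swarm_cohesion_radius_px + min_dist,
        placement_rng, scout_pos + loner_pos)

    # --- group centroid paths (directed, optionally following a scout) -----
    scout_paths: list[np.ndarray] = []
    cells: list[_Cell] = []
    cid = 0
    init_class: list[str] = []
    for p in scout_pos:
        rng = np.random.default_rng([config.seed, 2, cid])
        cells.append(_Cell(cid, p, rng.uniform(0, 2 * np.pi), rng))
        init_class.append("scout")
        cid += 1
    for p in loner_pos:
        rng = np.random.default_rng([config.seed, 2, cid])
        cells.append(_Cell(cid, p, rng.uniform(0, 2 * np.pi), rng))
        init_class.append("loner")
        cid += 1

    # pre-simulate scout centroid paths so follower groups can replay them
    for i, cell in enumerate(cells[:config.n_scouts]):
        rng = np.random.default_rng([config.seed, 3, i])
        path = np.empty((T, 2))
        path[0] = cell.pos
        theta = cell.theta
        for t in range(1, T):
            theta += rng.normal(0.0, config.directed_heading_sd)
            step = config.directed_speed_px * np.array([np.cos(theta), np.sin(theta)])
            nxt = _clamp_margin(path[t - 1] + step, (h, w), margin)
            if not np.allclose(nxt, path[t - 1] + step):
                theta += np.pi / 2.0          # graze along the border
            path[t] = nxt
        scout_paths.append(path)

    group_paths: list[np.ndarray] = []
    group_follows: list[bool] = []
    follow_rng = np.random.default_rng([config.seed, 4])
    for g, center in enumerate(group_centers):
        follows = (config.n_scouts > 0
                   and follow_rng.uniform() < config.trail_following)
        group_follows.append(follows)
        if follows:
            # retrace the scout's actual path with a short delay (stigmergy)
            lag = 5
            src = scout_paths[g % config.n_scouts]
            path = np.vstack([np.repeat(src[:1], lag, axis=0), src[:-lag]]) \
                if T > lag else np.repeat(src[:1], T, axis=0)
        else:
            rng = np.random.default_rng([config.seed, 5, g])
            path = np.empty((T, 2))
            path[0] = center
            theta = rng.uniform(0, 2 * np.pi)
            gm = min(group_margin, min(h, w) / 2.0)
            for t in range(1, T):
                theta += rng.normal(0.0, config.directed_heading_sd)
                step = (0.5 * config.directed_speed_px
                        * np.array([np.cos(theta), np.sin(theta)]))
                nxt = _clamp_margin(path[t - 1] + step, (h, w), gm)
                if not np.allclose(nxt, path[t - 1] + step):
                    theta += np.pi / 2.0
                path[t] = nxt
        group_paths.append(path)

    # swarm member cells
    for g in range(config.n_swarms):
        for m in range(config.cells_per_swarm):
            rng = np.random.default_rng([config.seed, 2, cid])
            r = config.swarm_cohesion_radius_px * np.sqrt(rng.uniform())
            phi = rng.uniform(0, 2 * np.pi)
            offset = r * np.array([np.cos(phi), np.sin(phi)])
            cell = _Cell(cid, group_paths[g][0] + offset,
                         rng.uniform(0, 2 * np.pi), rng)
            cell.group = g
            cell.offset = offset
            cells.append(cell)
            init_class.append("swarm")
            cid += 1

    # --- class series ------------------------------------------------------
    class_series = []
    for cell, c0 in zip(cells, init_class):
        rng = np.random.default_rng([config.seed, 6, cell.cid])
        series = _markov_class_series(c0, T, config.transition_rate, rng)
        if config.n_swarms == 0:      # no group to join: swarm states degrade
            series = ["loner" if c == "swarm" else c for c in series]
        class_series.append(series)

    events = []
    for cell, series in zip(cells, class_series):
        for t in range(1, T):
            if series[t] != series[t - 1]:
                events.append({"cell_id": cell.cid, "frame": t,
                               "from": series[t - 1], "to": series[t]})

    # --- propagate positions ------------------------------------------------
    records = []
    coh = config.swarm_cohesion_radius_px
    for t in range(T):
        for cell, series in zip(cells, class_series):
            cls = series[t]
            if t > 0:
                prev_cls = series[t - 1]
                if cls != prev_cls:
                    if cls == "loner":
                        cell.anchor = cell.pos.copy()
                    elif cls == "swarm":
                        if config.n_swarms > 0:
                            dists = [np.hypot(*(cell.pos - gp[t]))
                                     for gp in group_paths]
                            cell.group = int(np.argmin(dists))
                            off = cell.pos - group_paths[cell.group][t]
                            nrm = np.hypot(*off)
                            if nrm > coh:
                                off = off * (coh / nrm)
                            cell.offset = off
                if cls == "scout":
                    cell.theta += cell.rng.normal(0.0, config.directed_heading_sd)
                    step = (config.directed_speed_px
                            * np.array([np.cos(cell.theta), np.sin(cell.theta)]))
                    nxt = _clamp_margin(cell.pos + step, (h, w), margin)
                    if not np.allclose(nxt, cell.pos + step):
                        cell.theta += np.pi / 2.0
                    cell.pos = nxt
                elif cls == "loner":
                    nxt = cell.pos + cell.rng.normal(0.0, config.brownian_step_sd,
                                                     size=2)
                    nxt = _reflect_into_disk(nxt, cell.anchor,
                                             config.confinement_radius_px)
                    cell.pos = _clamp_margin(nxt, (h, w), margin)
                elif cls == "swarm" and cell.group is not None:
                    cell.offset = cell.offset + cell.rng.normal(
                        0.0, 0.5 * config.brownian_step_sd, size=2)
                    if group_follows[cell.group]:
                        # followers string out along the trail: damp the
                        # offset component perpendicular to the path tangent
                        gpath = group_paths[cell.group]
                        tvec = gpath[t] - gpath[t - 1] if t > 0 else gpath[1] - gpath[0]
                        nt = np.hypot(*tvec)
                        if nt > 1e-9:
                            u = tvec / nt
                            along = (cell.offset @ u) * u
                            cell.offset = along + 0.2 * (cell.offset - along)
                    nrm = np.hypot(*cell.offset)
                    if nrm > coh:
                        cell.offset *= coh / nrm
                    gp = group_paths[cell.group][t]
                    disp = gp + cell.offset - cell.pos
                    if np.hypot(*disp) > 1e-9:
                        cell.theta = float(np.arctan2(disp[1], disp[0]))
                    cell.pos = _clamp_margin(gp + cell.offset, (h, w), margin)
            grp = cell.group if cls == "swarm" else None
            records.append((cell.cid, t, cell.pos[0], cell.pos[1],
                            cell.theta, cls, grp))

    positions = pd.DataFrame(records, columns=["cell_id", "frame", "row", "col",
                                               "orientation", "class", "group"])

    # --- render label masks -------------------------------------------------
    for t in range(T):
        frame = labels[t]
        sub = positions[positions.frame == t]
        for _, rec in sub.sort_values("cell_id").iterrows():
            paint_capsule(frame, rec.row, rec.col, rec.orientation,
                          config.cell_length_px, config.cell_width_px,
                          int(rec.cell_id) + 1)

    prey_truth = build_prey_field(config)
    prey = render_fluorescence(prey_truth, config.illumination_sigma_px,
                               config.bleach_rate, config.noise_sd,
                               np.random.default_rng([config.seed, 2 ** 20]))

    truth = GroundTruth(positions, events, prey_truth, config,
                        np.asarray(group_paths) if group_paths else None)
    truth.validate()
    return labels, prey, truth
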