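"""Configuration objects for the simulator and the pipeline.

Both configs are plain dataclasses validated eagerly in ``__post_init__`` so
that a bad field fails with a message naming the field, before any stage runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

CLASSES = ("scout", "loner", "swarm")


class ConfigError(ValueError):
    """A configuration field is missing or out of its documented range."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass
class SimConfig:
    """Parameters of a synthetic predation scene.

    Spatial units are pixels, temporal units are frames unless suffixed.
    Defaults describe a desk-scale scene: a 512 px square field observed for
    120 frames at the acquisition cadence of the imaging assay this package
    models (38 s frame interval, 106 nm pixels).
    """

    field_size_px: tuple[int, int] = (512, 512)
    n_frames: int = 120
    dt_s: float = 38.0          # midpoint of the 35-40 s acquisition interval
    pixel_nm: float = 106.0

    # rod-shaped cell geometry (capsule); ~4.2 x 0.5 um at 106 nm/px
    cell_length_px: float = 40.0
    cell_width_px: float = 5.0

    # population counts
    n_scouts: int = 6
    n_loners: int = 6
    n_swarms: int = 2
    cells_per_swarm: int = 8

    # motion parameters per mode
    directed_speed_px: float = 10.0      # ~1.7 um/min gliding speed
    directed_heading_sd: float = 0.2     # rad / frame
    brownian_step_sd: float = 2.0        # px / frame per axis
    confinement_radius_px: float = 5.0
    swarm_cohesion_radius_px: float = 30.0

    # per-frame probability of switching to each *other* class
    transition_rate: float = 0.01

    # fraction of swarm groups steered along a scout's path (trail following)
    trail_following: float = 0.0

    # prey lawn and lysis front (front advances along rows, from row 0 down)
    prey_lawn_intensity: float = 1.0
    prey_front_row0: float = 170.0
    prey_front_speed_px: float = 1.0     # px / frame
    prey_lysis_rate: float = 0.02        # per frame, behind the front

    # optics
    illumination_sigma_px: float | None = 256.0
    bleach_rate: float = 0.002           # per frame
    noise_sd: float = 0.01               # additive, in lawn-intensity units

    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.field_size_px
        if h < 1 or w < 1:
            raise ConfigError("field_size_px", "both dimensions must be >= 1")
        if self.n_frames < 1:
            raise ConfigError("n_frames", "must be >= 1")
        if self.dt_s <= 0:
            raise ConfigError("dt_s", "must be > 0")
        for name in ("n_scouts", "n_loners", "n_swarms", "cells_per_swarm"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be >= 0")
        for name in ("transition_rate", "prey_lysis_rate", "bleach_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(name, "must lie in [0, 1]")
        if not 0.0 <= self.trail_following <= 1.0:
            raise ConfigError("trail_following", "must lie in [0, 1]")
        if self.cell_width_px <= 0 or self.cell_length_px < self.cell_width_px:
            raise ConfigError("cell_length_px", "need 0 < width <= length")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd", "must be >= 0")
        if self.illumination_sigma_px is not None and self.illumination_sigma_px <= 0:
            raise ConfigError("illumination_sigma_px", "must be > 0 or None")
        margin = self.cell_length_px
        n_cells = self.n_scouts + self.n_loners + self.n_swarms * self.cells_per_swarm
        usable = max(0.0, h - 2 * margin) * max(0.0, w - 2 * margin)
        # rough packing bound: each cell needs about a cell-length square
        if n_cells > 0 and usable < n_cells * (self.cell_length_px ** 2) / 2:
            raise ConfigError("field_size_px", "field too small for the requested cells")

    @property
    def n_cells(self) -> int:
        return self.n_scouts + self.n_loners + self.n_swarms * self.cells_per_swarm

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["field_size_px"] = list(self.field_size_px)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        if "field_size_px" in d:
            d["field_size_px"] = tuple(d["field_size_px"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown SimConfig field")
        return cls(**d)


#: stages in execution order
STAGES = ("simulate", "track", "spatial", "classify", "motion",
          "transitions", "trails", "prey")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration: stage toggles plus per-stage knobs."""

    sim: SimConfig = field(default_factory=SimConfig)
    stages: tuple[str, ...] = STAGES
    out_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"
    # input paths; when None the simulate stage provides the data
    label_stack_path: str | None = None
    prey_stack_path: str | None = None

    # tracking
    search_radius_px: float = 30.0
    min_link_score: float = 0.1
    # spatial context
    cluster_kernel_px: int = 10
    mean_cell_area_px2: float | None = None
    # classification
    motile_threshold_px: float = 2.0
    normalized_motile_filter: bool = False
    # transitions
    smoothing_window: int = 10
    embedding_noise_sd: float = 0.05
    # trails
    trail_grid: tuple[int, int] | None = None   # None -> field size
    si_window: int = 3
    si_binarize_threshold: float = 0.5
    # prey
    invasion_axis: str = "rows"
    invaded_end: str = "start"   # which end of the axis the predator enters from

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig.from_dict(self.sim)
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ConfigError("stages", f"unknown stage {bad[0]!r}")
        self.stages = tuple(self.stages)
        if self.smoothing_window < 1:
            raise ConfigError("smoothing_window", "must be >= 1")
        if self.si_window % 2 != 1:
            raise ConfigError("si_window", "must be odd")
        if self.invasion_axis not in ("rows", "cols"):
            raise ConfigError("invasion_axis", "must be 'rows' or 'cols'")
        if self.invaded_end not in ("start", "end"):
            raise ConfigError("invaded_end", "must be 'start' or 'end'")
        if self.label_stack_path is None and "simulate" not in self.stages:
            raise ConfigError("label_stack_path",
                              "required when the simulate stage is disabled")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["stages"] = list(self.stages)
        if self.trail_grid is not None:
            d["trail_grid"] = list(self.trail_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "trail_grid" in d and d["trail_grid"] is not None:
            d["trail_grid"] = tuple(d["trail_grid"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown PipelineConfig field")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data or {})
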