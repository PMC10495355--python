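"""Readers and writers for the pipeline's on-disk artifacts.

Label and fluorescence stacks travel as multi-page TIFF (16-bit for
acquisition-like data, 32-bit float for derived maps), tables as CSV, and
structured results (transition matrices, decay fits, manifests) as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import GroundTruth

__all__ = ["write_label_stack", "read_label_stack", "write_fluorescence_stack",
           "read_stack", "write_float_map", "write_ground_truth",
           "read_ground_truth_positions", "write_tracks_csv", "write_json",
           "read_json"]


def write_label_stack(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels do not fit 16-bit TIFF")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def read_label_stack(path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    return arr[None] if arr.ndim == 2 else arr


def write_fluorescence_stack(path, stack: np.ndarray,
                             scale: float | None = None) -> float:
    """Write a float stack as 16-bit TIFF; returns the intensity scale used."""
    stack = np.asarray(stack, float)
    if scale is None:
        peak = float(stack.max()) if stack.size else 1.0
        scale = (np.iinfo(np.uint16).max / peak) if peak > 0 else 1.0
    tifffile.imwrite(str(path), np.clip(stack * scale, 0,
                                        np.iinfo(np.uint16).max).astype(np.uint16))
    return scale


def read_stack(path) -> np.ndarray:
    arr = tifffile.imread(str(path)).astype(np.float64)
    return arr[None] if arr.ndim == 2 else arr


def write_float_map(path, arr: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(arr, np.float32))


def write_ground_truth(out_dir, truth: GroundTruth) -> tuple[Path, Path]:
    """Ground truth as CSV (cell_id, frame, row, col, class) + JSON (events,
    config echo)."""
    out_dir = Path(out_dir)
    csv_path = out_dir / "ground_truth.csv"
    cols = ["cell_id", "frame", "row", "col", "orientation", "class"]
    truth.positions[cols].to_csv(csv_path, index=False)
    meta = {"events": truth.events,
            "config": truth.config.to_dict() if truth.config else None}
    json_path = out_dir / "ground_truth.json"
    write_json(json_path, meta)
    return csv_path, json_path


def read_ground_truth_positions(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_tracks_csv(path, tracks, extra: dict[int, dict] | None = None) -> None:
    """Tracks as CSV: track_id, frame, label, row, col plus optional
    per-track columns from ``extra`` keyed by track id."""
    rows = []
    for tr in tracks:
        for frame, label, (r, c) in tr.items:
            rec = {"track_id": tr.track_id, "frame": frame, "label": label,
                   "row": r, "col": c,
                   "flags": ";".join(sorted(tr.flags))}
            if extra and tr.track_id in extra:
                rec.update(extra[tr.track_id])
            rows.append(rec)
    pd.DataFrame(rows).to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
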