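"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes the toggled stages in order — simulate, track,
spatial, classify, motion, transitions, trails, prey — each stage reading
only the in-memory products of earlier stages and writing its declared
artifacts, and finally writes a JSON manifest with the config echo and a
sha256 checksum per artifact, so identical config + seed reruns are
verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import classify as _classify
from .classify import histogram2d as _histogram2d
from .classify import motile_filter as _motile_filter
from . import io as io_mod
from . import motion as motion_mod
from . import prey as prey_mod
from . import spatial as spatial_mod
from . import tracking as tracking_mod
from . import trails as trails_mod
from . import transitions as trans_mod
from .config import PipelineConfig

logger = logging.getLogger("myxotrack")

__all__ = ["run_pipeline", "spatial_table", "class_table"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def spatial_table(labels: np.ndarray, kernel_px: int = 10,
                  mean_cell_area: float | None = None) -> pd.DataFrame:
    """Per-frame spatial descriptors for every mask of a label stack.

    Voronoi seeds are the backbone midpoints of all masks (branchpoint-split
    masks contribute one seed per segment; such a mask's V is the summed
    area of its segments' polygons). Cluster membership and N come from
    square-kernel dilation.
    """
    rows = []
    h, w = labels.shape[1:]
    for t in range(labels.shape[0]):
        frame = labels[t]
        ids = np.unique(frame)
        ids = ids[ids > 0]
        if len(ids) == 0:
            continue
        seeds, owners, lengths = [], [], {}
        for lab in ids:
            sub_mask = frame == lab
            rr, cc = np.nonzero(sub_mask)
            bb = (rr.min(), cc.min(), rr.max() + 1, cc.max() + 1)
            bone = spatial_mod.extract_backbone(sub_mask[bb[0]:bb[2], bb[1]:bb[3]])
            lengths[int(lab)] = bone.total_length
            for mid in bone.midpoints:
                seeds.append((mid[0] + bb[0], mid[1] + bb[1]))
                owners.append(int(lab))
        records = spatial_mod.voronoi_areas(np.asarray(seeds), (h, w))
        v_of: dict[int, float] = {}
        for rec, owner in zip(records, owners):
            v_of[owner] = v_of.get(owner, 0.0) + rec.area_px2
        clusters = spatial_mod.cluster_cells(frame, kernel_px, mean_cell_area)
        cl_of = {}
        n_of = {}
        for cl in clusters:
            for m in cl.members:
                cl_of[m] = cl.cluster_id
                n_of[m] = cl.N
        for lab in ids:
            lab = int(lab)
            rows.append({"frame": t, "label": lab,
                         "backbone_len_px": lengths[lab],
                         "voronoi_area_px2": v_of[lab],
                         "cluster_id": cl_of[lab], "cluster_N": n_of[lab]})
    return pd.DataFrame(rows)


def class_table(tracks, spatial_df: pd.DataFrame,
                motile_threshold_px: float = 2.0,
                normalized: bool = False) -> pd.DataFrame:
    """Per (track, frame) class assignment joined from the spatial table."""
    sp = spatial_df.set_index(["frame", "label"])
    rows = []
    for tr in tracks:
        motile = _motile_filter(tr.coords, motile_threshold_px,
                                       normalized)
        for frame, label, (r, c) in tr.items:
            try:
                rec = sp.loc[(frame, label)]
            except KeyError:
                continue
            log10v = float(np.log10(rec["voronoi_area_px2"]))
            n = float(rec["cluster_N"])
            rows.append({"track_id": tr.track_id, "frame": frame,
                         "label": label, "row": r, "col": c,
                         "log10V": log10v, "N": n,
                         "class": _classify(log10v, n),
                         "motile": motile})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the toggled stages; returns the manifest dict (also written to
    ``<out_dir>/manifest.json``)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "artifacts": {},
                      "timings_s": {}, "failures": {}}

    def register(name: str, path: Path):
        manifest["artifacts"][name] = {"path": str(path),
                                       "sha256": _sha256(path)}

    sim = dataclasses.replace(config.sim, seed=config.seed)
    labels = prey_stack = truth = None
    tracks = spatial_df = classes = None
    state: dict = {}

    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                from .synthetic import simulate_scene
                labels, prey_stack, truth = simulate_scene(sim)
                io_mod.write_label_stack(out / "labels.tif", labels)
                io_mod.write_fluorescence_stack(out / "prey.tif", prey_stack)
                io_mod.write_ground_truth(out, truth)
                register("labels", out / "labels.tif")
                register("prey", out / "prey.tif")
                register("ground_truth_csv", out / "ground_truth.csv")
                register("ground_truth_json", out / "ground_truth.json")
            elif stage == "track":
                if labels is None:
                    labels = io_mod.read_label_stack(config.label_stack_path)
                tracks = tracking_mod.track_label_stack(
                    labels, config.search_radius_px, config.min_link_score)
                io_mod.write_tracks_csv(out / "tracks.csv", tracks)
                register("tracks", out / "tracks.csv")
            elif stage == "spatial":
                spatial_df = spatial_table(labels, config.cluster_kernel_px,
                                           config.mean_cell_area_px2)
                spatial_df.to_csv(out / "spatial.csv", index=False)
                register("spatial", out / "spatial.csv")
            elif stage == "classify":
                classes = class_table(tracks, spatial_df,
                                      config.motile_threshold_px,
                                      config.normalized_motile_filter)
                classes.to_csv(out / "classes.csv", index=False)
                register("classes", out / "classes.csv")
                if len(classes):
                    hist = _histogram2d(classes.log10V, classes.N)
                    np.savetxt(out / "histogram2d.csv", hist.counts,
                               delimiter=",")
                    register("histogram2d", out / "histogram2d.csv")
            elif stage == "motion":
                rows = []
                for tr in tracks:
                    xy = tr.coords
                    speeds = motion_mod.speed_series(xy, dt=1.0)
                    gyr = motion_mod.gyration_radius(xy)
                    alpha = (motion_mod.directionality_alpha(xy).alpha
                             if len(xy) > 5 else None)
                    rows.append({"track_id": tr.track_id,
                                 "duration": tr.duration,
                                 "displacement_px": tr.displacement_px,
                                 "mean_speed_px_per_frame":
                                     float(speeds.mean()) if len(speeds) else np.nan,
                                 "gyration_radius_px": gyr,
                                 "alpha": alpha if alpha is not None else np.nan})
                pd.DataFrame(rows).to_csv(out / "motion.csv", index=False)
                register("motion", out / "motion.csv")
            elif stage == "transitions":
                series_list, ids = [], []
                for tid, grp in classes.groupby("track_id"):
                    series = grp.sort_values("frame")["class"].tolist()
                    series = ["loner" if s == "unclassified" else s
                              for s in series]
                    series_list.append(trans_mod.smooth_classes(
                        series, config.smoothing_window))
                    ids.append(tid)
                tm, per_track = trans_mod.transition_matrix(series_list)
                io_mod.write_json(out / "transition_matrix.json",
                                  {"counts": tm.counts,
                                   "probabilities": tm.probabilities,
                                   "n_tracks": tm.n_tracks,
                                   "n_events": tm.n_events})
                pd.DataFrame({"track_id": ids, "n_transitions": per_track}) \
                    .to_csv(out / "transition_counts.csv", index=False)
                emb_rows = []
                for tid, series in zip(ids, series_list):
                    pts = trans_mod.triangle_embedding(
                        series, config.embedding_noise_sd,
                        np.random.default_rng([config.seed, 7, int(tid)]))
                    for k, (x, y) in enumerate(pts):
                        emb_rows.append({"track_id": tid, "frame": k,
                                         "x": x, "y": y})
                pd.DataFrame(emb_rows).to_csv(out / "embedding.csv", index=False)
                register("transition_matrix", out / "transition_matrix.json")
                register("transition_counts", out / "transition_counts.csv")
                register("embedding", out / "embedding.csv")
                state["series_list"] = series_list
                state["series_ids"] = ids
            elif stage == "trails":
                grid = config.trail_grid or labels.shape[1:]
                by_track = {tid: grp.sort_values("frame")
                            for tid, grp in classes.groupby("track_id")}
                xy = [g[["row", "col"]].to_numpy(float) for g in by_track.values()]
                cl = [g["class"].tolist() for g in by_track.values()]
                s_xy, s_fr, r_xy, r_fr = trails_mod.split_by_class(xy, cl)
                scout_map = (trails_mod.rasterize_trails(s_xy, grid, s_fr)
                             if s_xy else trails_mod.TrailMap(
                                 np.full(grid, np.nan), np.zeros(grid, bool)))
                rest_map = (trails_mod.rasterize_trails(r_xy, grid, r_fr)
                            if r_xy else trails_mod.TrailMap(
                                np.full(grid, np.nan), np.zeros(grid, bool)))
                sim_map = trails_mod.similarity_index_map(
                    scout_map, rest_map, config.si_window)
                areas, _ = trails_mod.shared_trail_lengths(
                    sim_map, config.si_binarize_threshold,
                    restrict_to=scout_map.occupancy | rest_map.occupancy)
                io_mod.write_float_map(out / "trail_scouts.tif", scout_map.values)
                io_mod.write_float_map(out / "trail_rest.tif", rest_map.values)
                io_mod.write_float_map(out / "similarity_map.tif", sim_map.values)
                pd.DataFrame({"area_px2": areas}).to_csv(
                    out / "shared_trail_areas.csv", index=False)
                for n in ("trail_scouts.tif", "trail_rest.tif",
                          "similarity_map.tif", "shared_trail_areas.csv"):
                    register(n.split(".")[0], out / n)
            elif stage == "prey":
                if prey_stack is None:
                    prey_stack = io_mod.read_stack(config.prey_stack_path)
                norm = prey_mod.normalize_illumination(prey_stack)
                zones = prey_mod.zone_intensity_series(
                    norm, config.invasion_axis, config.invaded_end)
                pd.DataFrame([
                    {"zone": z.zone, "frame": i, "mean_intensity": v}
                    for z in zones.values() for i, v in enumerate(z.values)
                ]).to_csv(out / "zone_series.csv", index=False)
                fit = prey_mod.decay_time(zones["predation"], zones["safe"])
                safe_fit = prey_mod.decay_time(zones["safe"])
                io_mod.write_json(out / "decay_fits.json", {
                    "predation": {"tau_frames": fit.tau,
                                  "non_decaying": fit.non_decaying},
                    "safe": {"tau_frames": safe_fit.tau,
                             "non_decaying": safe_fit.non_decaying}})
                register("zone_series", out / "zone_series.csv")
                register("decay_fits", out / "decay_fits.json")
        except Exception as exc:   # record and stop: later stages need this one
            manifest["failures"][stage] = repr(exc)
            logger.exception("stage %s failed", stage)
            break
        finally:
            manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %-12s %6.2f s", stage, manifest["timings_s"][stage])

    io_mod.write_json(out / "manifest.json", manifest)
    return manifest
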