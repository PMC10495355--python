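"""Quantify how much swarm groups reuse scout trails.

Scout and non-scout trajectories are rasterized onto separate occupancy
maps; a 3-px structural-similarity (SSIM) map highlights pixels where both
populations laid trail, and thresholding it yields shared-trail segments.
The simulator's trail_following knob sets the fraction of swarm groups
that retrace a scout's path.
"""

import numpy as np

from myxotrack import (SimConfig, shared_trail_lengths, similarity_index_map,
                       simulate_scene)
from myxotrack.trails import rasterize_trails, split_by_class


def shared_area(knob: float, seed: int) -> int:
    cfg = SimConfig(field_size_px=(360, 360), n_frames=25,
                    n_scouts=3, n_loners=0, n_swarms=3, cells_per_swarm=4,
                    cell_length_px=16, cell_width_px=5,
                    directed_speed_px=4.0, swarm_cohesion_radius_px=12.0,
                    transition_rate=0.0, trail_following=knob,
                    illumination_sigma_px=180.0, prey_front_row0=120.0,
                    seed=seed)
    _, _, truth = simulate_scene(cfg)
    xy, cls = [], []
    for cid in truth.positions.cell_id.unique():
        sel = truth.positions[truth.positions.cell_id == cid] \
            .sort_values("frame")
        xy.append(sel[["row", "col"]].to_numpy(float))
        cls.append(sel["class"].tolist())
    s_xy, s_fr, r_xy, r_fr = split_by_class(xy, cls)
    scouts = rasterize_trails(s_xy, cfg.field_size_px, s_fr)
    rest = rasterize_trails(r_xy, cfg.field_size_px, r_fr)
    sim = similarity_index_map(scouts, rest, window=3)
    areas, _ = shared_trail_lengths(sim, 0.5,
                                    restrict_to=scouts.occupancy
                                    | rest.occupancy)
    return sum(areas)


for knob in (0.0, 0.5, 1.0):
    areas = [shared_area(knob, s) for s in range(5)]
    print(f"trail_following = {knob:.1f}: "
          f"mean shared trail area = {np.mean(areas):7.1f} px^2 "
          f"(5 seeds: {areas})")
print("\nshared area grows as more swarm groups follow scout trails.")
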