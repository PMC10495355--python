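"""Trail rasterization, SSIM overlap maps, shared-segment extraction."""

import numpy as np
import pytest

from myxotrack.trails import (TrailMap, rasterize_trails, shared_trail_lengths,
                              similarity_index_map, split_by_class)


def ssim_formula_oracle(a, b, window=3, data_range=1.0):
    """Direct evaluation of the SSIM formula on sliding windows."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    r = window // 2
    h, w = a.shape
    out = np.full((h, w), np.nan)
    np_pix = window * window
    for i in range(r, h - r):
        for j in range(r, w - r):
            wa = a[i - r:i + r + 1, j - r:j + r + 1].ravel()
            wb = b[i - r:i + r + 1, j - r:j + r + 1].ravel()
            mu_a, mu_b = wa.mean(), wb.mean()
            cov_norm = 1.0 / (np_pix - 1)          # unbiased, as is standard
            va = cov_norm * ((wa - mu_a) ** 2).sum()
            vb = cov_norm * ((wb - mu_b) ** 2).sum()
            cab = cov_norm * ((wa - mu_a) * (wb - mu_b)).sum()
            out[i, j] = (((2 * mu_a * mu_b + c1) * (2 * cab + c2))
                         / ((mu_a ** 2 + mu_b ** 2 + c1) * (va + vb + c2)))
    return out


class TestRasterize:
    def test_straight_track_marks_exactly_its_segment(self):
        track = np.array([[2.0, 2.0], [2.0, 10.0]])
        tm = rasterize_trails([track], (16, 16))
        rr, cc = np.nonzero(tm.occupancy)
        assert set(rr) == {2}
        assert set(cc) == set(range(2, 11))

    def test_shared_pixel_takes_mean_visit_time(self):
        t1 = np.array([[5.0, 3.0], [5.0, 8.0]])
        t2 = np.array([[5.0, 3.0], [5.0, 8.0]])
        tm = rasterize_trails([t1, t2], (16, 16),
                              frames=[np.array([10.0, 10.0]),
                                      np.array([30.0, 30.0])])
        assert tm.values[5, 5] == pytest.approx(20.0)

    def test_no_tracks_gives_all_background(self):
        tm = rasterize_trails([], (8, 8))
        assert not tm.occupancy.any()
        assert np.isnan(tm.values).all()

    def test_order_independence_with_mean_aggregation(self):
        rng = np.random.default_rng(0)
        tracks = [np.cumsum(rng.normal(8, 1, size=(10, 2)), axis=0) % 30
                  for _ in range(5)]
        frames = [np.arange(10.0) + 3 * k for k in range(5)]
        fwd = rasterize_trails(tracks, (30, 30), frames)
        rev = rasterize_trails(tracks[::-1], (30, 30), frames[::-1])
        np.testing.assert_allclose(np.nan_to_num(fwd.values),
                                   np.nan_to_num(rev.values))


class TestSimilarityMap:
    def test_identical_maps_give_unit_similarity(self):
        occ = np.zeros((20, 20), bool)
        occ[5, 3:15] = True
        tm = TrailMap(np.where(occ, 1.0, np.nan), occ)
        sim = similarity_index_map(tm, tm)
        assert np.allclose(sim.values, 1.0)

    def test_matches_direct_windowed_formula(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(size=(24, 24)) < 0.3
        b = rng.uniform(size=(24, 24)) < 0.3
        sim = similarity_index_map(a.astype(float), b.astype(float))
        oracle = ssim_formula_oracle(a.astype(float), b.astype(float))
        inner = ~np.isnan(oracle)
        np.testing.assert_allclose(sim.values[inner], oracle[inner],
                                   rtol=1e-7, atol=1e-9)

    def test_complement_has_minimal_similarity_in_textured_region(self):
        rng = np.random.default_rng(2)
        a = (rng.uniform(size=(24, 24)) < 0.5).astype(float)
        b = 1.0 - a
        sim = similarity_index_map(a, b)
        oracle = ssim_formula_oracle(a, b)
        inner = ~np.isnan(oracle)
        assert sim.values[inner].mean() < 0.0

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(3)
        a = (rng.uniform(size=(30, 30)) < 0.2).astype(float)
        b = (rng.uniform(size=(30, 30)) < 0.2).astype(float)
        ab = similarity_index_map(a, b).values
        ba = similarity_index_map(b, a).values
        np.testing.assert_array_equal(ab, ba)

    def test_shared_trail_high_similarity_only_on_shared_segment(self):
        shared = np.array([[10.0, 2.0], [10.0, 27.0]])
        only_a = np.array([[3.0, 2.0], [3.0, 27.0]])
        only_b = np.array([[20.0, 2.0], [20.0, 27.0]])
        map_a = rasterize_trails([shared, only_a], (30, 30))
        map_b = rasterize_trails([shared, only_b], (30, 30))
        sim = similarity_index_map(map_a, map_b)
        assert sim.values[10, 5:25].min() > 0.9
        assert sim.values[3, 5:25].max() < 0.5
        assert sim.values[20, 5:25].max() < 0.5


class TestSharedTrails:
    def test_identical_single_trail_one_component_with_trail_area(self):
        track = np.array([[5.0, 2.0], [5.0, 12.0]])
        tm = rasterize_trails([track], (20, 20))
        sim = similarity_index_map(tm, tm)
        areas, _ = shared_trail_lengths(sim, 0.5, restrict_to=tm.occupancy)
        assert len(areas) == 1
        assert areas[0] == int(tm.occupancy.sum())

    def test_disjoint_maps_have_no_shared_component(self):
        a = rasterize_trails([np.array([[2.0, 2.0], [2.0, 18.0]])], (24, 24))
        b = rasterize_trails([np.array([[20.0, 2.0], [20.0, 18.0]])], (24, 24))
        sim = similarity_index_map(a, b)
        areas, _ = shared_trail_lengths(sim, 0.5,
                                        restrict_to=a.occupancy | b.occupancy)
        assert areas == []

    def test_two_shared_patches_give_two_components(self):
        s1 = np.array([[3.0, 2.0], [3.0, 10.0]])
        s2 = np.array([[20.0, 2.0], [20.0, 10.0]])
        a = rasterize_trails([s1, s2], (24, 24))
        b = rasterize_trails([s1, s2], (24, 24))
        sim = similarity_index_map(a, b)
        areas, _ = shared_trail_lengths(sim, 0.5,
                                        restrict_to=a.occupancy)
        assert len(areas) == 2


class TestSplitByClass:
    def test_framewise_partition_respects_class_changes(self):
        xy = np.stack([np.arange(6.0), np.zeros(6)], axis=1)
        classes = ["scout", "scout", "swarm", "swarm", "scout", "scout"]
        s_xy, s_fr, r_xy, r_fr = split_by_class([xy], [classes])
        assert len(s_xy) == 2 and len(r_xy) == 1
        np.testing.assert_array_equal(s_fr[0], [0, 1])
        np.testing.assert_array_equal(r_fr[0], [2, 3])
        np.testing.assert_array_equal(s_fr[1], [4, 5])


def test_trail_following_knob_monotonically_increases_shared_area():
    """More swarm groups steered along scout paths -> more shared trail."""
    from myxotrack.config import SimConfig
    from myxotrack.synthetic import simulate_scene

    def shared_area(knob, seed):
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
        a = rasterize_trails(s_xy, (360, 360), s_fr)
        b = rasterize_trails(r_xy, (360, 360), r_fr)
        sim = similarity_index_map(a, b)
        areas, _ = shared_trail_lengths(sim, 0.5,
                                        restrict_to=a.occupancy | b.occupancy)
        return sum(areas)

    knobs = (0.0, 0.5, 1.0)
    totals = []
    for knob in knobs:
        totals.append(np.mean([shared_area(knob, s) for s in range(5)]))
    assert totals[0] < totals[1] < totals[2]
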