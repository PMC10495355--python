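"""Simulator: motion regimes, scene structure, fluorescence rendering."""

import numpy as np
import pandas as pd
import pytest

from myxotrack.config import ConfigError, SimConfig
from myxotrack.motion import directionality_alpha
from myxotrack.synthetic import (build_prey_field, gaussian_profile,
                                 render_fluorescence, simulate_motion,
                                 simulate_scene)


class TestSimulateMotion:
    def test_straight_line_when_heading_noise_is_zero(self):
        pos = simulate_motion("directed", 10,
                              {"speed": 1.0, "heading_sd": 0.0}, seed=0)
        assert pos.shape == (11, 2)
        assert np.hypot(*(pos[-1] - pos[0])) == pytest.approx(10.0)

    def test_same_seed_reproduces_series(self):
        a = simulate_motion("brownian", 50, {"step_sd": 1.0}, seed=42)
        b = simulate_motion("brownian", 50, {"step_sd": 1.0}, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_confined_never_leaves_disk(self):
        pos = simulate_motion("confined", 500,
                              {"step_sd": 2.0, "radius": 5.0}, seed=1)
        r = np.hypot(*(pos - pos[0]).T)
        assert r.max() <= 5.0 + 1e-9
        assert r.max() <= 2 * 5.0       # a fortiori within 2R of the start

    def test_brownian_ensemble_alpha_is_one(self):
        alphas = [directionality_alpha(
            simulate_motion("brownian", 100, {"step_sd": 1.0}, seed=s)).alpha
            for s in range(500)]
        alphas = np.array([a for a in alphas if a is not None])
        mean = alphas.mean()
        ci = 1.96 * alphas.std(ddof=1) / np.sqrt(len(alphas))
        assert mean - ci <= 1.0 <= mean + ci

    def test_confined_ensemble_alpha_below_one(self):
        alphas = [directionality_alpha(
            simulate_motion("confined", 200, {"step_sd": 1.0, "radius": 5.0},
                            seed=s)).alpha for s in range(100)]
        alphas = [a for a in alphas if a is not None]
        assert np.mean(alphas) < 1.0

    @pytest.mark.parametrize("mode,params,err", [
        ("walk", {}, "unknown"),
        ("brownian", {"step_sd": 0.0}, "step_sd"),
        ("confined", {"radius": -1.0}, "radius"),
    ])
    def test_invalid_inputs_raise(self, mode, params, err):
        with pytest.raises(ValueError, match=err):
            simulate_motion(mode, 5, params, seed=0)


class TestSimulateScene:
    def test_zero_cells_gives_empty_stack_and_truth(self):
        cfg = SimConfig(field_size_px=(64, 64), n_frames=3, n_scouts=0,
                        n_loners=0, n_swarms=0, cells_per_swarm=0,
                        cell_length_px=10, cell_width_px=3,
                        illumination_sigma_px=32.0, prey_front_row0=20.0)
        labels, prey, truth = simulate_scene(cfg)
        assert labels.sum() == 0
        assert len(truth.positions) == 0
        assert truth.events == []

    def test_single_scout_yields_one_full_track(self):
        cfg = SimConfig(field_size_px=(300, 300), n_frames=50, n_scouts=1,
                        n_loners=0, n_swarms=0, cells_per_swarm=0,
                        cell_length_px=20, cell_width_px=5,
                        directed_speed_px=3.0, transition_rate=0.0,
                        illumination_sigma_px=150.0, prey_front_row0=100.0,
                        seed=2)
        labels, _, truth = simulate_scene(cfg)
        assert truth.positions.cell_id.nunique() == 1
        assert len(truth.positions) == 50
        assert (truth.positions["class"] == "scout").all()
        # the cell's label is present in every frame
        assert all((labels[t] == 1).any() for t in range(50))

    def test_swarm_members_stay_within_cohesion_radius(self):
        cfg = SimConfig(field_size_px=(300, 300), n_frames=30, n_scouts=0,
                        n_loners=0, n_swarms=1, cells_per_swarm=8,
                        cell_length_px=20, cell_width_px=5,
                        swarm_cohesion_radius_px=30.0, transition_rate=0.0,
                        illumination_sigma_px=150.0, prey_front_row0=100.0,
                        seed=3)
        _, _, truth = simulate_scene(cfg)
        assert truth.group_paths is not None
        pos = truth.positions
        for _, rec in pos.iterrows():
            path = truth.group_paths[int(rec.group)]
            d = np.hypot(rec.row - path[int(rec.frame), 0],
                         rec.col - path[int(rec.frame), 1])
            assert d <= 30.0 + 1e-9

    def test_bit_identical_under_same_config(self, small_scene):
        cfg, labels, prey, truth = small_scene
        labels2, prey2, truth2 = simulate_scene(cfg)
        np.testing.assert_array_equal(labels, labels2)
        np.testing.assert_array_equal(prey, prey2)
        pd.testing.assert_frame_equal(truth.positions, truth2.positions)

    def test_one_class_per_cell_frame_and_events_consistent(self, small_scene):
        _, _, _, truth = small_scene
        truth.validate()
        changes = 0
        for cid in truth.positions.cell_id.unique():
            s = truth.class_series_of(cid)
            changes += sum(a != b for a, b in zip(s[:-1], s[1:]))
        assert changes == len(truth.events)

    def test_class_frequencies_approach_stationary_distribution(self):
        # symmetric rates -> uniform stationary law over the three classes
        from myxotrack.synthetic import _markov_class_series
        rng = np.random.default_rng(5)
        counts = {"scout": 0, "loner": 0, "swarm": 0}
        for _ in range(30):
            for c in _markov_class_series("scout", 2000, 0.05, rng):
                counts[c] += 1
        freqs = np.array(list(counts.values())) / sum(counts.values())
        assert np.allclose(freqs, 1 / 3, atol=0.03)

    def test_field_too_small_raises(self):
        with pytest.raises(ConfigError, match="field_size_px"):
            SimConfig(field_size_px=(50, 50), n_scouts=100,
                      cell_length_px=20, cell_width_px=5)


class TestRenderFluorescence:
    def test_flat_profile_no_bleach_no_noise_is_constant(self):
        field = np.ones((5, 16, 16), np.float32)
        out = render_fluorescence(field, None, 0.0, 0.0)
        assert np.allclose(out, 1.0)

    def test_bleach_factor_matches_closed_form(self):
        field = np.ones((10, 16, 16), np.float32)
        out = render_fluorescence(field, None, 0.05, 0.0)
        ratio = out.mean(axis=(1, 2)) / out[0].mean()
        np.testing.assert_allclose(ratio, np.exp(-0.05 * np.arange(10)),
                                   rtol=1e-5)

    def test_gaussian_profile_is_brighter_at_center(self):
        field = np.ones((1, 33, 33), np.float32)
        out = render_fluorescence(field, 8.0, 0.0, 0.0)
        assert out[0, 16, 16] > out[0, 0, 0]

    def test_unlysed_unbleached_region_constant_up_to_noise(self):
        cfg = SimConfig(field_size_px=(90, 90), n_frames=40, n_scouts=0,
                        n_loners=0, n_swarms=0, cells_per_swarm=0,
                        cell_length_px=10, cell_width_px=3,
                        prey_front_row0=30.0, prey_front_speed_px=0.0,
                        prey_lysis_rate=0.05, bleach_rate=0.0, noise_sd=0.01,
                        illumination_sigma_px=None, seed=4)
        field = build_prey_field(cfg)
        out = render_fluorescence(field, None, 0.0, cfg.noise_sd,
                                  np.random.default_rng(0))
        safe = out[:, 60:, :].mean(axis=(1, 2))   # front never reaches here
        assert np.allclose(safe, 1.0, atol=3 * 0.01 / np.sqrt(90 * 30))

    def test_negative_bleach_rejected(self):
        with pytest.raises(ValueError, match="bleach"):
            render_fluorescence(np.ones((2, 4, 4)), None, -0.1, 0.0)

    def test_profile_peak_is_one_and_centered(self):
        p = gaussian_profile((21, 21), 5.0)
        assert p[10, 10] == pytest.approx(1.0)
        assert p[0, 0] < p[10, 10]
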