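import numpy as np
import pytest
from hypothesis import settings

from myxotrack.config import SimConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_scene():
    """A small mixed scene with every population present (session-cached)."""
    from myxotrack.synthetic import simulate_scene
    cfg = SimConfig(field_size_px=(220, 220), n_frames=15,
                    n_scouts=2, n_loners=2, n_swarms=1, cells_per_swarm=4,
                    cell_length_px=20, cell_width_px=5,
                    directed_speed_px=4.0, brownian_step_sd=1.0,
                    swarm_cohesion_radius_px=20.0,
                    illumination_sigma_px=110.0, prey_front_row0=70.0,
                    seed=7)
    labels, prey, truth = simulate_scene(cfg)
    return cfg, labels, prey, truth


@pytest.fixture(scope="session")
def separated_scene():
    """Confined walkers placed far apart: trajectories never approach,
    the premise of the near-perfect link-recovery check."""
    from myxotrack.synthetic import simulate_scene
    cfg = SimConfig(field_size_px=(400, 400), n_frames=40,
                    n_scouts=0, n_loners=10, n_swarms=0, cells_per_swarm=0,
                    cell_length_px=20, cell_width_px=5,
                    brownian_step_sd=1.0, confinement_radius_px=5.0,
                    transition_rate=0.0,
                    illumination_sigma_px=200.0, prey_front_row0=130.0,
                    seed=11)
    labels, prey, truth = simulate_scene(cfg)
    return cfg, labels, prey, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
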