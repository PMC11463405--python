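import numpy as np
import pytest

from opsindiff.synthetic import (
    ToySystemConfig,
    build_toy_system,
    default_two_system_config,
    simulate_two_system_trajectories,
)


@pytest.fixture(scope="session")
def small_system():
    """Tiny toy topology + base frame (4 cage residues, 2 waters)."""
    return build_toy_system(ToySystemConfig(n_cage_residues=4, n_waters=2))


@pytest.fixture(scope="session")
def short_pair():
    """Matched A/B pair at 400 frames under the default study conditions."""
    cfg = default_two_system_config(seed=0, n_frames=400)
    traj_a, traj_b, truth = simulate_two_system_trajectories(cfg)
    return cfg, traj_a, traj_b, truth


@pytest.fixture(scope="session")
def full_pair():
    """Matched A/B pair at the full 2000-frame study length (seed 0)."""
    cfg = default_two_system_config(seed=0, n_frames=2000)
    traj_a, traj_b, truth = simulate_two_system_trajectories(cfg)
    return cfg, traj_a, traj_b, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
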