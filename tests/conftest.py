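import numpy as np
import pytest

from lncoord.synthetic import (
    SyntheticTrajSpec,
    generate_complex_trajectory,
)


@pytest.fixture(scope="session")
def la_system():
    """Small La trajectory with ground truth, shared across read-only tests."""
    spec = SyntheticTrajSpec(n_frames=400, water_count=12, seed=7)
    traj, top, gt = generate_complex_trajectory(spec)
    return spec, traj, top, gt


@pytest.fixture(scope="session")
def frozen_bound_system():
    """Trajectory frozen in state i (all donors bound, no shell waters)."""
    rates = {("i", "ii"): 0.0}
    spec = SyntheticTrajSpec(
        n_frames=50, water_count=6, seed=5, state_rates=rates,
        chelation_rates=(0.0, 0.0),
    )
    traj, top, gt = generate_complex_trajectory(spec)
    return spec, traj, top, gt


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
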