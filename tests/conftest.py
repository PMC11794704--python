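import numpy as np
import pytest

from cyclefit import SimulationConfig, TransitionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def control_matrix():
    """A cycling-population matrix with realistic dwell times."""
    return TransitionMatrix.from_dwell_times(7.9, 37.7, 3.4, 0.95)


@pytest.fixture
def control_initial():
    return np.array([120.0, 60.0, 15.0, 5.0])


@pytest.fixture
def small_sim_config(control_matrix):
    return SimulationConfig(
        true_matrix=control_matrix,
        initial_counts=[200, 100, 25, 8],
        n_hours=12,
        frames_per_hour=4,
        seed=7,
    )
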