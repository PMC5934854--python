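import numpy as np
import pytest

from vestibinfer import (
    ConditionDefaults,
    InternalModel,
    TrajectoryProfile,
    generate_trajectory,
    make_time_grid,
)


@pytest.fixture(scope="session")
def grid():
    """Default 2-s grid at 10-ms resolution (201 points)."""
    return make_time_grid(dt=0.01, total_time=2.0)


@pytest.fixture(scope="session")
def truth(grid):
    """Default 1-s, 60 deg/s leftward raised-cosine head turn."""
    return generate_trajectory(TrajectoryProfile(), grid)


@pytest.fixture(scope="session")
def defaults():
    return ConditionDefaults()


@pytest.fixture(scope="session")
def internal():
    return InternalModel()


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
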