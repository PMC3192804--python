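import numpy as np
import pytest

from armioc import ArmParams, SolverOptions, default_tasks


@pytest.fixture(scope="session")
def params():
    return ArmParams()


@pytest.fixture(scope="session")
def params_frictionless():
    """Arm without joint viscosity (conservative dynamics)."""
    return ArmParams(B=np.zeros((2, 2)))


@pytest.fixture(scope="session")
def fast_options():
    """Reduced-resolution solver options for cheap test solves."""
    return SolverOptions(nodes=25, basis_size=6)


@pytest.fixture(scope="session")
def bar_task(params):
    """The level-start posture reaching the bar at 85% arm length."""
    return default_tasks(params)[2]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
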