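import numpy as np
import pytest

from anttow.controller import ControllerParams
from anttow.load_dynamics import GaitSchedule, LoadParams
from anttow.order_stats import SpeedDistribution


@pytest.fixture(scope="session")
def fitted_dist() -> SpeedDistribution:
    """Fitted individual-speed distribution: μ=0.7, σ=0.36 on [0, 1.2] cm/s."""
    return SpeedDistribution(mu=0.7, sigma=0.36, lower=0.0, upper=1.2)


@pytest.fixture(scope="session")
def degenerate_fit() -> SpeedDistribution:
    """Near-degenerate distribution: all mass effectively at μ."""
    return SpeedDistribution(mu=0.7, sigma=1e-9, lower=0.0, upper=1.2)


@pytest.fixture()
def controller_params() -> ControllerParams:
    """Adaptive-experiment controller settings."""
    return ControllerParams()


@pytest.fixture()
def step_gait() -> GaitSchedule:
    """Duty-cycled gait: 1.5 s contact in a 3 s stride (p_f = 0.5)."""
    return GaitSchedule(t_c=1.5, t_s=3.0)


@pytest.fixture()
def soft_load() -> LoadParams:
    """Stepping-experiment load for a 3-walker team (500 g per walker)."""
    return LoadParams(m=1500.0, mu_k=1e-4, K=50.0, v_max=8.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
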