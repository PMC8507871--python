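import pytest

from zmtcp import (
    FractionationSchedule,
    PopulationDistribution,
    ResensitizationParams,
    TumorKinetics,
)

ALPHA0 = 0.12
ALPHA_M = 0.23
BETA0 = 0.12 / 4.5
B_SLOW = 0.066


@pytest.fixture
def stock_params() -> ResensitizationParams:
    """Mean calibrated radiosensitivity of the prostate population."""
    return ResensitizationParams(alpha0=ALPHA0, alpha_m=ALPHA_M, beta0=BETA0, b=B_SLOW)


@pytest.fixture
def sched_2f() -> FractionationSchedule:
    return FractionationSchedule([0, 14], [14, 14])


@pytest.fixture
def sched_3f() -> FractionationSchedule:
    return FractionationSchedule([0, 14, 28], [11, 11, 11])


@pytest.fixture
def stock_kinetics() -> TumorKinetics:
    return TumorKinetics(n0=1e8, lam=0.02)


@pytest.fixture
def small_population() -> PopulationDistribution:
    """Stock spread at a reduced sample size for fast tests."""
    return PopulationDistribution(n_samples=2000, seed=11)
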