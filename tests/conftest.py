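import numpy as np
import pytest

from kneebalance import (
    CohortConfig,
    Thresholds,
    default_calibration,
    simulate_cohort,
)
from kneebalance.effects import CalibrationTable


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def calibration():
    return default_calibration()


@pytest.fixture(scope="session")
def noiseless_calibration(calibration):
    """Default mean effects with patient offsets and residual noise silenced."""
    return CalibrationTable(
        profiles=calibration.profiles,
        sigma_patient=np.zeros(6),
        sigma_resid=np.zeros(6),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition simulated cohort, shared across tests."""
    return simulate_cohort(CohortConfig(), seed=20210700)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
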