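import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cyclesim import (
    constant_schedule,
    default_amp_tol,
    default_parameters,
    reference_cycle,
    run_protocol,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def reference(params):
    """Normal-cycle statistics (300-day window after a 300-day transient)."""
    return reference_cycle(params)


@pytest.fixture(scope="session")
def amp_tol(reference):
    return default_amp_tol(reference)


@pytest.fixture(scope="session")
def baseline_traj(params):
    """Undosed run used by several analyses (burn-in 300 d, 300 d window)."""
    return run_protocol(constant_schedule(0.0, 0.0), params=params,
                        burn_in=300.0, horizon=600.0)


@pytest.fixture(scope="session")
def combined_low_traj(params):
    """Combined low-dose run (40 pg/mL, 0.6 ng/mL)."""
    return run_protocol(constant_schedule(40.0, 0.6), params=params,
                        burn_in=300.0, horizon=500.0)


@pytest.fixture(scope="session")
def progestin_high_traj(params):
    """High-progestin run (p_dose = 1.3 ng/mL)."""
    return run_protocol(constant_schedule(0.0, 1.3), params=params,
                        burn_in=300.0, horizon=500.0)


class SyntheticTrajectory:
    """Stand-in trajectory with a prescribed LH signal (synthetic; for
    testing the analysis functions without an integration)."""

    def __init__(self, lh_func, t0=0.0, t_end=100.0, burn_in=0.0):
        self.t0 = t0
        self.t_end = t_end
        self.burn_in = burn_in
        self._lh = lh_func

    def sample(self, window, dt=0.01):
        ts = np.arange(window[0], window[1], dt)
        y = np.zeros((13, ts.size))
        y[1] = self._lh(ts)
        return ts, y


@pytest.fixture
def synthetic_trajectory():
    return SyntheticTrajectory
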