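import numpy as np
import pytest

from cyclesim import (
    MID_FOLLICULAR_STATE,
    constant_history,
    dense_eval,
    integrate_dde,
)
from cyclesim.dde_engine import IntegrationError, _segment_boundaries


def scalar_rhs(t, y, z, doses, params):
    """x'(t) = -x(t - 1): the classic single-delay test problem."""
    return np.array([-z])


def integrate_scalar(t_end, rel_tol=1e-10, abs_tol=1e-12):
    return integrate_dde(
        rhs=scalar_rhs,
        history=lambda t: (np.array([1.0]) if np.ndim(t) == 0
                           else np.ones((1, np.size(t)))),
        t_span=(0.0, t_end),
        tau=1.0,
        delayed_observable=lambda y: y[0],
        rel_tol=rel_tol, abs_tol=abs_tol,
    )


class TestScalarDelayProblem:
    """Method-of-steps exactness on x' = -x(t-1), constant history 1:
    the solution is polynomial on each unit interval."""

    def test_first_interval_is_linear(self):
        traj = integrate_scalar(1.0)
        ts = np.linspace(0.0, 1.0, 11)
        assert np.allclose(traj(ts)[0], 1.0 - ts, atol=1e-10)

    def test_second_interval_is_quadratic(self):
        traj = integrate_scalar(2.0)
        ts = np.linspace(1.0, 2.0, 11)
        exact = 1.0 - ts + (ts - 1.0) ** 2 / 2.0
        assert np.allclose(traj(ts)[0], exact, atol=1e-10)

    def test_error_decreases_with_tolerance(self):
        # on [n-1, n] the exact solution is the degree-n polynomial
        # sum_k (-1)^k (t-k+1)^k / k!; past degree 5 the RK pair is no
        # longer exact and the error must track the tolerance
        from math import factorial

        ts = np.linspace(7.0, 8.0, 7)
        exact = sum((-1.0) ** k * (ts - k + 1.0) ** k / factorial(k)
                    for k in range(9))
        errs = []
        for rtol in (1e-4, 1e-8):
            traj = integrate_scalar(8.0, rel_tol=rtol, abs_tol=rtol * 1e-2)
            errs.append(np.max(np.abs(traj(ts)[0] - exact)))
        assert errs[1] < errs[0]
        assert errs[1] < 1e-8


class TestTrajectory:
    def test_grid_nodes_reproduce_stored_states(self, baseline_traj):
        nodes = baseline_traj.t[::50]
        vals = baseline_traj(nodes)
        stored = baseline_traj.y[:, ::50]
        assert np.array_equal(vals, stored)

    def test_history_region_returns_history_values(self):
        traj = integrate_dde(t_span=(0.0, 5.0), doses=(0.0, 0.0))
        assert np.array_equal(traj(-1.0), MID_FOLLICULAR_STATE)
        assert np.array_equal(dense_eval(traj, -0.5), MID_FOLLICULAR_STATE)

    def test_out_of_range_rejected(self):
        traj = integrate_dde(t_span=(0.0, 5.0), doses=(0.0, 0.0))
        with pytest.raises(ValueError, match="range"):
            traj(6.0)
        with pytest.raises(ValueError, match="range"):
            traj(-2.0)

    def test_time_grid_strictly_increasing(self, baseline_traj):
        assert np.all(np.diff(baseline_traj.t) > 0)

    def test_segment_boundaries_cap_step_at_delay(self):
        bounds = _segment_boundaries(0.0, 10.0, 1.5, breakpoints=(4.0,))
        assert np.all(np.diff(bounds) <= 1.5 + 1e-12)
        assert 4.0 in bounds and 5.5 in bounds


class TestContracts:
    def test_determinism_bit_identical(self):
        a = integrate_dde(t_span=(0.0, 30.0), doses=(0.0, 0.0))
        b = integrate_dde(t_span=(0.0, 30.0), doses=(0.0, 0.0))
        assert np.array_equal(a.y, b.y) and np.array_equal(a.t, b.t)

    def test_self_convergence_under_tolerance_halving(self):
        probes = np.array([10.0, 25.0, 40.0, 55.0])
        t1 = integrate_dde(t_span=(0.0, 60.0), doses=(0.0, 0.0),
                           rel_tol=1e-8, abs_tol=1e-10)
        t2 = integrate_dde(t_span=(0.0, 60.0), doses=(0.0, 0.0),
                           rel_tol=5e-9, abs_tol=5e-11)
        assert np.max(np.abs(t1(probes)[1] - t2(probes)[1])) < 1e-6

    def test_delay_consistency_with_own_history(self, baseline_traj):
        """Restarting the integration with the produced trajectory as its
        own history reproduces the solution."""
        again = integrate_dde(history=baseline_traj, t_span=(100.0, 160.0),
                              doses=(0.0, 0.0))
        probes = np.array([110.0, 130.0, 150.0])
        assert np.max(np.abs(baseline_traj(probes) - again(probes))) < 1e-5

    def test_trajectory_nonnegative_from_nonnegative_history(self, baseline_traj):
        assert baseline_traj.y.min() >= -1e-8

    def test_nonnegative_history_required(self):
        with pytest.raises(ValueError):
            constant_history(np.full(13, -1.0))

    def test_invalid_spans_and_tolerances_rejected(self):
        with pytest.raises(ValueError):
            integrate_dde(t_span=(5.0, 5.0), doses=(0.0, 0.0))
        with pytest.raises(ValueError):
            integrate_dde(t_span=(0.0, 5.0), doses=(0.0, 0.0), rel_tol=-1.0)
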