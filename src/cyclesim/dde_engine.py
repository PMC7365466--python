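"""Method-of-steps integrator for the single-discrete-delay system.

The delay differential equation is integrated interval by interval: the
time axis is cut at every multiple of the delay ``tau`` (and at every dose
breakpoint together with its first few delay images, where the solution
loses smoothness), and each interval is solved with an embedded explicit
Runge-Kutta pair (scipy's RK45) with its continuous extension retained.
Within an interval the delayed value is always read from already-completed
intervals or from the history function, so each interval is an ordinary
initial-value problem.

The returned :class:`Trajectory` is densely evaluable on
``[t0 - tau, t_end]`` and is the container all analysis modules operate on.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import (
    ParameterSet,
    STATE_NAMES,
    _auxiliaries,
    default_parameters,
    dde_rhs,
    inhibin_a,
)

__all__ = [
    "DEFAULT_REL_TOL",
    "DEFAULT_ABS_TOL",
    "MID_FOLLICULAR_STATE",
    "CYCLE_START_STATE",
    "constant_history",
    "Trajectory",
    "integrate_dde",
    "dense_eval",
    "IntegrationError",
]

#: Default solver tolerances.  Chosen so that the cycle period is resolved
#: well past two decimal places (see docs/methods.md).
DEFAULT_REL_TOL = 1e-8
DEFAULT_ABS_TOL = 1e-10

#: A positive mid-follicular state on the converged normal cycle, roughly
#: one week before the LH surge.  Used as the default constant seed history;
#: any positive history reaches the same attractor after the burn-in, this
#: one merely starts close to it.  Generated by this package's own baseline
#: simulation (synthetic fixture, frozen for reproducibility).
MID_FOLLICULAR_STATE = np.array([
    194.6765, 13.4540, 67.4944, 13.7915,   # RP_LH, LH, RP_FSH, FSH
    21.4788, 10.7190, 3.1369,              # RcF, GrF, DomF
    1.4651, 0.7457,                        # Sc1, Sc2
    0.5825, 0.6282, 1.0304, 1.7511,        # Lut1..Lut4
])

#: State on the converged normal cycle at the start of a cycle
#: (menstruation onset, half a period before the LH surge).  Used to phase
#: protocols that begin dosing at a cycle boundary.  Same provenance as
#: :data:`MID_FOLLICULAR_STATE`.
CYCLE_START_STATE = np.array([
    107.2169, 10.6397, 24.1904, 10.6472,   # RP_LH, LH, RP_FSH, FSH
    0.1450, 0.1096, 0.1549,                # RcF, GrF, DomF
    1.1974, 3.6414,                        # Sc1, Sc2
    6.2486, 8.2502, 13.0357, 19.0919,      # Lut1..Lut4
])


class IntegrationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""

    def __init__(self, message: str, t: float):
        super().__init__(message)
        self.t = t


def constant_history(state) -> Callable[[float], np.ndarray]:
    """History function equal to ``state`` for all past times."""
    y = np.asarray(state, dtype=float).copy()
    if (y < 0).any():
        raise ValueError("history state must be nonnegative")

    def history(t):
        t = np.asarray(t, dtype=float)
        if t.ndim == 0:
            return y.copy()
        return np.repeat(y[:, None], t.size, axis=1)

    return history


class _ConstantDoses:
    """Minimal dose-schedule interface for a fixed (e, p) pair."""

    breakpoints: tuple[float, ...] = ()

    def __init__(self, e: float, p: float):
        if e < 0 or p < 0:
            raise ValueError("doses must be nonnegative")
        self.e = float(e)
        self.p = float(p)

    def doses_at(self, t):
        t = np.asarray(t, dtype=float)
        if t.ndim == 0:
            return self.e, self.p
        return np.full(t.shape, self.e), np.full(t.shape, self.p)


@dataclass
class Trajectory:
    """Densely evaluable DDE solution over ``[t0 - tau, t_end]``.

    ``t``/``y`` hold the accepted solver grid; ``__call__`` evaluates the
    continuous extension anywhere in range (snapping to stored values at
    grid points so interpolation never disagrees with the grid).
    """

    t0: float
    t_end: float
    tau: float
    t: np.ndarray                      # accepted time grid, shape (n,)
    y: np.ndarray                      # states at grid, shape (13, n) (or (m, n))
    history: Callable[[float], np.ndarray]
    doses: object                      # DoseSchedule-like, has doses_at / breakpoints
    params: ParameterSet | None
    meta: dict = field(default_factory=dict)
    burn_in: float | None = None       # analysis windows should start after this
    _seg_starts: list = field(default_factory=list, repr=False)
    _seg_sols: list = field(default_factory=list, repr=False)

    def __call__(self, t):
        scalar = np.ndim(t) == 0
        tq = np.atleast_1d(np.asarray(t, dtype=float))
        if (tq < self.t0 - self.tau - 1e-9).any() or (tq > self.t_end + 1e-9).any():
            raise ValueError(
                f"time out of range [{self.t0 - self.tau}, {self.t_end}]"
            )
        out = np.empty((self.y.shape[0], tq.size))
        past = tq <= self.t0
        if past.any():
            out[:, past] = self.history(tq[past])
        fut = ~past
        if fut.any():
            tf = tq[fut]
            idx = np.searchsorted(self._seg_starts, tf, side="right") - 1
            idx = np.clip(idx, 0, len(self._seg_sols) - 1)
            vals = np.empty((self.y.shape[0], tf.size))
            for seg in np.unique(idx):
                m = idx == seg
                vals[:, m] = self._seg_sols[seg](tf[m])
            # snap exact grid hits to stored states
            gpos = np.searchsorted(self.t, tf)
            gpos = np.clip(gpos, 0, self.t.size - 1)
            exact = self.t[gpos] == tf
            vals[:, exact] = self.y[:, gpos[exact]]
            out[:, fut] = vals
        return out[:, 0] if scalar else out

    # -- convenience accessors -------------------------------------------

    def sample(self, window: tuple[float, float], dt: float = 0.01):
        """Evaluate the solution on a regular grid over ``window``."""
        a, b = window
        ts = np.arange(a, b, dt)
        return ts, self(ts)

    def hormones(self, t):
        """Hormone panel (E2, P4, P_app, InhA) at time(s) ``t``."""
        if self.params is None:
            raise ValueError("trajectory has no model parameters attached")
        y = self(t)
        e, p = self.doses.doses_at(t)
        return np.asarray(_auxiliaries(y, e, p, self.params))


def dense_eval(traj: Trajectory, t):
    """Evaluate a trajectory's continuous extension (module-level alias)."""
    return traj(t)


def _segment_boundaries(t0: float, t_end: float, tau: float,
                        breakpoints: Sequence[float]) -> np.ndarray:
    """Integration restart points: multiples of tau from t0, plus dose
    breakpoints and their first two delay images (where the delayed term
    is not smooth)."""
    pts = {t0, t_end}
    k, t = 1, t0 + tau
    while t < t_end:
        pts.add(t)
        k += 1
        t = t0 + k * tau
    for bp in breakpoints:
        for img in (bp, bp + tau, bp + 2 * tau):
            if t0 < img < t_end:
                pts.add(img)
    bounds = np.array(sorted(pts))
    # drop near-duplicates
    keep = np.concatenate([[True], np.diff(bounds) > 1e-9])
    return bounds[keep]


def integrate_dde(
    rhs=dde_rhs,
    history: Callable[[float], np.ndarray] | None = None,
    t_span: tuple[float, float] = (0.0, 100.0),
    doses=None,
    params: ParameterSet | None = None,
    *,
    tau: float | None = None,
    delayed_observable: Callable[[np.ndarray], float] | None = None,
    rel_tol: float = DEFAULT_REL_TOL,
    abs_tol: float = DEFAULT_ABS_TOL,
) -> Trajectory:
    """Integrate a single-discrete-delay system by the method of steps.

    Parameters
    ----------
    rhs : callable ``rhs(t, y, delayed_value, doses_at_t, params)``
        Defaults to the cycle model's right-hand side.
    history : callable ``history(t) -> state``
        Defined for all ``t <= t0``.  Defaults to a constant history at
        :data:`MID_FOLLICULAR_STATE`.
    t_span : (t0, t_end)
    doses : dose schedule, ``(e, p)`` tuple, or None
        None uses the constant doses stored in ``params``.
    params : ParameterSet or None
        None uses the published defaults.  May be None for non-model
        systems if ``tau`` and ``delayed_observable`` are given.
    tau : float, optional
        Delay; defaults to ``params.tau``.
    delayed_observable : callable ``obs(state) -> float``, optional
        Scalar read from the solution at ``t - tau`` and fed to ``rhs``.
        Defaults to the model's inhibin A.
    rel_tol, abs_tol : float
        Solver tolerances, applied per method-of-steps interval.

    Notes
    -----
    The integration is fully deterministic: identical inputs produce
    bit-identical trajectories.
    """
    if rhs is dde_rhs and params is None:
        params = default_parameters()
    if tau is None:
        if params is None:
            raise ValueError("tau is required when no parameter set is given")
        tau = params.tau
    if tau <= 0:
        raise ValueError("tau must be positive")
    if rel_tol <= 0 or abs_tol <= 0:
        raise ValueError("tolerances must be positive")
    t0, t_end = map(float, t_span)
    if not t_end > t0:
        raise ValueError("t_span must have positive length")

    if doses is None:
        doses = _ConstantDoses(
            params.e_dose if params is not None else 0.0,
            params.p_dose if params is not None else 0.0,
        )
    elif isinstance(doses, tuple):
        doses = _ConstantDoses(*doses)

    if history is None:
        history = constant_history(MID_FOLLICULAR_STATE)
    if delayed_observable is None:
        obs = lambda y: inhibin_a(y, params)  # noqa: E731
    else:
        obs = delayed_observable

    seg_starts: list[float] = []
    seg_ends: list[float] = []
    seg_sols: list = []

    def delayed(t: float) -> float:
        td = t - tau
        if td <= t0 + 1e-13:
            return float(obs(history(min(td, t0))))
        i = bisect.bisect_right(seg_starts, td) - 1
        if i < 0 or td > seg_ends[i] + 1e-9:
            raise IntegrationError(f"delayed lookup outside history at t={t}", t)
        return float(obs(seg_sols[i](min(td, seg_ends[i]))))

    def f(t, y):
        return rhs(t, y, delayed(t), doses.doses_at(t), params)

    bounds = _segment_boundaries(t0, t_end, tau, tuple(doses.breakpoints))
    y = np.asarray(history(t0), dtype=float)
    ts: list[np.ndarray] = [np.array([t0])]
    ys: list[np.ndarray] = [y[:, None]]
    nfev = 0
    for a, b in zip(bounds[:-1], bounds[1:]):
        sol = solve_ivp(
            f, (a, b), y, method="RK45", dense_output=True,
            rtol=rel_tol, atol=abs_tol,
        )
        if not sol.success:
            raise IntegrationError(f"integration failed near t={sol.t[-1]}: "
                                   f"{sol.message}", float(sol.t[-1]))
        y = sol.y[:, -1]
        if not np.isfinite(y).all():
            bad = ", ".join(
                np.array(STATE_NAMES)[~np.isfinite(y)]
            ) if y.shape[0] == len(STATE_NAMES) else "state"
            raise IntegrationError(
                f"non-finite component(s) {bad} at t={b}", float(b)
            )
        seg_starts.append(float(a))
        seg_ends.append(float(b))
        seg_sols.append(sol.sol)
        ts.append(sol.t[1:])
        ys.append(sol.y[:, 1:])
        nfev += sol.nfev

    traj = Trajectory(
        t0=t0, t_end=t_end, tau=float(tau),
        t=np.concatenate(ts), y=np.concatenate(ys, axis=1),
        history=history, doses=doses, params=params,
        meta={"rel_tol": rel_tol, "abs_tol": abs_tol,
              "n_segments": len(seg_sols), "nfev": nfev},
    )
    traj._seg_starts = seg_starts
    traj._seg_sols = seg_sols
    return traj
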