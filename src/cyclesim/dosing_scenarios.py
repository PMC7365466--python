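"""Dose schedules and the standard simulation protocols.

Doses are blood concentrations, not pill contents: ``e_dose`` is exogenous
estrogen in pg/mL added to E2 and ``p_dose`` exogenous progestin in ng/mL
added to P4.  Two schedule shapes cover the study designs: a constant
schedule (chronic dosing) and a temporary schedule that switches on at
``t_start``, holds a constant level until ``t_stop``, then decays
exponentially with each drug's elimination half-life (washout; about one
day for progestins and two days for estrogens).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dde_engine import (
    CYCLE_START_STATE,
    DEFAULT_ABS_TOL,
    DEFAULT_REL_TOL,
    MID_FOLLICULAR_STATE,
    Trajectory,
    constant_history,
    integrate_dde,
)
from .model_core import ParameterSet, default_parameters

__all__ = [
    "DoseSchedule",
    "constant_schedule",
    "washout_schedule",
    "run_protocol",
    "nine_cycle_washout",
]

#: Default elimination half-lives (days).
HALF_LIFE_E = 2.0
HALF_LIFE_P = 1.0


@dataclass(frozen=True)
class DoseSchedule:
    """Piecewise dose pair ``(e_dose(t), p_dose(t))``.

    ``t_start``/``t_stop`` of None mean the dose is always on (constant
    schedule).  After ``t_stop`` each dose decays as
    ``level * 2**(-(t - t_stop)/t_half)``, which is continuous at the stop
    time.
    """

    e_level: float = 0.0
    p_level: float = 0.0
    t_start: float | None = None
    t_stop: float | None = None
    t_half_e: float = HALF_LIFE_E
    t_half_p: float = HALF_LIFE_P

    def __post_init__(self):
        if self.e_level < 0 or self.p_level < 0:
            raise ValueError("dose levels must be nonnegative")
        if self.t_half_e <= 0 or self.t_half_p <= 0:
            raise ValueError("half-lives must be positive")
        if (self.t_start is None) != (self.t_stop is None):
            raise ValueError("t_start and t_stop must be given together")
        if self.t_start is not None and not self.t_stop > self.t_start:
            raise ValueError("t_stop must exceed t_start")

    @property
    def breakpoints(self) -> tuple[float, ...]:
        if self.t_start is None:
            return ()
        return (self.t_start, self.t_stop)

    def doses_at(self, t):
        """Evaluate ``(e_dose, p_dose)`` at time(s) ``t`` (vectorized)."""
        t = np.asarray(t, dtype=float)
        if self.t_start is None:
            if t.ndim == 0:
                return self.e_level, self.p_level
            return (np.full(t.shape, self.e_level),
                    np.full(t.shape, self.p_level))
        on = (t >= self.t_start) & (t <= self.t_stop)
        after = t > self.t_stop
        dt = np.where(after, t - self.t_stop, 0.0)
        e = np.where(on, self.e_level, 0.0) + np.where(
            after, self.e_level * 2.0 ** (-dt / self.t_half_e), 0.0)
        p = np.where(on, self.p_level, 0.0) + np.where(
            after, self.p_level * 2.0 ** (-dt / self.t_half_p), 0.0)
        if t.ndim == 0:
            return float(e), float(p)
        return e, p


def constant_schedule(e: float = 0.0, p: float = 0.0) -> DoseSchedule:
    """Time-invariant dose pair; ``(0, 0)`` is the normal cycle."""
    return DoseSchedule(e_level=e, p_level=p)


def washout_schedule(
    e: float, p: float, t_start: float, t_stop: float,
    t_half_e: float = HALF_LIFE_E, t_half_p: float = HALF_LIFE_P,
) -> DoseSchedule:
    """Temporary dose: zero before ``t_start``, constant on
    ``[t_start, t_stop]``, exponential washout after."""
    return DoseSchedule(e_level=e, p_level=p, t_start=t_start,
                        t_stop=t_stop, t_half_e=t_half_e, t_half_p=t_half_p)


def run_protocol(
    schedule: DoseSchedule,
    params: ParameterSet | None = None,
    burn_in: float = 300.0,
    horizon: float = 600.0,
    history=None,
    rel_tol: float = DEFAULT_REL_TOL,
    abs_tol: float = DEFAULT_ABS_TOL,
) -> Trajectory:
    """Integrate a dosing protocol from the standard seed history.

    ``burn_in`` days at the start of the run are marked as transient and
    excluded from analysis windows (asymptotic analyses use at least three
    months so dosing effects and the arbitrary initial condition have both
    settled; protocols that replicate a published time course set it to 0).
    """
    if burn_in < 0 or not horizon > burn_in:
        raise ValueError("require horizon > burn_in >= 0")
    params = params or default_parameters()
    if history is None:
        history = constant_history(MID_FOLLICULAR_STATE)
    traj = integrate_dde(
        history=history, t_span=(0.0, horizon), doses=schedule,
        params=params, rel_tol=rel_tol, abs_tol=abs_tol,
    )
    traj.burn_in = float(burn_in)
    return traj


def nine_cycle_washout(
    e: float = 40.0, p: float = 0.6,
    params: ParameterSet | None = None,
    rel_tol: float = DEFAULT_REL_TOL,
    abs_tol: float = DEFAULT_ABS_TOL,
) -> Trajectory:
    """The temporary-dose protocol: nine nominal 28-day cycles.

    Three undosed cycles (days 0-84), three dosed cycles (dosing on
    [84, 168]), and three recovery cycles while the doses wash out with
    their respective half-lives.  The run starts at a cycle boundary
    (menstruation onset) so that dosing begins at the start of the fourth
    cycle, and uses no burn-in, mirroring the published layout.
    """
    schedule = washout_schedule(e, p, t_start=84.0, t_stop=168.0)
    return run_protocol(
        schedule, params=params, burn_in=0.0, horizon=252.0,
        history=constant_history(CYCLE_START_STATE),
        rel_tol=rel_tol, abs_tol=abs_tol,
    )
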