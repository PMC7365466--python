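"""Cycle statistics, asymptotic classification and contraception criteria.

The LH surge is the cycle's clock: the period is measured as the median
interval between successive surge maxima, each refined by a local
quadratic fit.  A treatment reaches "total contraception" when the
asymptotic solution is a constant steady state, operationalized as the LH
oscillation amplitude over the analysis window falling below a tolerance.
Biological contraception is assessed with the standard clinical surrogate
(peak P4 below 5 ng/mL implies suppressed ovulation) together with
suppression of the LH surge relative to the normal cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .dde_engine import Trajectory
from .dosing_scenarios import constant_schedule, run_protocol
from .model_core import ParameterSet

__all__ = [
    "CycleStats",
    "StateClassification",
    "ContraceptionReport",
    "TooFewSurgesError",
    "detect_lh_peaks",
    "cycle_period",
    "classify_asymptotic",
    "contraception_assessment",
    "reference_cycle",
    "default_amp_tol",
]

_LH = 1  # index of serum LH in the state vector

#: Ovulation-suppression surrogate: peak P4 below this (ng/mL) is read as
#: anovulatory.
P4_OVULATION_THRESHOLD = 5.0

#: A surge counts as suppressed when peak LH falls below this fraction of
#: the normal-cycle surge amplitude.
SURGE_SUPPRESSION_FRACTION = 0.5

#: Peak prominence required of an LH surge, as a fraction of the
#: normal-cycle surge amplitude (robust to numerical wiggles; conclusions
#: are insensitive within a decade).
PEAK_PROMINENCE_FRACTION = 0.1

#: Steady-state tolerance, as a fraction of the normal-cycle surge
#: amplitude.
AMP_TOL_FRACTION = 0.01


class TooFewSurgesError(RuntimeError):
    """Raised when a period is requested but the window has < 3 surges
    (possibly a steady-state regime)."""


@dataclass(frozen=True)
class CycleStats:
    """Summary of an oscillatory analysis window."""

    period: float                    # days
    surge_times: np.ndarray          # days
    surge_amplitude: float           # max - min of LH over window, IU/L
    hormone_extrema: dict = field(default_factory=dict)  # name -> (min, max)


@dataclass(frozen=True)
class StateClassification:
    """Periodic-versus-steady verdict for an analysis window."""

    label: str                       # "periodic" | "steady"
    amplitude: float                 # LH max - min over window, IU/L
    tolerance: float                 # amp_tol used
    state_amplitudes: np.ndarray | None = None  # per-state max-min / mean

    @property
    def is_steady(self) -> bool:
        return self.label == "steady"


@dataclass(frozen=True)
class ContraceptionReport:
    """Contraception criteria for a dosed run against a normal reference."""

    max_P4: float
    ovulation_suppressed: bool       # max P4 < threshold
    max_LH: float
    surge_ratio: float               # max LH / normal surge amplitude
    surge_suppressed: bool
    classification: StateClassification

    def as_dict(self) -> dict:
        return {
            "max_P4": self.max_P4,
            "ovulation_suppressed": self.ovulation_suppressed,
            "max_LH": self.max_LH,
            "surge_ratio": self.surge_ratio,
            "surge_suppressed": self.surge_suppressed,
            "label": self.classification.label,
            "lh_amplitude": self.classification.amplitude,
            "amp_tol": self.classification.tolerance,
        }


def _check_window(traj: Trajectory, window: tuple[float, float]) -> None:
    a, b = window
    if not b > a:
        raise ValueError("window must have positive length")
    if a < traj.t0 - 1e-9 or b > traj.t_end + 1e-9:
        raise ValueError(f"window {window} outside trajectory "
                         f"[{traj.t0}, {traj.t_end}]")
    if traj.burn_in is not None and a < traj.burn_in - 1e-9:
        raise ValueError(f"window starts inside the burn-in "
                         f"(first {traj.burn_in} days)")


def _lh_samples(traj: Trajectory, window, dt):
    ts, y = traj.sample(window, dt)
    return ts, y[_LH]


def detect_lh_peaks(
    traj: Trajectory,
    window: tuple[float, float],
    prominence: float | None = None,
    dt: float = 0.01,
    min_range: float = 1e-6,
) -> np.ndarray:
    """Times of LH surge maxima in ``window``.

    ``prominence`` is the absolute peak prominence (IU/L) required; pass
    ``PEAK_PROMINENCE_FRACTION`` times a normal-cycle surge amplitude when
    a reference is available.  When None, it defaults to that fraction of
    the window's own LH range, which is appropriate for measuring an
    undosed (fully oscillatory) run.  A window whose LH range is below
    ``min_range`` is treated as constant (no surges).

    Peak times are refined by a quadratic fit through the three samples
    around each discrete maximum.
    """
    _check_window(traj, window)
    ts, lh = _lh_samples(traj, window, dt)
    rng = float(lh.max() - lh.min()) if lh.size else 0.0
    if rng < min_range:
        return np.empty(0)
    if prominence is None:
        prominence = PEAK_PROMINENCE_FRACTION * rng
    idx, _ = find_peaks(lh, prominence=prominence)
    times = []
    for i in idx:
        y1, y2, y3 = lh[i - 1], lh[i], lh[i + 1]
        denom = y1 - 2.0 * y2 + y3
        shift = 0.5 * (y1 - y3) / denom if denom != 0 else 0.0
        times.append(ts[i] + dt * shift)
    return np.asarray(times)


def cycle_period(
    traj: Trajectory,
    window: tuple[float, float],
    prominence: float | None = None,
    dt: float = 0.01,
) -> float:
    """Median interval between successive LH surges (days).

    Raises :class:`TooFewSurgesError` when fewer than three surges are
    found, which signals a possibly-steady regime rather than a cycle.
    """
    surges = detect_lh_peaks(traj, window, prominence=prominence, dt=dt)
    if len(surges) < 3:
        raise TooFewSurgesError(
            f"only {len(surges)} LH surge(s) in window {window}; "
            "the regime may be steady"
        )
    return float(np.median(np.diff(surges)))


def classify_asymptotic(
    traj: Trajectory,
    window: tuple[float, float],
    amp_tol: float,
    dt: float = 0.02,
) -> StateClassification:
    """Label a window ``steady`` iff the LH oscillation amplitude
    (max - min) is below ``amp_tol``; per-state relative amplitudes are
    recorded as a secondary diagnostic."""
    _check_window(traj, window)
    if window[1] - window[0] < 90.0:
        raise ValueError("classification window must span >= 90 days "
                         "(about three nominal cycles)")
    ts, y = traj.sample(window, dt)
    amp = float(y[_LH].max() - y[_LH].min())
    means = np.abs(y.mean(axis=1))
    rel = (y.max(axis=1) - y.min(axis=1)) / np.where(means > 0, means, 1.0)
    label = "steady" if amp < amp_tol else "periodic"
    return StateClassification(label=label, amplitude=amp,
                               tolerance=float(amp_tol),
                               state_amplitudes=rel)


def reference_cycle(
    params: ParameterSet | None = None,
    burn_in: float = 300.0,
    window_length: float = 300.0,
    rel_tol: float | None = None,
    dt: float = 0.01,
) -> CycleStats:
    """Statistics of the undosed (normal) cycle after the transient.

    Runs the model with no exogenous doses, discards ``burn_in`` days and
    measures the next ``window_length`` days.
    """
    kwargs = {} if rel_tol is None else {"rel_tol": rel_tol}
    traj = run_protocol(constant_schedule(0.0, 0.0), params=params,
                        burn_in=burn_in, horizon=burn_in + window_length,
                        **kwargs)
    window = (burn_in, burn_in + window_length)
    ts, y = traj.sample(window, dt)
    surges = detect_lh_peaks(traj, window, dt=dt)
    hormones = traj.hormones(ts)
    extrema = {name: (float(h.min()), float(h.max()))
               for name, h in zip(("E2", "P4", "P_app", "InhA"), hormones)}
    extrema["LH"] = (float(y[_LH].min()), float(y[_LH].max()))
    period = float(np.median(np.diff(surges))) if len(surges) >= 3 else float("nan")
    return CycleStats(
        period=period,
        surge_times=surges,
        surge_amplitude=float(y[_LH].max() - y[_LH].min()),
        hormone_extrema=extrema,
    )


def default_amp_tol(reference: CycleStats) -> float:
    """Steady-state tolerance: 1% of the normal-cycle LH surge amplitude."""
    return AMP_TOL_FRACTION * reference.surge_amplitude


def contraception_assessment(
    traj: Trajectory,
    window: tuple[float, float],
    normal_reference: CycleStats,
    amp_tol: float | None = None,
    surge_fraction: float = SURGE_SUPPRESSION_FRACTION,
    p4_threshold: float = P4_OVULATION_THRESHOLD,
    dt: float = 0.02,
) -> ContraceptionReport:
    """Apply the contraception criteria to a dosed run.

    Reports (a) peak total P4 over the window against the anovulation
    surrogate threshold, (b) peak LH relative to the normal surge
    amplitude against the surge-suppression fraction, and (c) the
    periodic/steady classification.
    """
    if normal_reference is None:
        raise ValueError("a normal-cycle reference is required")
    _check_window(traj, window)
    if amp_tol is None:
        amp_tol = default_amp_tol(normal_reference)
    ts, y = traj.sample(window, dt)
    hormones = traj.hormones(ts)
    max_p4 = float(hormones[1].max())
    max_lh = float(y[_LH].max())
    ratio = max_lh / normal_reference.surge_amplitude
    return ContraceptionReport(
        max_P4=max_p4,
        ovulation_suppressed=max_p4 < p4_threshold,
        max_LH=max_lh,
        surge_ratio=ratio,
        surge_suppressed=ratio < surge_fraction,
        classification=classify_asymptotic(traj, window, amp_tol, dt=dt),
    )
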