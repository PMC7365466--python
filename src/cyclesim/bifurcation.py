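"""Equilibria and the Hopf boundary in the (e_dose, p_dose) plane.

Sufficiently high doses make the cycle collapse onto a constant steady
state ("total contraception"); the boundary between cycling and constancy
is a curve of Hopf bifurcations in dose space.  Two locators are provided:

* **Amplitude bisection** (primary): at each candidate dose the model is
  integrated from a fresh constant history, a burn-in is discarded, and
  the long-run LH oscillation amplitude is compared against a steady-state
  tolerance; the critical dose is found by bisection.  This is the
  operational definition used throughout the package and needs no
  continuation machinery.  Because the transient decays slowly near a Hopf
  point, the finite burn-in leaves a residual oscillation and the located
  dose depends (weakly) on the burn-in and tolerance chosen; see
  docs/methods.md.

* **Characteristic roots** (cross-check): the equilibrium is computed by
  root finding, the system is linearized about it, and the rightmost
  eigenvalue of the delay system's characteristic problem is found by
  Chebyshev collocation of the solution-operator generator.  The sign
  change of its real part is the Hopf point in the linear (infinite-time)
  sense.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, root

from .dde_engine import (
    DEFAULT_ABS_TOL,
    DEFAULT_REL_TOL,
    MID_FOLLICULAR_STATE,
    constant_history,
    integrate_dde,
)
from .model_core import (
    ParameterSet,
    default_parameters,
    dde_rhs,
    equilibrium_residual,
    inhibin_a,
)

__all__ = [
    "AmplitudeSettings",
    "Equilibrium",
    "HopfBoundary",
    "BracketError",
    "EquilibriumError",
    "find_equilibrium",
    "oscillation_amplitude",
    "critical_dose_bisection",
    "hopf_boundary_curve",
    "rightmost_characteristic_root",
    "critical_dose_linear",
]

_LH = 1


class BracketError(ValueError):
    """The bisection bracket does not straddle the boundary."""


class EquilibriumError(RuntimeError):
    """Equilibrium search failed to converge."""


@dataclass(frozen=True)
class AmplitudeSettings:
    """Settings for the long-run amplitude measurement.

    The burn-in must comfortably exceed three nominal cycles so both the
    seed history and the dose onset have settled; the window must cover
    several cycles of the slowest oscillation near the boundary (the
    near-Hopf period is ~30-40 days).
    """

    burn_in: float = 300.0
    window: float = 200.0
    dt: float = 0.02
    rel_tol: float = DEFAULT_REL_TOL
    abs_tol: float = DEFAULT_ABS_TOL
    seed_state: np.ndarray | None = None  # None -> MID_FOLLICULAR_STATE


@dataclass(frozen=True)
class Equilibrium:
    """A constant solution of the delay system at fixed doses."""

    state: np.ndarray
    doses: tuple[float, float]
    residual_norm: float
    rightmost_root: complex | None = None  # leading characteristic root

    @property
    def stable(self) -> bool | None:
        if self.rightmost_root is None:
            return None
        return self.rightmost_root.real < 0


@dataclass(frozen=True)
class HopfBoundary:
    """Critical (e_dose, p_dose) pairs traced over a progestin grid."""

    points: np.ndarray               # shape (n, 2): columns e_dose, p_dose
    bracket_widths: np.ndarray       # per-point final bracket width
    skipped: list = field(default_factory=list)  # (p, reason) pairs


def _long_run_state(doses, params, horizon=400.0, settings=None):
    s = settings or AmplitudeSettings()
    seed = s.seed_state if s.seed_state is not None else MID_FOLLICULAR_STATE
    traj = integrate_dde(
        history=constant_history(seed), t_span=(0.0, horizon), doses=doses,
        params=params, rel_tol=s.rel_tol, abs_tol=s.abs_tol,
    )
    return traj(horizon)


def find_equilibrium(
    doses: tuple[float, float],
    params: ParameterSet | None = None,
    seed: np.ndarray | None = None,
    residual_tol: float = 1e-8,
    with_stability: bool = False,
) -> Equilibrium:
    """Locate a nonnegative equilibrium at constant doses.

    When no seed is given, a 400-day integration provides one, so in
    steady regimes the search starts essentially on the root.  The root
    itself is polished with a damped-Newton solver (MINPACK hybr).
    """
    params = params or default_parameters()
    if seed is None:
        seed = _long_run_state(doses, params)
    seed = np.asarray(seed, dtype=float)

    sol = root(lambda y: equilibrium_residual(y, doses, params),
               seed, method="hybr", tol=1e-13)
    x = sol.x
    res = float(np.max(np.abs(equilibrium_residual(x, doses, params))))
    if res > residual_tol:
        raise EquilibriumError(
            f"no equilibrium at doses {doses}: residual max-norm {res:.3e} "
            f"after {sol.nfev} evaluations"
        )
    if (x < -1e-9).any():
        raise EquilibriumError(f"equilibrium at doses {doses} has negative "
                               "components")
    x = np.clip(x, 0.0, None)
    lam = rightmost_characteristic_root(x, doses, params) if with_stability else None
    return Equilibrium(state=x, doses=tuple(map(float, doses)),
                       residual_norm=res, rightmost_root=lam)


def oscillation_amplitude(
    doses: tuple[float, float],
    params: ParameterSet | None = None,
    settings: AmplitudeSettings | None = None,
) -> float:
    """Long-run LH oscillation amplitude (max - min, IU/L) at constant
    doses, from a fresh constant-history start.  Deterministic."""
    s = settings or AmplitudeSettings()
    params = params or default_parameters()
    seed = s.seed_state if s.seed_state is not None else MID_FOLLICULAR_STATE
    traj = integrate_dde(
        history=constant_history(seed),
        t_span=(0.0, s.burn_in + s.window),
        doses=tuple(doses), params=params,
        rel_tol=s.rel_tol, abs_tol=s.abs_tol,
    )
    ts = np.arange(s.burn_in, s.burn_in + s.window, s.dt)
    lh = traj(ts)[_LH]
    return float(lh.max() - lh.min())


def _doses_for(axis: str, value: float, fixed_value: float):
    if axis in ("e", "e_dose"):
        return (value, fixed_value)
    if axis in ("p", "p_dose"):
        return (fixed_value, value)
    raise ValueError(f"axis must be 'e_dose' or 'p_dose', got {axis!r}")


def critical_dose_bisection(
    axis: str,
    fixed_value: float,
    bracket: tuple[float, float],
    tol: float,
    amp_tol: float,
    params: ParameterSet | None = None,
    settings: AmplitudeSettings | None = None,
) -> float:
    """Critical dose along one axis by bisection on the amplitude indicator.

    The bracket must straddle the boundary: oscillatory (amplitude above
    ``amp_tol``) at the low end, steady below it at the high end.  Returns
    the bracket midpoint once its width is at most ``tol``.
    """
    lo, hi = map(float, bracket)
    if not hi > lo:
        raise ValueError("bracket must be increasing")
    amp_lo = oscillation_amplitude(_doses_for(axis, lo, fixed_value), params, settings)
    amp_hi = oscillation_amplitude(_doses_for(axis, hi, fixed_value), params, settings)
    if not (amp_lo > amp_tol and amp_hi < amp_tol):
        raise BracketError(
            f"bracket {bracket} does not straddle the boundary: "
            f"amplitude({lo})={amp_lo:.4g}, amplitude({hi})={amp_hi:.4g}, "
            f"amp_tol={amp_tol:.4g}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        amp = oscillation_amplitude(_doses_for(axis, mid, fixed_value), params, settings)
        if amp > amp_tol:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def hopf_boundary_curve(
    p_grid,
    e_bracket: tuple[float, float],
    tol: float,
    amp_tol: float,
    params: ParameterSet | None = None,
    settings: AmplitudeSettings | None = None,
) -> HopfBoundary:
    """Trace the boundary: for each progestin level in ``p_grid``, the
    critical estrogen dose by bisection.  Points whose bracket fails are
    recorded in ``skipped`` and omitted from the curve."""
    points, widths, skipped = [], [], []
    for p in np.asarray(p_grid, dtype=float):
        try:
            e_crit = critical_dose_bisection(
                "e_dose", p, e_bracket, tol, amp_tol, params, settings)
        except BracketError as err:
            skipped.append((float(p), str(err)))
            continue
        points.append((e_crit, p))
        widths.append(tol)
    return HopfBoundary(points=np.asarray(points),
                        bracket_widths=np.asarray(widths),
                        skipped=skipped)


# ---------------------------------------------------------------------------
# linearized cross-check
# ---------------------------------------------------------------------------

def _linearize(eq_state, doses, params, step=1e-6):
    """Jacobians of the rhs f(y, z) at an equilibrium: A = df/dy at fixed
    delayed input z, b = df/dz, and the gradient c of the delayed
    observable z = InhA(y)."""
    y0 = np.asarray(eq_state, dtype=float)
    z0 = inhibin_a(y0, params)
    n = y0.size
    A = np.empty((n, n))
    for j in range(n):
        h = step * max(1.0, abs(y0[j]))
        yp, ym = y0.copy(), y0.copy()
        yp[j] += h
        ym[j] -= h
        A[:, j] = (dde_rhs(0.0, yp, z0, doses, params)
                   - dde_rhs(0.0, ym, z0, doses, params)) / (2 * h)
    hz = step * max(1.0, abs(z0))
    b = (dde_rhs(0.0, y0, z0 + hz, doses, params)
         - dde_rhs(0.0, y0, z0 - hz, doses, params)) / (2 * hz)
    c = np.zeros(n)
    c[6], c[10], c[11] = params.h1, params.h2, params.h3
    return A, b, c


def _cheb_diff(n: int):
    """Chebyshev points on [-1, 1] and the differentiation matrix."""
    theta = np.pi * np.arange(n + 1) / n
    x = np.cos(theta)
    w = np.ones(n + 1)
    w[0] = w[n] = 2.0
    w *= (-1.0) ** np.arange(n + 1)
    X = np.tile(x, (n + 1, 1)).T
    dX = X - X.T + np.eye(n + 1)
    D = np.outer(w, 1.0 / w) / dX
    D -= np.diag(D.sum(axis=1))
    return x, D


def rightmost_characteristic_root(
    eq_state,
    doses: tuple[float, float],
    params: ParameterSet | None = None,
    n_nodes: int = 24,
) -> complex:
    """Rightmost eigenvalue of the linearized delay system at an
    equilibrium, via Chebyshev collocation on the delay interval.

    The linearization is ``u'(t) = A u(t) + b c^T u(t - tau)``; its
    spectrum is approximated by discretizing functions on [-tau, 0] at
    Chebyshev points and imposing the differential equation at the
    right endpoint.
    """
    params = params or default_parameters()
    A, b, c = _linearize(eq_state, doses, params)
    n = A.shape[0]
    _, D = _cheb_diff(n_nodes)
    D = D * (2.0 / params.tau)  # map [-1, 1] -> [-tau, 0]
    M = np.kron(D, np.eye(n))
    M[:n, :] = 0.0
    M[:n, :n] = A
    M[:n, n_nodes * n:] += np.outer(b, c)
    eigs = np.linalg.eigvals(M)
    return complex(eigs[np.argmax(eigs.real)])


def critical_dose_linear(
    axis: str,
    fixed_value: float,
    bracket: tuple[float, float],
    xtol: float = 1e-3,
    params: ParameterSet | None = None,
) -> float:
    """Hopf point along one axis from the sign change of the real part of
    the rightmost characteristic root (linear-stability cross-check).

    The bracket must lie inside the region where an equilibrium exists and
    is reachable by the default seed integration.
    """
    params = params or default_parameters()
    cache: dict[float, np.ndarray] = {}

    def re_lam(x: float) -> float:
        doses = _doses_for(axis, x, fixed_value)
        seed = cache.get("seed")
        eq = find_equilibrium(doses, params, seed=seed)
        cache["seed"] = eq.state
        return rightmost_characteristic_root(eq.state, doses, params).real

    lo, hi = map(float, bracket)
    # evaluate the steady (high-dose) end first so the equilibrium seed is
    # obtained where the long-run state sits on the equilibrium
    f_hi = re_lam(hi)
    f_lo = re_lam(lo)
    if f_lo * f_hi > 0:
        raise BracketError(
            f"no stability change in bracket {bracket}: "
            f"Re lambda = {f_lo:.3e} and {f_hi:.3e}"
        )
    return float(brentq(re_lam, lo, hi, xtol=xtol))
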