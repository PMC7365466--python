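"""Core equations of the hypothalamic-pituitary-ovarian cycle model.

The model tracks 13 dynamic states: two pituitary reserve pools and the
matching serum gonadotropins (``RP_LH``, ``LH``, ``RP_FSH``, ``FSH``), and a
nine-stage chain of ovarian "active tissue" masses moving through the
follicular phase (``RcF`` recruited, ``GrF`` growing, ``DomF`` dominant),
ovulation (``Sc1``, ``Sc2``) and the luteal phase (``Lut1``-``Lut4``).
Four auxiliary serum hormones are algebraic functions of the state:
estradiol ``E2``, progesterone ``P4``, the "apparent" progesterone signal
``P_app`` and inhibin A ``InhA``.  FSH synthesis responds to inhibin A with
a discrete delay ``tau``, which makes the system a delay differential
equation.

Exogenous hormonal contraception enters as constant (or scheduled)
concentration offsets ``e_dose`` (synthetic estrogen, pg/mL) added to E2
and ``p_dose`` (progestin, ng/mL) added to P4.  Two autocrine mechanisms
make the dosing contraceptive:

* recruited-follicle growth is divided by ``(1 + P_app/Ki_RcF_P)**xi``,
  so progesterone blunts follicular sensitivity to FSH;
* ``P_app = (P4/2) * (1 + E2**mu / (Km_Papp**mu + E2**mu))`` scales
  progesterone by an estrogen-dependent Hill factor modelling E2-driven
  progesterone-receptor upregulation, so estrogen potentiates progestin.

All quantities are treated numerically on the scales used by the published
parameter table (E2 in pg/mL, P4 in ng/mL, gonadotropin pools in IU,
serum gonadotropins in IU/L, ovarian masses in the model's own scaled
units); no dimensional conversion is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import ClassVar, Iterable, Mapping

import numpy as np

__all__ = [
    "STATE_NAMES",
    "STATE_UNITS",
    "HORMONE_NAMES",
    "HORMONE_UNITS",
    "LH_SYNTHESIS_HILL_EXPONENT",
    "ParameterSet",
    "HormonePanel",
    "default_parameters",
    "auxiliary_hormones",
    "inhibin_a",
    "dde_rhs",
    "equilibrium_residual",
]

#: Names of the 13 dynamic states, in integration order.
STATE_NAMES: tuple[str, ...] = (
    "RP_LH", "LH", "RP_FSH", "FSH",
    "RcF", "GrF", "DomF", "Sc1", "Sc2",
    "Lut1", "Lut2", "Lut3", "Lut4",
)

STATE_UNITS: tuple[str, ...] = (
    "IU", "IU/L", "IU", "IU/L",
    "mass", "mass", "mass", "mass", "mass",
    "mass", "mass", "mass", "mass",
)

HORMONE_NAMES: tuple[str, ...] = ("E2", "P4", "P_app", "InhA")
HORMONE_UNITS: tuple[str, ...] = ("pg/mL", "ng/mL", "ng/mL", "IU/mL")

#: Hill exponent of the estradiol term driving LH synthesis.  This is a
#: structural constant of the LH synthesis equation; it is kept separate
#: from the receptor-expression exponent ``mu`` (which happens to share the
#: numerical value 8) so the two can be varied independently.
LH_SYNTHESIS_HILL_EXPONENT: float = 8.0

# indices used by the fast paths below
_GRF, _DOMF, _LUT2, _LUT3, _LUT4 = 5, 6, 10, 11, 12


@dataclass(frozen=True)
class ParameterSet:
    """The 46 named model constants with their published default values.

    Pituitary parameters govern synthesis, release and clearance of LH and
    FSH; ovarian parameters govern transfer through the follicular/luteal
    stage chain; auxiliary parameters map stage masses to serum hormone
    concentrations.  ``e_dose`` and ``p_dose`` are the constant exogenous
    doses used when no explicit dose schedule is supplied.
    """

    # --- hypothalamus / pituitary ---
    V0_LH: float = 500.0        # basal LH synthesis, IU/day
    V1_LH: float = 4500.0       # E2-stimulated LH synthesis, IU/day
    Km_LH: float = 175.0        # E2 half-saturation of the LH surge term, pg/mL
    Ki_LH_P: float = 12.2       # P_app inhibition of LH synthesis, mL/ng
    k_LH: float = 2.42          # LH release rate, 1/day
    c_LH_P: float = 0.26        # P_app promotion of LH release, mL/ng
    c_LH_E: float = 0.004       # E2 inhibition of LH release, mL/pg
    a_LH: float = 14.0          # LH clearance, 1/day
    V_FSH: float = 375.0        # FSH synthesis scale, IU/day
    tau: float = 1.5            # inhibin A action delay, day
    Ki_FSH_InhA: float = 1.75   # InhA inhibition of FSH synthesis, IU/mL
    k_FSH: float = 1.9          # FSH release rate, 1/day
    c_FSH_P: float = 12.0       # P_app promotion of FSH release, mL/ng
    c_FSH_E: float = 0.0018     # E2^2 inhibition of FSH release, mL^2/pg^2
    a_FSH: float = 8.21         # FSH clearance, 1/day
    v: float = 2.5              # blood distribution volume, L

    # --- ovarian stage chain ---
    b: float = 0.34             # FSH-driven follicle recruitment
    Ki_RcF_P: float = 1.0       # P_app inhibition of recruited-follicle growth, mL/ng
    xi: float = 2.2             # exponent of the recruitment inhibition
    c1: float = 0.25            # FSH-driven self-amplified RcF growth
    c2: float = 0.07            # LH^alpha transfer RcF -> GrF
    c3: float = 0.027           # LH transfer GrF -> DomF
    c4: float = 0.51            # LH^gamma transfer DomF -> Sc1
    d1: float = 0.5             # Sc1 -> Sc2, 1/day
    d2: float = 0.56            # Sc2 -> Lut1, 1/day
    k1: float = 0.69            # Lut1 -> Lut2, 1/day
    k2: float = 0.86            # Lut2 -> Lut3, 1/day
    k3: float = 0.85            # Lut3 -> Lut4, 1/day
    k4: float = 0.85            # Lut4 decay, 1/day
    alpha: float = 0.79         # LH exponent in RcF -> GrF transfer
    gamma: float = 0.02         # LH exponent in DomF -> Sc1 transfer

    # --- auxiliary hormone production ---
    e0: float = 30.0            # basal estradiol, pg/mL
    e1: float = 0.30            # GrF contribution to E2, 1/L
    e2: float = 0.80            # DomF contribution to E2, 1/L
    e3: float = 1.67            # Lut4 contribution to E2, 1/L
    p0: float = 0.8             # basal progesterone, ng/mL
    p1: float = 0.15            # Lut3 contribution to P4, 1/kL
    p2: float = 0.13            # Lut4 contribution to P4, 1/kL
    Km_Papp: float = 75.0       # E2 half-saturation of receptor upregulation
    mu: float = 8.0             # Hill exponent of receptor upregulation
    h0: float = 0.4             # basal inhibin A, IU/mL
    h1: float = 0.009           # DomF contribution to InhA, IU/(ug mL)
    h2: float = 0.029           # Lut2 contribution to InhA, IU/(ug mL)
    h3: float = 0.018           # Lut3 contribution to InhA, IU/(ug mL)

    # --- exogenous doses ---
    p_dose: float = 0.0         # exogenous progestin, ng/mL
    e_dose: float = 0.0         # exogenous estrogen, pg/mL

    #: Parameters introduced by the contraception mechanisms (not present
    #: in the ancestral normal-cycle models).
    NEW_PARAMETERS: ClassVar[frozenset[str]] = frozenset(
        {"Ki_RcF_P", "xi", "Km_Papp", "mu"}
    )

    _POSITIVE: ClassVar[tuple[str, ...]] = (
        "V0_LH", "V1_LH", "Km_LH", "Ki_LH_P", "k_LH", "a_LH", "V_FSH",
        "tau", "Ki_FSH_InhA", "k_FSH", "a_FSH", "v",
        "b", "Ki_RcF_P", "xi", "c1", "c2", "c3", "c4",
        "d1", "d2", "k1", "k2", "k3", "k4", "alpha", "gamma",
        "e0", "p0", "Km_Papp", "mu", "h0",
    )
    _NONNEGATIVE: ClassVar[tuple[str, ...]] = (
        "c_LH_P", "c_LH_E", "c_FSH_P", "c_FSH_E",
        "e1", "e2", "e3", "p1", "p2", "h1", "h2", "h3",
        "p_dose", "e_dose",
    )

    def __post_init__(self) -> None:
        for name in self._POSITIVE:
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        for name in self._NONNEGATIVE:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name!r} must be nonnegative")

    @classmethod
    def names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.names()}

    def with_overrides(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the given parameters replaced.

        Unknown parameter names are rejected, so typos in override files
        cannot silently leave a default in place.
        """
        known = set(self.names())
        unknown = sorted(set(overrides) - known)
        if unknown:
            raise KeyError(f"unknown parameter(s): {', '.join(unknown)}")
        merged = self.as_dict()
        merged.update({k: float(v) for k, v in overrides.items()})
        return ParameterSet(**merged)

    @classmethod
    def from_file(cls, path) -> "ParameterSet":
        """Load a flat ``name: value`` override file (YAML) over the defaults."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ValueError(f"{path}: expected a flat name/value mapping")
        return cls().with_overrides(**data)


def default_parameters() -> ParameterSet:
    """Return the published default parameter set."""
    return ParameterSet()


@dataclass(frozen=True)
class HormonePanel:
    """Auxiliary serum hormones at one time point."""

    E2: float      # estradiol, pg/mL
    P4: float      # progesterone (endogenous + progestin dose), ng/mL
    P_app: float   # apparent progesterone signal, ng/mL
    InhA: float    # inhibin A, IU/mL

    def as_array(self) -> np.ndarray:
        return np.array([self.E2, self.P4, self.P_app, self.InhA])


def _as_state_array(state) -> np.ndarray:
    y = np.asarray(state, dtype=float)
    if y.shape != (len(STATE_NAMES),):
        raise ValueError(
            f"state must have {len(STATE_NAMES)} components, got shape {y.shape}"
        )
    return y


def _auxiliaries(y, e_dose: float, p_dose: float, p: ParameterSet):
    """Fast unchecked evaluation of (E2, P4, P_app, InhA).

    Accepts scalar state components or numpy arrays (vectorized over time).
    """
    E2 = p.e0 + p.e1 * y[_GRF] + p.e2 * y[_DOMF] + p.e3 * y[_LUT4] + e_dose
    P4 = p.p0 + p.p1 * y[_LUT3] + p.p2 * y[_LUT4] + p_dose
    Emu = E2 ** p.mu
    P_app = 0.5 * P4 * (1.0 + Emu / (p.Km_Papp ** p.mu + Emu))
    InhA = p.h0 + p.h1 * y[_DOMF] + p.h2 * y[_LUT2] + p.h3 * y[_LUT3]
    return E2, P4, P_app, InhA


def inhibin_a(state, params: ParameterSet) -> float:
    """Serum inhibin A implied by a state (the delayed observable)."""
    y = np.asarray(state, dtype=float)
    return params.h0 + params.h1 * y[_DOMF] + params.h2 * y[_LUT2] + params.h3 * y[_LUT3]


def auxiliary_hormones(
    state, e_dose: float = 0.0, p_dose: float = 0.0,
    params: ParameterSet | None = None,
) -> HormonePanel:
    """Compute the serum hormone panel implied by a state and dose pair.

    E2 and P4 are linear in the stage masses plus the exogenous dose;
    InhA is linear in the luteal-transition masses; P_app multiplies P4/2
    by ``1 + Hill(E2)`` and therefore lies in ``[P4/2, P4)``.

    Raises ``ValueError`` on negative state components or doses.
    """
    p = params or default_parameters()
    y = _as_state_array(state)
    if (y < 0).any():
        bad = STATE_NAMES[int(np.argmin(y))]
        raise ValueError(f"negative state component {bad!r}")
    if e_dose < 0 or p_dose < 0:
        raise ValueError("doses must be nonnegative")
    E2, P4, P_app, InhA = _auxiliaries(y, float(e_dose), float(p_dose), p)
    return HormonePanel(float(E2), float(P4), float(P_app), float(InhA))


def dde_rhs(t, state, delayed_InhA: float, doses, params: ParameterSet) -> np.ndarray:
    """Right-hand side of the 13-state delay system.

    Parameters
    ----------
    t : float
        Time in days (the system is autonomous except through `doses`).
    state : array-like, shape (13,)
        Current state in ``STATE_NAMES`` order.
    delayed_InhA : float
        Inhibin A evaluated at ``t - tau`` from the solution history.
    doses : (float, float)
        ``(e_dose, p_dose)`` at time ``t`` in (pg/mL, ng/mL).
    params : ParameterSet

    Returns
    -------
    numpy.ndarray, shape (13,)
        Time derivative of the state.
    """
    p = params
    y = np.asarray(state, dtype=float)
    if not np.isfinite(y).all():
        bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(y))]
        raise FloatingPointError(
            f"non-finite state component(s) {', '.join(bad)} at t={t!r}"
        )
    e_dose, p_dose = doses
    E2, P4, P_app, _ = _auxiliaries(y, e_dose, p_dose, p)

    RP_LH, LH, RP_FSH, FSH = y[0], y[1], y[2], y[3]
    RcF, GrF, DomF, Sc1, Sc2 = y[4], y[5], y[6], y[7], y[8]
    Lut1, Lut2, Lut3, Lut4 = y[9], y[10], y[11], y[12]

    # fractional LH powers need a nonnegative base; the solver may probe
    # values a rounding error below zero
    LH_pos = LH if LH > 0.0 else 0.0

    n = LH_SYNTHESIS_HILL_EXPONENT
    E2n = E2 ** n
    synth_LH = (p.V0_LH + p.V1_LH * E2n / (p.Km_LH ** n + E2n)) / (1.0 + P_app / p.Ki_LH_P)
    rel_LH = p.k_LH * (1.0 + p.c_LH_P * P_app) * RP_LH / (1.0 + p.c_LH_E * E2)
    synth_FSH = p.V_FSH / (1.0 + delayed_InhA / p.Ki_FSH_InhA)
    rel_FSH = p.k_FSH * (1.0 + p.c_FSH_P * P_app) * RP_FSH / (1.0 + p.c_FSH_E * E2 * E2)

    growth_RcF = (p.b + p.c1 * RcF) * FSH / (1.0 + P_app / p.Ki_RcF_P) ** p.xi
    lh_a = LH_pos ** p.alpha
    lh_g = LH_pos ** p.gamma

    d = np.empty(13)
    d[0] = synth_LH - rel_LH
    d[1] = rel_LH / p.v - p.a_LH * LH
    d[2] = synth_FSH - rel_FSH
    d[3] = rel_FSH / p.v - p.a_FSH * FSH
    d[4] = growth_RcF - p.c2 * lh_a * RcF
    d[5] = p.c2 * lh_a * RcF - p.c3 * LH * GrF
    d[6] = p.c3 * LH * GrF - p.c4 * lh_g * DomF
    d[7] = p.c4 * lh_g * DomF - p.d1 * Sc1
    d[8] = p.d1 * Sc1 - p.d2 * Sc2
    d[9] = p.d2 * Sc2 - p.k1 * Lut1
    d[10] = p.k1 * Lut1 - p.k2 * Lut2
    d[11] = p.k2 * Lut2 - p.k3 * Lut3
    d[12] = p.k3 * Lut3 - p.k4 * Lut4
    return d


def equilibrium_residual(state, doses, params: ParameterSet) -> np.ndarray:
    """Residual whose root is a constant solution of the delay system.

    At a constant solution the delayed inhibin A equals the current one,
    so the delay is immaterial and equilibria are roots of the
    instantaneous right-hand side.
    """
    y = _as_state_array(state)
    z = inhibin_a(y, params)
    return dde_rhs(0.0, y, z, doses, params)
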