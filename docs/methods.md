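# Methods

## Model and assumptions

The simulator implements a lumped endocrine feedback model of the
menstrual cycle.  Thirteen states evolve in time: pituitary reserve pools
and serum levels of LH and FSH, and nine ovarian active-tissue masses
(follicular stages RcF → GrF → DomF, ovulatory transition Sc1 → Sc2,
luteal stages Lut1 → … → Lut4).  Serum E2, P4 and inhibin A are assumed
to be in quasi-steady state with the tissue masses and are computed
algebraically; inhibin A feeds back on FSH synthesis with a discrete
delay of τ = 1.5 days, making the system a delay differential equation.
GnRH pulsatility is sub-day physiology and is deliberately lumped away —
the model predicts daily mean hormone levels, not pulse structure.

Hormonal contraception is modelled as constant (or scheduled) additive
offsets to the serum concentrations: `e_dose` (pg/mL) on E2 and `p_dose`
(ng/mL) on P4.  Exogenous hormone is assumed to act exactly like the
endogenous one.  No pharmacokinetics is modelled beyond the exponential
washout of a stopped dose; "dose" always means a blood concentration.

Two autocrine mechanisms carry the contraceptive action:

1. follicle recruitment is divided by `(1 + P_app/Ki_RcF_P)^xi`, so the
   progesterone signal blunts follicular sensitivity to FSH; and
2. `P_app = (P4/2)(1 + E2^mu/(Km_Papp^mu + E2^mu))` scales progesterone
   by an estrogen-dependent Hill factor (progesterone-receptor
   upregulation), so estrogen potentiates progestin.

`P_app` is used as the single progesterone signal everywhere progesterone
acts (pituitary and ovary alike); by construction it lies between P4/2
(no estrogen) and P4 (saturating estrogen).  The Hill exponent 8 in the
LH-synthesis term is a separate structural constant from the receptor
exponent `mu` (also 8); the two are stored independently so either can be
varied.

All 46 constants are kept at their published values and are treated
numerically on the printed scales.  The published table lists the
E2-saturation constant of the receptor Hill function with units "mL/ng"
although it multiplies E2 (pg/mL); we take the number (75) on the E2
scale and attempt no dimensional repair — this reproduces the original
numerics and we read the printed unit as a typo.  Similarly, the printed
FSH clearance is labelled `a_FSH,E`; the FSH equation requires a plain
clearance and no other candidate exists, so it is housed as
`a_FSH = 8.21/day`.

## Integration

The single discrete delay is handled by the method of steps: the time
axis is cut at every multiple of τ (and at every dose breakpoint plus its
first two delay images, where the solution loses smoothness), and each
interval is an ordinary initial-value problem solved with scipy's RK45
embedded pair, keeping its continuous extension.  Delayed inhibin A is
read from the already-computed interpolant, or from the history function
for times before the start.  Dose discontinuities are integration restart
points, preserving the solver's order of accuracy.  Default tolerances
are rel 1e-8 / abs 1e-10, tight enough that the measured cycle period is
converged well past two decimal places (halving the tolerances moves LH
at fixed probe times by under 1e-6 IU/L over a 60-day span, and the
period by far less than 0.001 day).  Everything is deterministic:
identical inputs give bit-identical trajectories.

The published study does not state initial conditions.  The packaged
seed histories are constant histories at states harvested from this
package's own converged normal cycle: `MID_FOLLICULAR_STATE` (about one
week before the LH surge) for general use, and `CYCLE_START_STATE`
(menstruation onset, half a period before the surge) for protocols that
must begin at a cycle boundary.  Any positive history reaches the same
attractor after the burn-in; these merely start close to it.

## Protocols and analysis windows

Chronic-dosing analyses integrate from the seed history with the dose on
from t = 0, discard a 300-day burn-in (comfortably more than the "three
months of treatment before analysis" convention, and enough for the
arbitrary history to settle) and measure over the following 200–300 days.

The temporary-dose protocol replicates the nine-cycle layout: three
undosed cycles (days 0–84), constant combined dosing on [84, 168], then
exponential washout at each drug's elimination half-life (1 day for
progestin, 2 days for estrogen).  The run starts at a cycle boundary so
dosing begins at the start of the fourth cycle, and uses no burn-in.

Cycle statistics: LH surges are local maxima of the densely sampled LH
signal exceeding a prominence threshold of 10 % of the normal-cycle surge
amplitude (the conclusions are insensitive to this fraction within a
decade); peak times are refined by a local quadratic fit; the period is
the median inter-surge interval, and at least three surges are required
before a period is reported.  A window is classified *steady* ("total
contraception") when the LH amplitude (max − min) falls below `amp_tol`,
defaulting to 1 % of the normal surge amplitude (≈ 1.07 IU/L).
Contraception reports combine (a) peak total P4 against the 5 ng/mL
clinical surrogate for suppressed ovulation, (b) peak LH against 50 % of
the normal surge amplitude (the literature does not quantify a
"non-ovulatory LH level"; the fraction is configurable and the reported
cases are order-of-magnitude suppressed, so the verdicts do not hinge on
it), and (c) the steady/periodic classification.

## Locating the cycling/steady boundary

Two independent locators are provided.

**Amplitude bisection (operational).**  At each candidate dose the model
is integrated from a fresh constant history, 300 days are discarded, and
the LH amplitude over the next 200 days is compared with `amp_tol`; the
critical dose is bisected to a bracket width of 0.5 pg/mL (estrogen axis)
or 0.05 ng/mL (progestin axis).  Fresh identical starts make the
indicator reproducible even if the bifurcation were subcritical.  With
the default settings this places the boundary at ≈ 87.4 pg/mL on the
estrogen-only axis and ≈ 1.02 ng/mL on the progestin-only axis.

**Characteristic roots (asymptotic).**  The equilibrium at the given
doses is found by root-finding on the instantaneous right-hand side
(delays are immaterial at constant solutions; seeds come from a long
integration, polished by MINPACK's hybrid Newton), the system is
linearized as `u' = A u(t) + b cᵀ u(t−τ)`, and the rightmost eigenvalue
is computed by Chebyshev collocation of the delay interval (24 nodes; the
leading root is converged to many digits at this resolution and agrees
with decay rates measured from nonlinear simulations to three
significant figures).  The Hopf point is the sign change of the real
part: 85.0 pg/mL and 1.193 ng/mL on the two axes, with a purely imaginary
pair (period ≈ 2π/0.21 ≈ 30 d and 2π/0.175 ≈ 36 d respectively).

The two locators disagree by a few percent *by design*: near a Hopf point
the leading mode decays at a rate proportional to the distance from the
boundary (measured decay exponents are ~0.001–0.006/day within a few
pg/mL of the boundary), so a finite 300-day burn-in leaves a residual
transient oscillation that the amplitude indicator reads as cycling.
The operational boundary therefore sits slightly outside the asymptotic
one and depends (weakly, and monotonically) on the burn-in and tolerance.
This is the same operational regime in which finite-time simulation
studies classify doses as "reaching steady state", which typically yields
higher reported thresholds than the linearized analysis of the identical
equations; both numbers are reported by this package rather than
reconciled.  On this parameter set the qualitative dose–response is
unambiguous either way: 92 pg/mL estrogen-only and 1.3 ng/mL
progestin-only are on the steady side, 40 pg/mL and 0.6 ng/mL alone are
cycling, and the combination (40, 0.6) is steady.

## Degenerate inputs and numerical guards

Fractional LH exponents (α = 0.79, γ = 0.02) are evaluated on
`max(LH, 0)` so that solver probes a rounding error below zero cannot
produce complex values; trajectories from nonnegative histories stay
nonnegative to solver tolerance.  Non-finite states abort integration
with the offending component and time.  Equilibrium searches reject
negative roots and residual max-norms above 1e-8.  Peak detection treats
a window whose LH range is below 1e-6 IU/L as constant.  Exact-grid-time
queries of a trajectory return the stored states, so interpolation can
never disagree with the accepted solver steps.

## Known limitations

* The model is qualitative: parameters are taken as given, no fitting to
  clinical time courses is performed, and FSH runs high under dosing
  because inhibin B (the follicular-phase FSH brake) is not modelled.
* A single `P_app` signal acts identically on brain and ovary; organ-
  specific progesterone action is outside scope.
* Washout is a pure exponential on concentration; no oral-administration
  pharmacokinetics.
* The boundary tracer assumes the amplitude indicator crosses `amp_tol`
  once within the bracket; brackets that do not straddle the boundary
  are reported, not repaired.
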