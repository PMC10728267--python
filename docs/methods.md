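# Methods

## Models and standing assumptions

The two-stage system tracks eggs E and larvae L with continuous T-periodic
coefficients: oviposition b_E, egg death d_E, hatching h, larval death d_L
(all nonnegative with positive average over a period) and larval competition
c (strictly positive).  Under these assumptions the positive quadrant is
invariant, solutions are eventually bounded, and any nonzero nonnegative
start is strictly positive in both components after one period, so the
period map Ψ_T is a positive, smooth, strongly monotone and strictly
subhomogeneous map.  The qualitative theory then leaves exactly two
outcomes, decided by the vectorial reproduction number R₀ of the origin
linearization: extinction when R₀ ≤ 1, and a unique positive T-periodic
orbit attracting all nonzero nonnegative starts when R₀ > 1.  The package
treats these statements as *numerically checkable predictions* and ships
the checkers; it does not re-derive the proofs.

The four-stage system adds pupae P and adults A, maturation rates τ_L, τ_P,
a female fraction σ ∈ (0, 1], and an oviposition function B(t, A): either
the saturating form B_S = b(t)/(1 + (A/K)^n) or the logistic form
B_L = b(t)(1 − A/K) on A ∈ [0, K).  With B_S and n = 1 the recruitment term
is strictly subhomogeneous on its own, so larval competition may be absent
(c ≡ 0).  Because a single positive stage needs up to three periods to
populate the whole cycle, positivity — and hence the monotone-map machinery —
applies to the 3T map; the T-periodicity of the resulting orbit is not
assumed but *verified*: the solver locates the 3T fixed point and certifies
that the T-map residual at it is below tolerance.

The bundle type for the four-stage model includes the hatching rate h as a
first-class coefficient (it appears in both the egg and larva equations and
is essential for the 3T positivity argument).

## Reproduction number

With F(t) = [[0, b_E(t)], [0, 0]] (new eggs) and
V(t) = [[d_E+h, 0], [−h, d_L]] (transitions), the sign test computes
ρ(Φ_{F−V}), the spectral radius of the monodromy matrix of
x' = (F−V)(t) x, and classifies it against 1 with a band of ±1e−6 (the
integration-accuracy limit).  The numeric R₀ is the unique λ > 0 with
ρ(λ) := ρ(Φ_{−V + F/λ}) = 1; ρ(λ) is strictly decreasing, so a geometric
pre-scan from λ = 1 brackets the root inside [1e−6, 1e6] and bisection on
log λ narrows it to relative width 1e−8 by default.  For constant
coefficients R₀ = b_E h / ((d_E + h) d_L) in closed form; this oracle is
kept separate from the Floquet path and used only for cross-checks.

Strongly seasonal oviposition (the climate presets reach b_E ≈ 200/day)
makes the fundamental matrix overflow double precision within one year
(log ρ ≈ 3000).  The monodromy integrator therefore chains 32 sub-interval
propagators and rescales the running product by its largest entry whenever
it exceeds 1e100, accumulating the log factor; spectral radii beyond
floating-point range are reported as `inf` with an exact
`log_spectral_radius`.

## Integration

All solves use adaptive RK45 with rtol 1e−9 / atol 1e−12 (Floquet
multipliers near 1 and 1e−6 fixed-point tolerances demand tight
integration), falling back to LSODA on failure.  Piecewise-linear
coefficients are only C⁰ at their corner times t₁…t₅; the integrator
restarts at every corner (unwrapped over periods) to preserve solver order.
Negative undershoot beyond −1e−9 is an error; smaller undershoot is clipped
to zero for the biological models (never for the odd-extended system).

## Periodic orbits

The orbit solver runs damped Newton on Ψ(x) − x, propagating state and
variational matrix together so DΨ is exact to solver tolerance; steps are
halved up to 8 times on residual increase, and a stalled Newton step falls
back to plain map iteration (safe in the persistent regime, where the orbit
attracts globally).  Without a user guess the solver first integrates 50
transient periods from the unit state (tests and examples use 10–20 for the
small-period scenarios).  Stability is classified from the multiplier
moduli with a ±1e−6 "marginal" band.  The attraction experiment iterates
the period map from several starts and reports the pairwise max-distance
history; non-convergence within the period cap (default 500) is a reported
outcome, not an error.

## Condition checkers

The persistence hypotheses are evaluated on a uniform grid of 2048 points
per period (plus coefficient corners).  "Zero" means |f(t)| ≤ 1e−12·max(1,
f^M) — ramp endpoints of piecewise profiles do not evaluate to exact zeros
in floating point.  Inequalities are strict: a margin of exactly 0 fails.
The gap condition reports sup d_L/b_E and inf h/(d_E+h) over the active set
{t : b_E ≠ 0 and h ≠ 0} and is undefined (reported, not raised) when that
set is empty on the grid.

The explicit dissipativity bounds follow the comparison-equation route: for
the two-stage system U_M = (b_E^M + d_E^M − d_L^m)²/(4c^m) when the net
inflow coefficient is positive (else 0), and the eventual bound K is the
maximum over one period of the attracting periodic solution of
y' = −d_E(t) y + U_M, computed by integrating 50 periods from the
mean-value start and taking the last-period maximum, inflated by
ε = 1e−6·scale.  The four-stage analogue replaces d_E by the mortality
floor M(t) = min(d_E, d_L, d_P, d_A) and U_M by K·b^M.

## Extinction construction

The seasonal extinction example uses trapezoid profiles: b_E, d_E, h at
their plateau on [0, t₁] ∪ [t₅, T], zero on [t₂, t₄]; d_L at its plateau
until t₂ and zero only on [t₃, t₄].  Defaults are the published values
(0.1, 0.05, 0.02, 0.3; times 2, 15, 180, 199, 199.6; T = 200).  The
contraction factor λ has two modes.  *Measured*: λ is the spectral radius
of the one-period monodromy of the linear system (the asymptotic per-period
contraction), with the per-component ratios E(T)/E₀, L(T)/L₀ reported
alongside.  *Exact*: the coefficients are frozen at their plateau beyond t₅
and the first time T' > t₅ at which the trajectory returns to the ray
{s·P₀} is root-found; the construction is returned with period T', so the
period map contracts exactly along the ray and the k-period state is λᵏP₀.
The default P₀ is (1, 1): the linear flow maps every positive start to
slope L/E ≈ 0.78–0.86 at t₅ regardless of its initial slope, so an exact
ray return requires a P₀ slope above that value; (1, 1) lies in the
admissible cone Γ₁ (E > (b̄_E/(d̄_E+h̄))·L ≈ 0.286·L) and safely above the
t₅ slope.

One derivation note: inside Γ₁ the sign condition for the egg equation of
the linear system on the active windows reads Ė ≥ 0 iff
E ≤ (b̄_E/(d̄_E+h̄))·L — the bound is proportional to L, not a constant.
Statements of the condition that drop the factor L appear in the
literature; the implementation uses the full inequality.

## Synthetic scenarios

Two seeded generators emulate realistic inputs.

*Persistence-hypothesis sets* (`gen_persistent_scenario`): strictly
positive truncated random Fourier series for b_E, h, c (3 harmonics,
rescaled to a band of ±amplitude around a drawn midpoint; amplitude default
0.4), constant d_E = 0.05/day, and d_L built as r(t)·b_E(t) with
max r = frac · inf h/(d_E+h), frac drawn in [0.3, 0.5] — so the gap
condition holds by construction with known margin and the implied R₀ is
roughly 1/frac.  All rates strictly positive makes the zero-linkage
conditions vacuous.  Midpoint bands (b_E ∈ [0.3, 1.2], h ∈ [0.25, 0.5],
c ∈ [0.05, 0.2]) are chosen so the resulting orbits are O(1–10) in size and
integrate quickly; at amplitude 0 every rate is constant and the closed-form
R₀ applies.

*Climate-like presets* (`gen_climate_like`): each rate is a raised cosine
spanning exactly the published min–max interval of its scenario (tropical
or temperate), with one peak per year and constant d_E = 0.05/day.  Phases
encode the narrative — oviposition and hatching peak in the wet/warm season
while larval competition peaks in the opposite season; the seed jitters the
peak days by ±10 days without leaving the ranges.  What these presets do
*not* emulate: the actual interpolated thermal/rainfall response curves
(multi-modal shapes, inter-parameter correlation).  Passing tests on them
demonstrate the qualitative chain (hypotheses → R₀ > 1 → unique attracting
cycle) for rates confined to realistic ranges, not agreement with any
specific climate record.  Consequently the persistence margins
inf h/(d_E+h) are exact functions of the printed ranges, while sup d_L/b_E
depends mildly on the phases.

Monthly tables (12 samples) are interpolated at month midpoints of a
365-day year with a periodic shape-preserving monotone cubic (PCHIP on a
three-year tiling, evaluated on the central year) — plain cubic splines can
overshoot below zero on rate data; periodic-linear interpolation is
available as an option.

## Problem sizes used in tests

Synthetic persistence scenarios run with T = 30–60 days (the theory is
period-agnostic and shorter periods keep orbit shooting fast); climate
presets use the full 365-day year; the four-stage scenarios use T = 40 with
(σ, K) = (0.5, 100).  The acceptance script evaluates the climate margins
on an 8001-point grid and the extinction monodromy over its full 200-day
period.

## Known limitations

- The four-stage model with B_L, or B_S with n > 1, combined with c > 0 is
  supported for simulation but the orbit-uniqueness certificate (3T → T
  reduction) is only claimed for B_S with n = 1; other forms warn.
- R₀ values for strongly supercritical seasonal systems are limited by the
  renormalized-monodromy accuracy; classifications remain reliable.
- No stochasticity, spatial structure, or delayed stages; no fitting of
  thermal-response curves to temperature records — coefficient inputs are
  taken as given (TOML/CSV) or generated synthetically.
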