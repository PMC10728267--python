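"""Periodic orbit of the four-stage model with larval competition.

Uses the egg-larva-pupa-adult system with saturating oviposition
B_S(t, A) = b(t)/(1 + A/K) and c > 0, locates the fixed point of the
three-period Poincaré map (the positivity horizon), and certifies that it
is in fact a one-period fixed point — the orbit is T-periodic.
"""

import numpy as np

import mosquitodyn as md
from mosquitodyn.periodic import constant, from_expression

T = 40.0


def seasonal(base, amp, phase=0.0):
    return from_expression(
        lambda t: base * (1 + amp * np.cos(2 * np.pi * (np.asarray(t, float) - phase) / T)), T)


coeffs = md.FourStageCoefficients(
    b=seasonal(5.0, 0.3), d_E=constant(0.05, T), d_L=constant(0.05, T),
    d_P=constant(0.05, T), d_A=seasonal(0.1, 0.2, 10.0), h=seasonal(0.3, 0.2),
    tau_L=constant(0.1, T), tau_P=constant(0.2, T), c=constant(0.001, T),
    sigma=0.5, K_carry=100.0)

orbit = md.four_stage_orbit(coeffs, tol=1e-6, transient_periods=20)
x = orbit.fixed_point
print(f"orbit start (E*, L*, P*, A*): {np.round(x, 3)}")
print(f"T-map residual at the 3T fixed point: "
      f"{np.max(np.abs(md.poincare_map(coeffs, x, 1) - x)):.2e}")
print(f"stability: {orbit.stability}  "
      f"(multiplier moduli {np.round(np.abs(orbit.multipliers), 4)})")

rep = md.positivity_3T_check(coeffs, [np.eye(4)[i] for i in range(4)])
print(f"positivity at 3T from single-stage starts: {rep.holds}")
print("A population seeded in any single stage fills all four stages within")
print("three seasons and settles on the unique yearly cycle above.")
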