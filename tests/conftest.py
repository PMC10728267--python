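import numpy as np
import pytest

from mosquitodyn.periodic import (FourStageCoefficients, TwoStageCoefficients,
                                  constant, from_expression)

# Constant-coefficient reference set used across modules: persistent regime,
# closed-form equilibrium E* = b_E L*/(d_E+h), L* = (b_E h/(d_E+h) - d_L)/c.
CONST = dict(b_E=0.1, d_E=0.05, d_L=0.02, h=0.3, c=0.01)
CONST_T = 50.0


@pytest.fixture(scope="session")
def const_coeffs() -> TwoStageCoefficients:
    return TwoStageCoefficients(
        constant(CONST["b_E"], CONST_T, "b_E"),
        constant(CONST["d_E"], CONST_T, "d_E"),
        constant(CONST["d_L"], CONST_T, "d_L"),
        constant(CONST["h"], CONST_T, "h"),
        constant(CONST["c"], CONST_T, "c"),
    )


@pytest.fixture(scope="session")
def const_equilibrium() -> np.ndarray:
    bE, dE, dL, h, c = (CONST[k] for k in ("b_E", "d_E", "d_L", "h", "c"))
    L = (bE * h / (dE + h) - dL) / c
    E = bE * L / (dE + h)
    return np.array([E, L])


def seasonal(base: float, amp_frac: float, T: float, phase: float = 0.0):
    """Strictly positive single-harmonic profile base*(1 + a cos(...))."""

    def ev(t, b=base, a=amp_frac, p=phase, T=T):
        return b * (1.0 + a * np.cos(2.0 * np.pi * (np.asarray(t, float) - p) / T))

    return from_expression(ev, T)


@pytest.fixture(scope="session")
def four_stage_seasonal() -> FourStageCoefficients:
    """Persistent seasonal four-stage set with competition (c > 0)."""
    T = 40.0
    return FourStageCoefficients(
        b=seasonal(5.0, 0.3, T), d_E=constant(0.05, T),
        d_L=constant(0.05, T), d_P=constant(0.05, T),
        d_A=seasonal(0.1, 0.2, T, 10.0), h=seasonal(0.3, 0.2, T),
        tau_L=constant(0.1, T), tau_P=constant(0.2, T),
        c=constant(0.001, T), sigma=0.5, K_carry=100.0)


@pytest.fixture(scope="session")
def four_stage_const() -> FourStageCoefficients:
    """Autonomous four-stage set; its periodic orbit is the equilibrium."""
    T = 40.0
    return FourStageCoefficients(
        b=constant(5.0, T), d_E=constant(0.05, T), d_L=constant(0.05, T),
        d_P=constant(0.05, T), d_A=constant(0.1, T), h=constant(0.3, T),
        tau_L=constant(0.1, T), tau_P=constant(0.2, T), c=constant(0.001, T),
        sigma=0.5, K_carry=100.0)


def four_stage_equilibrium_oracle(c4: FourStageCoefficients) -> np.ndarray:
    """Equilibrium of the autonomous four-stage system by a scalar root-find.

    E, L, P are eliminated in favour of A; the larval balance becomes a
    scalar equation solved by bisection.  Independent of the orbit solver.
    """
    from scipy.optimize import brentq

    t = 0.0
    b, dE, dL, dP, dA = (c4.b(t), c4.d_E(t), c4.d_L(t), c4.d_P(t), c4.d_A(t))
    h, tL, tP, c = c4.h(t), c4.tau_L(t), c4.tau_P(t), c4.c(t)
    sig, K = c4.sigma, c4.K_carry

    def L_of(A):
        return (dP + tP) * dA * A / (tL * sig * tP)

    def resid(A):
        E = b / (1.0 + A / K) * A / (dE + h)
        L = L_of(A)
        return h * E - (dL + tL) * L - c * L * L

    A = brentq(resid, 1e-9, 1e9, xtol=1e-12, rtol=1e-14)
    L = L_of(A)
    P = dA * A / (sig * tP)
    E = b / (1.0 + A / K) * A / (dE + h)
    return np.array([E, L, P, A])
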