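"""Monodromy matrices, Floquet multipliers, and the vectorial reproduction
number R0 of the seasonal egg-larvae model.

For a T-periodic linear system x' = J(t) x the monodromy matrix is the
fundamental matrix X(T) with X(0) = I; its eigenvalues are the Floquet
multipliers.  Linearizing the egg-larvae system at the origin and splitting
the Jacobian into new-recruitment (F, the oviposition term) and transition
(V, death and hatching) parts, the spectral radius rho(Phi_{F-V}) of the
monodromy of x' = (F(t) - V(t)) x sits on the same side of 1 as R0: the
population persists iff rho > 1.  The numeric value of R0 itself is the
unique lambda > 0 for which the monodromy of x' = (-V(t) + F(t)/lambda) x
has spectral radius exactly 1, found here by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .dynamics import DEFAULT_ATOL, DEFAULT_RTOL, simulate
from .periodic import TwoStageCoefficients

__all__ = [
    "MonodromyResult",
    "R0Result",
    "monodromy",
    "r0_sign_test",
    "r0_value",
    "autonomous_r0_oracle",
    "fv_jacobian",
    "CLASS_TOL",
]

#: Half-width of the "at one" classification band on rho(Phi_{F-V}).
CLASS_TOL = 1e-6


@dataclass
class MonodromyResult:
    """Fundamental matrix at the horizon, its eigenvalues and spectral radius.

    Strongly seasonal oviposition rates can make the fundamental matrix grow
    past floating-point range within one period; the integration then
    renormalizes by a scalar and accumulates ``log_scale``, so ``matrix``
    and ``multipliers`` refer to the rescaled matrix while
    ``spectral_radius`` (and ``log_spectral_radius``) include the factor.
    ``log_scale`` is 0 whenever no renormalization was needed, in which case
    ``matrix`` is the plain fundamental matrix.
    """

    horizon: float
    matrix: np.ndarray
    multipliers: np.ndarray
    spectral_radius: float
    log_scale: float = 0.0

    @property
    def log_spectral_radius(self) -> float:
        with np.errstate(divide="ignore"):
            return float(np.log(np.max(np.abs(self.multipliers))) +
                         self.log_scale)

    @classmethod
    def from_matrix(cls, horizon: float, X: np.ndarray,
                    log_scale: float = 0.0) -> "MonodromyResult":
        eig = np.linalg.eigvals(X)
        with np.errstate(over="ignore"):
            rho = float(np.max(np.abs(eig)) * np.exp(log_scale))
        return cls(horizon, X, eig, rho, log_scale)


@dataclass
class R0Result:
    """Classification of R0 against 1, optionally with its numeric value."""

    classification: str  # below_one | at_one | above_one
    rho: float
    value: float | None = None
    bracket: tuple[float, float] | None = None
    tolerance: float | None = None
    meta: dict = field(default_factory=dict)


def monodromy(jacobian_provider: Callable[[float], np.ndarray], horizon: float,
              breakpoints=(), period_T: float | None = None,
              rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
              segments: int = 32) -> MonodromyResult:
    """Integrate X' = J(t) X, X(0) = I over [0, horizon] and diagonalize X(horizon).

    All columns are propagated together as a flattened matrix ODE, in
    ``segments`` sub-intervals chained by the propagator product
    X(horizon) = Phi_n ... Phi_1.  After each segment the running product is
    rescaled by its largest entry once it exceeds 1e100, which keeps the
    integration inside floating-point range for strongly supercritical
    systems (the accumulated factor is reported as ``log_scale``).
    ``breakpoints``/``period_T`` trigger restarts at coefficient corners,
    exactly as in state-space integration.
    """
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    dim = np.asarray(jacobian_provider(0.0)).shape[0]

    def rhs(t, xflat):
        X = xflat.reshape(dim, dim)
        return (np.asarray(jacobian_provider(t)) @ X).ravel()

    edges = np.linspace(0.0, horizon, max(1, segments) + 1)
    M = np.eye(dim)
    log_scale = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        traj = simulate(rhs, np.eye(dim).ravel(), (a, b),
                        rtol=rtol, atol=atol, breakpoints=breakpoints,
                        period_T=period_T, clip_nonnegative=False,
                        t_eval=[a, b])
        M = traj.final.reshape(dim, dim) @ M
        s = float(np.max(np.abs(M)))
        if s > 1e100:
            M /= s
            log_scale += np.log(s)
    return MonodromyResult.from_matrix(horizon, M, log_scale)


def fv_jacobian(coeffs: TwoStageCoefficients, lam: float = 1.0):
    """t -> -V(t) + F(t)/lam for the origin linearization.

    F(t) = [[0, b_E(t)], [0, 0]] (new eggs from larvae),
    V(t) = [[d_E(t)+h(t), 0], [-h(t), d_L(t)]] (deaths and stage transfer).
    lam = 1 recovers the origin Jacobian F - V.
    """

    def J(t: float) -> np.ndarray:
        bE, dE, dL, h = (coeffs.b_E(t), coeffs.d_E(t), coeffs.d_L(t),
                         coeffs.h(t))
        return np.array([[-(dE + h), bE / lam], [h, -dL]])

    return J


def _rho(coeffs: TwoStageCoefficients, lam: float, rtol, atol) -> float:
    res = monodromy(fv_jacobian(coeffs, lam), coeffs.period_T,
                    breakpoints=coeffs.breakpoints(),
                    period_T=coeffs.period_T, rtol=rtol, atol=atol)
    return res.spectral_radius


def _classify(rho: float, class_tol: float) -> str:
    if rho > 1.0 + class_tol:
        return "above_one"
    if rho < 1.0 - class_tol:
        return "below_one"
    return "at_one"


def r0_sign_test(coeffs: TwoStageCoefficients, class_tol: float = CLASS_TOL,
                 rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL) -> R0Result:
    """Persistence/extinction classification from rho(Phi_{F-V}) vs 1."""
    rho = _rho(coeffs, 1.0, rtol, atol)
    return R0Result(_classify(rho, class_tol), rho)


def r0_value(coeffs: TwoStageCoefficients,
             bracket: tuple[float, float] = (1e-6, 1e6),
             tol: float = 1e-8, class_tol: float = CLASS_TOL,
             rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL) -> R0Result:
    """Numeric R0 by bisection on lambda with rho(lambda) = 1.

    rho(lambda), the spectral radius of the monodromy of
    x' = (-V(t) + F(t)/lambda) x, is strictly decreasing in lambda, so a
    geometric pre-scan locates a sign change of rho - 1 inside ``bracket``
    and bisection (on log lambda) narrows it to relative width ``tol``.
    """
    lo, hi = bracket
    if not (0 < lo < hi):
        raise ValueError("bracket must satisfy 0 < lo < hi")
    rho1 = _rho(coeffs, 1.0, rtol, atol)
    if abs(rho1 - 1.0) <= class_tol:
        return R0Result("at_one", rho1, value=1.0, bracket=(1.0, 1.0),
                        tolerance=tol)

    def g(lam: float) -> float:
        return _rho(coeffs, lam, rtol, atol) - 1.0

    # geometric pre-scan from lambda = 1 toward the side rho - 1 points to
    a, ga = 1.0, rho1 - 1.0
    b = a
    factor = 4.0 if ga > 0 else 0.25
    gb = ga
    while np.sign(gb) == np.sign(ga):
        b *= factor
        if not (lo <= b <= hi):
            raise ValueError(
                f"no sign change of rho-1 found within bracket {bracket}; "
                "widen the bracket"
            )
        gb = g(b)
    if b < a:
        a, b = b, a
        ga, gb = gb, ga
    # bisection on log lambda; rho - 1 is decreasing so ga > 0 > gb
    while (b - a) / a > tol:
        mid = float(np.sqrt(a * b))
        if g(mid) > 0:
            a = mid
        else:
            b = mid
    value = float(np.sqrt(a * b))
    return R0Result(_classify(rho1, class_tol), rho1, value=value,
                    bracket=(a, b), tolerance=tol)


def autonomous_r0_oracle(b_E: float, d_E: float, d_L: float, h: float) -> float:
    """Closed-form R0 for constant coefficients: b_E h / ((d_E + h) d_L).

    This is the spectral radius of F V^{-1} for the constant splitting, and
    serves as an independent check on the periodic machinery.
    """
    if any(v <= 0 for v in (b_E, d_E, d_L, h)):
        raise ValueError("autonomous oracle needs strictly positive constants")
    denom = (d_E + h) * d_L
    return b_E * h / denom
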