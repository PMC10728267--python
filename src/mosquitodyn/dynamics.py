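"""Right-hand sides, Jacobians and the ODE simulation contract.

Four vector fields are provided:

* the nonlinear egg-larvae system (quadratic larval competition),
* its odd extension to the whole plane (used to study the origin as a saddle),
* the linear comparison system (competition term dropped),
* the four-stage egg-larva-pupa-adult system with saturating or logistic
  oviposition.

Integration goes through :func:`simulate`, a thin adaptive-solver wrapper
that restarts at the corner times of piecewise-linear coefficients (the
vector field is only C^0 there) and clips solver-level negative undershoot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .periodic import FourStageCoefficients, TwoStageCoefficients

__all__ = [
    "Trajectory",
    "IntegrationError",
    "rhs_two_stage",
    "rhs_extended",
    "rhs_linear",
    "rhs_four_stage",
    "oviposition",
    "jacobian_two_stage",
    "jacobian_four_stage",
    "origin_jacobian_two_stage",
    "origin_jacobian_four_stage",
    "simulate",
    "simulate_two_stage",
    "simulate_four_stage",
    "rhs_for",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
]

DEFAULT_RTOL = 1e-9
DEFAULT_ATOL = 1e-12
CLIP_TOL = 1e-9


class IntegrationError(RuntimeError):
    """Adaptive ODE solve failed (both non-stiff and stiff attempts)."""


@dataclass
class Trajectory:
    """Time-stamped state sequence from an ODE solve.

    ``states`` has shape (len(times), ndim); ``solver_meta`` records method,
    tolerances and step counts for reproducibility.
    """

    times: np.ndarray
    states: np.ndarray
    solver_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.states = np.asarray(self.states, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory states must be finite")

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]


# -- right-hand sides ------------------------------------------------------


def rhs_two_stage(t: float, s, coeffs: TwoStageCoefficients) -> np.ndarray:
    """Egg-larvae vector field: E' = b_E L - (d_E + h) E, L' = h E - d_L L - c L^2."""
    if coeffs.is_linear:
        raise ValueError("coefficients lack c; use rhs_linear for the linear system")
    E, L = s
    bE, dE, dL, h, c = (coeffs.b_E(t), coeffs.d_E(t), coeffs.d_L(t),
                        coeffs.h(t), coeffs.c(t))
    return np.array([bE * L - (dE + h) * E, h * E - dL * L - c * L * L])


def rhs_extended(t: float, s, coeffs: TwoStageCoefficients) -> np.ndarray:
    """Odd extension of the egg-larvae field to the whole (E, L) plane.

    The competition term becomes sign(L) * c(t) L^2, making the field odd:
    (-E(t), -L(t)) solves the system whenever (E(t), L(t)) does.  The
    extension is C^1 but not C^2 across L = 0.
    """
    if coeffs.is_linear:
        raise ValueError("coefficients lack c; use rhs_linear for the linear system")
    E, L = s
    bE, dE, dL, h, c = (coeffs.b_E(t), coeffs.d_E(t), coeffs.d_L(t),
                        coeffs.h(t), coeffs.c(t))
    comp = c * L * L if L >= 0 else -c * L * L
    return np.array([bE * L - (dE + h) * E, h * E - dL * L - comp])


def rhs_linear(t: float, s, coeffs: TwoStageCoefficients) -> np.ndarray:
    """Linear comparison system: the competition term dropped."""
    E, L = s
    bE, dE, dL, h = coeffs.b_E(t), coeffs.d_E(t), coeffs.d_L(t), coeffs.h(t)
    return np.array([bE * L - (dE + h) * E, h * E - dL * L])


def oviposition(form: str, t: float, A: float, b: Callable, K_carry: float,
                n: float = 1.0) -> float:
    """Per-female oviposition rate B(t, A).

    ``form='BS'``: saturating b(t) / (1 + (A/K)^n); ``form='BL'``: logistic
    b(t)(1 - A/K), defined only for A in [0, K).
    """
    bt = b(t)
    if form == "BS":
        return bt / (1.0 + (A / K_carry) ** n)
    if form == "BL":
        if not (0 <= A < K_carry):
            raise ValueError(f"B_L requires A in [0, K); got A={A}, K={K_carry}")
        return bt * (1.0 - A / K_carry)
    raise ValueError(f"unknown oviposition form {form!r}")


def rhs_four_stage(t: float, s, coeffs: FourStageCoefficients) -> np.ndarray:
    """Four-stage vector field with oviposition B(t, A) A feeding the eggs."""
    E, L, P, A = s
    if A <= -coeffs.K_carry:
        raise ValueError(f"A = {A} <= -K; oviposition denominator vanishes")
    B = oviposition(coeffs.oviposition_form, t, A, coeffs.b, coeffs.K_carry,
                    coeffs.n)
    dE, dL, dP, dA = (coeffs.d_E(t), coeffs.d_L(t), coeffs.d_P(t),
                      coeffs.d_A(t))
    h = coeffs.h(t)
    tL, tP, c = coeffs.tau_L(t), coeffs.tau_P(t), coeffs.c(t)
    return np.array([
        B * A - dE * E - h * E,
        h * E - dL * L - c * L * L - tL * L,
        tL * L - dP * P - tP * P,
        coeffs.sigma * tP * P - dA * A,
    ])


# -- Jacobians -------------------------------------------------------------


def jacobian_two_stage(t: float, s, coeffs: TwoStageCoefficients) -> np.ndarray:
    """Jacobian of the egg-larvae field at (t, s); variational-equation matrix.

    [[-(d_E + h), b_E], [h, -(d_L + 2 c L)]].  Off-diagonals are nonnegative
    (the system is cooperative), which is what makes the period map strongly
    monotone.
    """
    _, L = s
    bE, dE, dL, h = coeffs.b_E(t), coeffs.d_E(t), coeffs.d_L(t), coeffs.h(t)
    cterm = 0.0 if coeffs.is_linear else 2.0 * coeffs.c(t) * L
    return np.array([[-(dE + h), bE], [h, -(dL + cterm)]])


def origin_jacobian_two_stage(coeffs: TwoStageCoefficients):
    """t -> Jacobian at the origin: [[-(d_E+h), b_E], [h, -d_L]] (the F - V matrix)."""

    def J(t: float) -> np.ndarray:
        bE, dE, dL, h = (coeffs.b_E(t), coeffs.d_E(t), coeffs.d_L(t),
                         coeffs.h(t))
        return np.array([[-(dE + h), bE], [h, -dL]])

    return J


def jacobian_four_stage(t: float, s, coeffs: FourStageCoefficients) -> np.ndarray:
    """Jacobian of the four-stage field at (t, s).

    For the saturating form with n = 1 the oviposition column uses the
    analytic derivative d(B_S A)/dA = b(t) / (1 + A/K)^2; other forms fall
    back to a central finite difference of the recruitment term.
    """
    E, L, P, A = s
    dE, dL, dP, dA = (coeffs.d_E(t), coeffs.d_L(t), coeffs.d_P(t),
                      coeffs.d_A(t))
    h = coeffs.h(t)
    tL, tP, c = coeffs.tau_L(t), coeffs.tau_P(t), coeffs.c(t)
    if coeffs.oviposition_form == "BS" and coeffs.n == 1.0:
        dBA = coeffs.b(t) / (1.0 + A / coeffs.K_carry) ** 2
    else:
        eps = 1e-6 * (1.0 + abs(A))
        fp = oviposition(coeffs.oviposition_form, t, A + eps, coeffs.b,
                         coeffs.K_carry, coeffs.n) * (A + eps)
        fm = oviposition(coeffs.oviposition_form, t, max(A - eps, 0.0),
                         coeffs.b, coeffs.K_carry, coeffs.n) * max(A - eps, 0.0)
        dBA = (fp - fm) / (eps + min(eps, A))
    return np.array([
        [-(dE + h), 0.0, 0.0, dBA],
        [h, -(dL + 2.0 * c * L + tL), 0.0, 0.0],
        [0.0, tL, -(dP + tP), 0.0],
        [0.0, 0.0, coeffs.sigma * tP, -dA],
    ])


def origin_jacobian_four_stage(coeffs: FourStageCoefficients):
    """t -> Jacobian of the four-stage field at the origin."""

    def J(t: float) -> np.ndarray:
        return jacobian_four_stage(t, np.zeros(4), coeffs)

    return J


# -- integration -----------------------------------------------------------


def _segment_times(t0: float, t1: float, period_T: float,
                   breakpoints: Sequence[float]) -> np.ndarray:
    """All coefficient corner times in (t0, t1), unwrapped over periods."""
    if not breakpoints:
        return np.array([t0, t1])
    bps = np.asarray(sorted(set(breakpoints)), float)
    k0 = int(np.floor(t0 / period_T)) - 1
    k1 = int(np.ceil(t1 / period_T)) + 1
    all_bps = (bps[None, :] + period_T * np.arange(k0, k1 + 1)[:, None]).ravel()
    inner = all_bps[(all_bps > t0 + 1e-12) & (all_bps < t1 - 1e-12)]
    return np.concatenate([[t0], np.sort(inner), [t1]])


def simulate(rhs: Callable, x0, t_span: tuple[float, float],
             rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
             t_eval=None, breakpoints: Sequence[float] = (),
             period_T: float | None = None, clip_nonnegative: bool = True,
             method: str = "RK45") -> Trajectory:
    """Adaptive ODE solve with breakpoint restarts and stiff fallback.

    ``breakpoints`` (times within one period where the vector field is only
    C^0) are unwrapped over ``period_T`` and the integration is restarted at
    each, preserving solver order across corners.  On solver failure the
    integration is retried once with LSODA.  Negative undershoot below
    -CLIP_TOL raises; smaller undershoot is clipped to zero when
    ``clip_nonnegative`` is set.
    """
    x0 = np.asarray(x0, float)
    if not np.all(np.isfinite(x0)):
        raise ValueError("initial state must be finite")
    t0, t1 = map(float, t_span)
    if not t1 > t0:
        raise ValueError("t_span must be increasing")

    if breakpoints and period_T is None:
        raise ValueError("period_T is required when breakpoints are given")
    seg = (_segment_times(t0, t1, period_T, breakpoints)
           if breakpoints else np.array([t0, t1]))

    te = None if t_eval is None else np.asarray(t_eval, float)
    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    nfev = 0
    used_method = method
    x = x0.copy()
    for a, b in zip(seg[:-1], seg[1:]):
        if te is not None:
            mask = (te >= a) & (te < b) if b < t1 else (te >= a) & (te <= b)
            seg_eval = np.union1d(te[mask], [a, b])
        else:
            seg_eval = None
        sol = solve_ivp(rhs, (a, b), x, method=used_method, rtol=rtol,
                        atol=atol, t_eval=seg_eval, dense_output=False)
        if not sol.success and used_method != "LSODA":
            used_method = "LSODA"
            sol = solve_ivp(rhs, (a, b), x, method=used_method, rtol=rtol,
                            atol=atol, t_eval=seg_eval)
        if not sol.success:
            raise IntegrationError(
                f"ODE solve failed on [{a}, {b}]: {sol.message}"
            )
        nfev += sol.nfev
        x = sol.y[:, -1].copy()
        if clip_nonnegative:
            x[(x < 0) & (x > -CLIP_TOL)] = 0.0
        keep_t, keep_y = sol.t, sol.y
        if te is not None:
            sel = np.isin(keep_t, te) if b < t1 else np.isin(keep_t, te)
            keep_t, keep_y = keep_t[sel], keep_y[:, sel]
        if times and keep_t.size and times[-1].size and keep_t[0] <= times[-1][-1]:
            keep_t, keep_y = keep_t[1:], keep_y[:, 1:]
        times.append(keep_t)
        states.append(keep_y.T)

    t_all = np.concatenate(times)
    y_all = np.vstack(states)
    if clip_nonnegative:
        y_all = np.where((y_all < 0) & (y_all > -CLIP_TOL), 0.0, y_all)
    if t_all.size == 0 or t_all[0] > t0:
        t_all = np.concatenate([[t0], t_all])
        y_all = np.vstack([x0, y_all])
    meta = {"method": used_method, "rtol": rtol, "atol": atol, "nfev": nfev}
    return Trajectory(t_all, y_all, meta)


def rhs_for(coeffs, model: str = "auto") -> tuple[Callable, tuple[float, ...], float]:
    """Resolve (rhs closure, breakpoints, period) for a coefficient bundle.

    ``model`` is one of 'auto', 'two_stage', 'linear', 'extended',
    'four_stage'.  'auto' picks the nonlinear two-stage field (or the linear
    one when the bundle has no competition term) for two-stage bundles, and
    the four-stage field otherwise.
    """
    if isinstance(coeffs, FourStageCoefficients):
        if model not in ("auto", "four_stage"):
            raise ValueError(f"model {model!r} invalid for four-stage coefficients")
        return (lambda t, s: rhs_four_stage(t, s, coeffs),
                coeffs.breakpoints(), coeffs.period_T)
    if model == "auto":
        model = "linear" if coeffs.is_linear else "two_stage"
    table = {"two_stage": rhs_two_stage, "linear": rhs_linear,
             "extended": rhs_extended}
    if model not in table:
        raise ValueError(f"unknown model {model!r}")
    f = table[model]
    return (lambda t, s: f(t, s, coeffs), coeffs.breakpoints(), coeffs.period_T)


def simulate_two_stage(coeffs: TwoStageCoefficients, x0, t_span,
                       model: str = "auto", **kw) -> Trajectory:
    rhs, bps, T = rhs_for(coeffs, model)
    clip = model != "extended"
    return simulate(rhs, x0, t_span, breakpoints=bps, period_T=T,
                    clip_nonnegative=kw.pop("clip_nonnegative", clip), **kw)


def simulate_four_stage(coeffs: FourStageCoefficients, x0, t_span, **kw) -> Trajectory:
    rhs, bps, T = rhs_for(coeffs)
    return simulate(rhs, x0, t_span, breakpoints=bps, period_T=T, **kw)
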