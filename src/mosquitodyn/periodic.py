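"""T-periodic coefficient functions for seasonal mosquito models.

All model rates (oviposition, death, hatching, stage transitions, larval
competition) are represented as :class:`PeriodicFunction` objects: nonnegative,
piecewise-continuous functions of time (in days) with a common period ``T``.
Constructors are provided for the coefficient shapes that matter in practice:
constants, continuous trapezoid (piecewise-linear) seasonal profiles with a
zero window, periodic interpolants of monthly climatological tables, and the
composite oviposition rate obtained by collapsing the pupal and adult stages
of a four-stage life cycle onto the egg equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PeriodicFunction",
    "TwoStageCoefficients",
    "FourStageCoefficients",
    "constant",
    "from_expression",
    "make_trapezoid_profile",
    "make_monthly_interpolant",
    "composite_oviposition",
    "extremes",
    "average",
    "zero_tolerance",
    "MONTH_MIDPOINTS",
]

#: Default number of grid points per period for extremes/averages/zero sets.
DEFAULT_GRID_N = 2048

#: Midpoints (in days) of the 12 months of a 365-day year.
_MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], float)
MONTH_MIDPOINTS = np.cumsum(_MONTH_LENGTHS) - _MONTH_LENGTHS / 2.0


class CoefficientError(ValueError):
    """Raised when a coefficient specification violates a model assumption."""


class EvaluationError(ArithmeticError):
    """Raised when a coefficient evaluates to a non-finite value."""


@dataclass(frozen=True)
class PeriodicFunction:
    """A T-periodic, nonnegative scalar rate function of time in days.

    Parameters
    ----------
    period_T:
        Period in days, > 0.
    evaluator:
        Vectorised callable mapping time (already reduced mod T by
        :meth:`__call__`) to a rate.  Units are 1/day, except for the larval
        competition coefficient which is larvae^-1 day^-1.
    label:
        Human-readable name used in error messages and reports.
    breakpoints:
        Times in [0, T] where the function is only C^0 (e.g. the corners of a
        piecewise-linear profile).  ODE integrations restart at these times to
        preserve the order of the adaptive solver.
    """

    period_T: float
    evaluator: Callable[[np.ndarray], np.ndarray]
    label: str = ""
    breakpoints: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if not (self.period_T > 0):
            raise CoefficientError(f"period_T must be > 0, got {self.period_T}")

    def __call__(self, t):
        """Evaluate at time ``t`` (scalar or array), wrapping periodically."""
        if isinstance(t, (float, int)):  # fast path: ODE right-hand sides
            tau = t % self.period_T
            out = self.evaluator(tau)
            out = float(out) if isinstance(out, np.ndarray) else out
            if not math.isfinite(out):
                raise EvaluationError(
                    f"coefficient {self.label!r} is non-finite at t={tau}"
                )
            return out
        t = np.asarray(t, dtype=float)
        tau = np.mod(t, self.period_T)
        out = np.asarray(self.evaluator(tau), dtype=float)
        if not np.all(np.isfinite(out)):
            bad = tau if out.ndim == 0 else np.asarray(tau)[~np.isfinite(out)].flat[0]
            raise EvaluationError(
                f"coefficient {self.label!r} is non-finite at t={bad}"
            )
        return out if out.ndim else float(out)

    # -- queries -----------------------------------------------------------

    def extremes(self, grid_n: int = DEFAULT_GRID_N) -> tuple[float, float]:
        """Grid minimum and maximum over one period (superscripts m / M)."""
        return extremes(self, grid_n)

    def average(self, grid_n: int = DEFAULT_GRID_N) -> float:
        """Mean value (1/T) * integral over one period."""
        return average(self, grid_n)

    def grid(self, grid_n: int = DEFAULT_GRID_N) -> tuple[np.ndarray, np.ndarray]:
        t = np.linspace(0.0, self.period_T, grid_n)
        return t, self(t)


def extremes(f: PeriodicFunction, grid_n: int = DEFAULT_GRID_N) -> tuple[float, float]:
    """Minimum and maximum of ``f`` on a uniform grid of ``grid_n`` points.

    The grid includes breakpoints of piecewise-linear profiles, so plateau and
    zero-window values are recovered exactly.
    """
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    t = np.linspace(0.0, f.period_T, grid_n)
    if f.breakpoints:
        t = np.union1d(t, np.asarray(f.breakpoints, float))
    v = f(t)
    return float(np.min(v)), float(np.max(v))


def average(f: PeriodicFunction, grid_n: int = DEFAULT_GRID_N) -> float:
    """(1/T) * integral of ``f`` over [0, T] by composite trapezoid rule.

    Breakpoints are inserted into the quadrature grid so piecewise-linear
    profiles are integrated exactly.
    """
    t = np.linspace(0.0, f.period_T, grid_n)
    if f.breakpoints:
        t = np.union1d(t, np.asarray(f.breakpoints, float))
    v = f(t)
    return float(np.trapezoid(v, t) / f.period_T)


def zero_tolerance(f: PeriodicFunction, grid_n: int = DEFAULT_GRID_N) -> float:
    """Numerical threshold below which ``f(t)`` counts as zero.

    Ramp endpoints of piecewise-linear profiles evaluate to tiny nonzero
    values in floating point; condition sets such as {t : b_E(t) != 0} use
    this scale-aware tolerance.
    """
    _, fM = extremes(f, grid_n)
    return 1e-12 * max(1.0, fM)


# -- constructors ----------------------------------------------------------


def constant(value: float, period_T: float, label: str = "") -> PeriodicFunction:
    """A constant rate, as a degenerate periodic function."""
    if value < 0:
        raise CoefficientError(f"constant coefficient {label!r} must be >= 0")
    v = float(value)
    return PeriodicFunction(period_T, lambda t: np.full_like(np.asarray(t, float), v),
                            label or f"const({value})")


def from_expression(fn: Callable[[np.ndarray], np.ndarray], period_T: float,
                    label: str = "", breakpoints: Sequence[float] = ()) -> PeriodicFunction:
    """Wrap a closed-form expression of time as a periodic coefficient."""
    return PeriodicFunction(period_T, fn, label, tuple(breakpoints))


def make_trapezoid_profile(plateau: float, t1: float, t2: float, t4: float,
                           t5: float, T: float, label: str = "") -> PeriodicFunction:
    """Continuous piecewise-linear seasonal profile with a zero window.

    Equals ``plateau`` on [0, t1] and [t5, T], zero on [t2, t4], and is linear
    on the ramps [t1, t2] and [t4, t5].  This is the shape used to model a
    favourable season bracketing an adverse (e.g. diapause) window in which a
    rate switches off.
    """
    if not (0 < t1 < t2 < t4 < t5 < T):
        raise CoefficientError(
            f"trapezoid times must satisfy 0 < t1 < t2 < t4 < t5 < T, "
            f"got ({t1}, {t2}, {t4}, {t5}, {T})"
        )
    if plateau < 0:
        raise CoefficientError("plateau must be >= 0")
    xp = np.array([0.0, t1, t2, t4, t5, T])
    fp = np.array([plateau, plateau, 0.0, 0.0, plateau, plateau])

    def ev(t, xp=xp, fp=fp):
        return np.interp(t, xp, fp)

    return PeriodicFunction(T, ev, label or "trapezoid",
                            breakpoints=(t1, t2, t4, t5))


def make_monthly_interpolant(values: Sequence[float], T: float = 365.0,
                             method: str = "pchip", label: str = "") -> PeriodicFunction:
    """Periodic interpolant through 12 monthly samples at month midpoints.

    ``method='pchip'`` (default) gives a shape-preserving monotone-limited
    cubic that cannot overshoot below zero between nonnegative samples;
    ``method='linear'`` gives a periodic piecewise-linear interpolant.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (12,):
        raise CoefficientError("monthly interpolant needs exactly 12 samples")
    if not np.all(np.isfinite(values)):
        raise CoefficientError("monthly samples must be finite")
    if np.any(values < 0):
        raise CoefficientError("monthly samples must be nonnegative")

    # Anchor nodes at month midpoints, padded one year either side so the
    # interpolant (and, for pchip, its node derivatives) is exactly periodic
    # on the central year.
    x = np.concatenate([MONTH_MIDPOINTS - T, MONTH_MIDPOINTS, MONTH_MIDPOINTS + T])
    y = np.tile(values, 3)

    if method == "pchip":
        from scipy.interpolate import PchipInterpolator

        interp = PchipInterpolator(x, y, extrapolate=False)

        def ev(t, interp=interp):
            return interp(np.asarray(t, float))
    elif method == "linear":
        def ev(t, x=x, y=y):
            return np.interp(np.asarray(t, float), x, y)
    else:
        raise CoefficientError(f"unknown interpolation method {method!r}")

    return PeriodicFunction(T, ev, label or "monthly")


def composite_oviposition(beta_E: PeriodicFunction, tau_L: PeriodicFunction,
                          tau_P: PeriodicFunction, d_P: PeriodicFunction,
                          d_A: PeriodicFunction, grid_n: int = DEFAULT_GRID_N,
                          label: str = "b_E") -> PeriodicFunction:
    """Two-stage oviposition rate from four-stage life-history rates.

    b_E(t) = beta_E(t) * (tau_P(t) / d_A(t)) * (tau_L(t) / (tau_P(t) + d_P(t)))

    collapses adult lifespan (1/d_A), pupal emergence success
    (tau_P/(tau_P+d_P) folded with larval maturation tau_L) onto the per-larva
    egg-production rate of the reduced egg-larvae system.
    """
    fns = (beta_E, tau_L, tau_P, d_P, d_A)
    T = beta_E.period_T
    if any(abs(f.period_T - T) > 1e-9 for f in fns):
        raise CoefficientError("composite oviposition inputs must share the period")
    tgrid = np.linspace(0.0, T, grid_n)
    dA = d_A(tgrid)
    denom = tau_P(tgrid) + d_P(tgrid)
    for name, arr in (("d_A", dA), ("tau_P + d_P", denom)):
        idx = np.flatnonzero(arr <= 0)
        if idx.size:
            raise CoefficientError(
                f"composite oviposition: {name} vanishes at t={tgrid[idx[0]]:.4g}"
            )

    def ev(t):
        t = np.asarray(t, float)
        return beta_E(t) * (tau_P(t) / d_A(t)) * (tau_L(t) / (tau_P(t) + d_P(t)))

    bps = tuple(sorted({bp for f in fns for bp in f.breakpoints}))
    return PeriodicFunction(T, ev, label, breakpoints=bps)


# -- coefficient bundles ---------------------------------------------------


def _merged_breakpoints(fns) -> tuple[float, ...]:
    return tuple(sorted({bp for f in fns if f is not None for bp in f.breakpoints}))


@dataclass(frozen=True)
class TwoStageCoefficients:
    """Rate bundle for the seasonal egg-larvae system.

        E' = b_E(t) L - d_E(t) E - h(t) E
        L' = h(t) E  - d_L(t) L - c(t) L^2

    b_E, d_E, d_L, h are nonnegative with positive average over a period;
    the larval competition coefficient c is strictly positive.  Passing
    ``c=None`` selects the linear variant (the c-term dropped), used for
    comparison arguments in the extinction construction; the nonlinear
    right-hand sides refuse to run without c.
    """

    b_E: PeriodicFunction
    d_E: PeriodicFunction
    d_L: PeriodicFunction
    h: PeriodicFunction
    c: PeriodicFunction | None = None
    grid_n: int = DEFAULT_GRID_N

    def __post_init__(self) -> None:
        named = [("b_E", self.b_E), ("d_E", self.d_E), ("d_L", self.d_L),
                 ("h", self.h)]
        T = self.b_E.period_T
        for name, f in named + ([("c", self.c)] if self.c is not None else []):
            if abs(f.period_T - T) > 1e-9:
                raise CoefficientError(f"{name} period {f.period_T} != {T}")
        for name, f in named:
            if average(f, self.grid_n) <= 1e-14:
                raise CoefficientError(
                    f"{name} must have positive average over one period"
                )
        if self.c is not None:
            cm, _ = extremes(self.c, self.grid_n)
            if cm <= 0:
                raise CoefficientError("c must be strictly positive on the grid")

    @property
    def period_T(self) -> float:
        return self.b_E.period_T

    @property
    def is_linear(self) -> bool:
        """True for the c-less comparison system."""
        return self.c is None

    def breakpoints(self) -> tuple[float, ...]:
        return _merged_breakpoints((self.b_E, self.d_E, self.d_L, self.h, self.c))


@dataclass(frozen=True)
class FourStageCoefficients:
    """Rate bundle for the seasonal egg-larva-pupa-adult system.

        E' = B(t, A) A - d_E(t) E - h(t) E
        L' = h(t) E - d_L(t) L - c(t) L^2 - tau_L(t) L
        P' = tau_L(t) L - d_P(t) P - tau_P(t) P
        A' = sigma tau_P(t) P - d_A(t) A

    The oviposition function B is either the saturating form
    B_S(t, A) = b(t) / (1 + (A/K)^n) or the logistic form
    B_L(t, A) = b(t) (1 - A/K) for A in [0, K).  ``sigma`` is the female
    fraction of emerging adults and ``K_carry`` the adult carrying capacity.
    Unlike the two-stage bundle, c may be identically zero here: the
    saturating oviposition supplies the subhomogeneity that the competition
    term supplies in the reduced model.
    """

    b: PeriodicFunction
    d_E: PeriodicFunction
    d_L: PeriodicFunction
    d_P: PeriodicFunction
    d_A: PeriodicFunction
    h: PeriodicFunction
    tau_L: PeriodicFunction
    tau_P: PeriodicFunction
    c: PeriodicFunction
    sigma: float = 0.5
    K_carry: float = 1000.0
    oviposition_form: str = "BS"   # "BS" (saturating) or "BL" (logistic)
    n: float = 1.0
    grid_n: int = DEFAULT_GRID_N

    def __post_init__(self) -> None:
        T = self.b.period_T
        all_named = [("b", self.b), ("d_E", self.d_E), ("d_L", self.d_L),
                     ("d_P", self.d_P), ("d_A", self.d_A), ("h", self.h),
                     ("tau_L", self.tau_L), ("tau_P", self.tau_P), ("c", self.c)]
        for name, f in all_named:
            if abs(f.period_T - T) > 1e-9:
                raise CoefficientError(f"{name} period {f.period_T} != {T}")
        bm, _ = extremes(self.b, self.grid_n)
        if bm <= 0:
            raise CoefficientError("b must be strictly positive on the grid")
        for name, f in all_named[1:-1]:
            if average(f, self.grid_n) <= 1e-14:
                raise CoefficientError(f"{name} must have positive average")
        if not (0 < self.sigma <= 1):
            raise CoefficientError("sigma must lie in (0, 1]")
        if not (self.K_carry > 0):
            raise CoefficientError("K_carry must be positive")
        if self.oviposition_form not in ("BS", "BL"):
            raise CoefficientError("oviposition_form must be 'BS' or 'BL'")
        if not (self.n > 0):
            raise CoefficientError("n must be positive")
        if self.mortality_floor_average() <= 0:
            raise CoefficientError(
                "min of the four death rates must have positive average"
            )

    @property
    def period_T(self) -> float:
        return self.b.period_T

    def mortality_floor(self) -> PeriodicFunction:
        """Pointwise minimum of the four death rates (dissipativity floor)."""
        d_E, d_L, d_P, d_A = self.d_E, self.d_L, self.d_P, self.d_A

        def ev(t):
            t = np.asarray(t, float)
            return np.minimum(np.minimum(d_E(t), d_L(t)),
                              np.minimum(d_P(t), d_A(t)))

        bps = _merged_breakpoints((d_E, d_L, d_P, d_A))
        return PeriodicFunction(self.period_T, ev, "M(t)", breakpoints=bps)

    def mortality_floor_average(self) -> float:
        return average(self.mortality_floor(), self.grid_n)

    def breakpoints(self) -> tuple[float, ...]:
        return _merged_breakpoints((self.b, self.d_E, self.d_L, self.d_P,
                                    self.d_A, self.h, self.tau_L, self.tau_P,
                                    self.c))
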