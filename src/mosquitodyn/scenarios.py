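"""Preset and synthetic coefficient scenarios.

Three families of inputs are produced here:

* the published parameter presets: min-max ranges of the life-history rates
  in a tropical and a temperate climate scenario, and the exact
  piecewise-linear extinction construction (plateau values, switch times,
  period);
* the extinction construction itself, including the ray-return contraction
  factor lambda — the factor by which a solution of the linear comparison
  system shrinks along the ray through its initial point after one period;
* seeded random generators for climate-like seasonal coefficient sets that
  satisfy the persistence hypotheses by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .conditions import check_eq8
from .dynamics import rhs_linear, simulate_two_stage
from .floquet import monodromy, fv_jacobian
from .periodic import (PeriodicFunction, TwoStageCoefficients, constant,
                       from_expression, make_trapezoid_profile)

__all__ = [
    "ExtinctionConstruction",
    "EXTINCTION_BARS",
    "EXTINCTION_TIMES",
    "EXTINCTION_PERIOD",
    "CLIMATE_RANGES",
    "table_fixtures",
    "build_extinction_coeffs",
    "make_extinction_construction",
    "solve_return_factor",
    "gen_persistent_scenario",
    "gen_climate_like",
]

#: Plateau values (b_E, d_E, d_L, h) of the extinction construction.
EXTINCTION_BARS = (0.1, 0.05, 0.02, 0.3)
#: Switch times t1..t5 (days) of the extinction construction.
EXTINCTION_TIMES = (2.0, 15.0, 180.0, 199.0, 199.6)
#: Period (days) of the extinction construction.
EXTINCTION_PERIOD = 200.0

#: Published min-max ranges of the rates in the two climate scenarios.
CLIMATE_RANGES = {
    "tropical": {
        "b_E": (152.33, 204.75),
        "d_E": (0.05, 0.05),
        "d_L": (0.022, 0.029),
        "h": (0.41, 0.49),
        "c": (0.0041, 0.29),
    },
    "temperate": {
        "b_E": (5.96, 204.75),
        "d_E": (0.05, 0.05),
        "d_L": (0.017, 0.036),
        "h": (0.14, 0.51),
        "c": (0.0012, 0.014),
    },
}


def table_fixtures() -> dict:
    """Named presets: extinction-construction inputs and climate ranges."""
    return {
        "extinction": {
            "bars": EXTINCTION_BARS,
            "times": EXTINCTION_TIMES,
            "T": EXTINCTION_PERIOD,
        },
        "tropical": {k: tuple(v) for k, v in CLIMATE_RANGES["tropical"].items()},
        "temperate": {k: tuple(v) for k, v in CLIMATE_RANGES["temperate"].items()},
    }


def build_extinction_coeffs(bars: Sequence[float] = EXTINCTION_BARS,
                            times: Sequence[float] = EXTINCTION_TIMES,
                            T: float = EXTINCTION_PERIOD) -> TwoStageCoefficients:
    """Piecewise-linear coefficients of the seasonal extinction example.

    b_E, d_E and h sit at their plateau on [0, t1] and [t5, T], vanish on
    [t2, t4] and ramp linearly between; d_L stays at its plateau until t2,
    vanishes only on [t3, t4], and ramps on [t2, t3] and [t4, t5].  During
    (t2, t3) larval death is thus the only active rate — the mechanism (e.g.
    a diapause window with lingering larval mortality) that produces
    extinction.  Returns the linear-variant bundle (no competition term).
    """
    b_bar, dE_bar, dL_bar, h_bar = bars
    t1, t2, t3, t4, t5 = times
    rep = check_eq8(b_bar, dE_bar, dL_bar, h_bar)
    if not rep.holds:
        raise ValueError(
            "plateau values must satisfy d_L/h < b_E/(d_E+h); "
            f"margin {rep.margin:g}"
        )
    if not (0 < t1 < t2 < t3 < t4 < t5 < T):
        raise ValueError("times must satisfy 0 < t1 < ... < t5 < T")
    b_E = make_trapezoid_profile(b_bar, t1, t2, t4, t5, T, "b_E")
    d_E = make_trapezoid_profile(dE_bar, t1, t2, t4, t5, T, "d_E")
    h = make_trapezoid_profile(h_bar, t1, t2, t4, t5, T, "h")
    d_L = make_trapezoid_profile(dL_bar, t2, t3, t4, t5, T, "d_L")
    return TwoStageCoefficients(b_E, d_E, d_L, h, c=None)


@dataclass(frozen=True)
class ExtinctionConstruction:
    """The seasonal extinction example, bundled with its contraction factor.

    ``P0`` must lie in the cone Gamma_1 = {E > (b_E/(d_E+h)) L} (plateau
    values), from which eggs strictly decrease while the favourable-season
    rates are on.  ``lam`` is filled in by :func:`solve_return_factor`.
    """

    bars: tuple[float, float, float, float] = EXTINCTION_BARS
    times: tuple[float, float, float, float, float] = EXTINCTION_TIMES
    T: float = EXTINCTION_PERIOD
    P0: tuple[float, float] = (1.0, 1.0)
    lam: float | None = None

    def __post_init__(self) -> None:
        b_bar, dE_bar, _, h_bar = self.bars
        E0, L0 = self.P0
        if not (E0 > 0 and L0 > 0):
            raise ValueError("P0 must be in the open first quadrant")
        if not E0 > (b_bar / (dE_bar + h_bar)) * L0:
            raise ValueError("P0 must lie in Gamma_1: E0 > (b_E/(d_E+h)) L0")
        if self.lam is not None and not (0 < self.lam < 1):
            raise ValueError("lam must lie in (0, 1)")

    def coefficients(self) -> TwoStageCoefficients:
        return build_extinction_coeffs(self.bars, self.times, self.T)


def make_extinction_construction(bars=EXTINCTION_BARS, times=EXTINCTION_TIMES,
                                 T=EXTINCTION_PERIOD,
                                 P0=(1.0, 1.0)) -> ExtinctionConstruction:
    build_extinction_coeffs(bars, times, T)  # validates eq8 + time ordering
    return ExtinctionConstruction(tuple(bars), tuple(times), float(T),
                                  tuple(P0))


def solve_return_factor(construction: ExtinctionConstruction,
                        mode: str = "measured") -> tuple[float, ExtinctionConstruction, dict]:
    """Contraction factor of the linear comparison system along the P0 ray.

    ``mode='measured'``: integrates the linear system from P0 over one period
    and reports the per-component ratios lambda_E = E(T)/E0,
    lambda_L = L(T)/L0 together with the spectral radius of the monodromy
    (lambda is taken as the spectral radius — the asymptotic per-period
    contraction).

    ``mode='exact'``: keeps the coefficients frozen at their plateau beyond
    t5 and root-finds the first return time T' > t5 at which the trajectory
    crosses the ray {s * P0 : s > 0}; the construction is returned with its
    period reset to T' so that the period map contracts exactly along the
    ray: state(T') = lambda * P0.
    """
    coeffs = construction.coefficients()
    E0, L0 = construction.P0
    x0 = np.array([E0, L0])
    T = construction.T
    detail: dict = {}

    if mode == "measured":
        traj = simulate_two_stage(coeffs, x0, (0.0, T), model="linear",
                                  t_eval=[0.0, T])
        ET, LT = traj.final
        mono = monodromy(fv_jacobian(coeffs), T,
                         breakpoints=coeffs.breakpoints(), period_T=T)
        lam = mono.spectral_radius
        detail = {"lambda_E": ET / E0, "lambda_L": LT / L0,
                  "spectral_radius": lam, "state_T": traj.final}
        return lam, replace(construction, lam=lam), detail

    if mode != "exact":
        raise ValueError("mode must be 'measured' or 'exact'")

    t5 = construction.times[4]
    traj5 = simulate_two_stage(coeffs, x0, (0.0, t5), model="linear",
                               t_eval=[0.0, t5])
    x5 = traj5.final
    b_bar, dE_bar, dL_bar, h_bar = construction.bars
    A = np.array([[-(dE_bar + h_bar), b_bar], [h_bar, -dL_bar]])

    from scipy.linalg import expm

    def ray_gap(dt: float) -> float:
        x = expm(A * dt) @ x5
        # positive while above the ray in the E direction: E L0 - L E0 > 0
        return x[0] * L0 - x[1] * E0

    g0 = ray_gap(0.0)
    if g0 <= 0:
        raise RuntimeError("state at t5 is not strictly inside Gamma_2")
    span = 10.0 * (t5 - construction.times[3] + 1.0)
    hi = span
    while ray_gap(hi) > 0:
        hi *= 2.0
        if hi > 100.0 * span:
            raise RuntimeError("no ray crossing found after t5; "
                               "extend the search window")
    dt_star = brentq(ray_gap, 0.0, hi, xtol=1e-12, rtol=1e-14)
    x_star = expm(A * dt_star) @ x5
    lam_E, lam_L = x_star[0] / E0, x_star[1] / L0
    lam = float(0.5 * (lam_E + lam_L))
    if not (0 < lam < 1):
        raise RuntimeError(f"ray-return factor {lam:g} not in (0, 1)")
    T_new = t5 + dt_star
    detail = {"T_new": T_new, "lambda_E": lam_E, "lambda_L": lam_L,
              "state_T": x_star}
    return lam, replace(construction, T=T_new, lam=lam), detail


# -- seeded generators -----------------------------------------------------


def _smooth_profile(rng: np.random.Generator, T: float, lo: float, hi: float,
                    n_harmonics: int = 3, label: str = "") -> PeriodicFunction:
    """Random truncated Fourier series rescaled to take values in [lo, hi]."""
    a = rng.normal(size=n_harmonics)
    b = rng.normal(size=n_harmonics)
    k = np.arange(1, n_harmonics + 1)

    def raw(t):
        t = np.asarray(t, float)
        ang = 2.0 * np.pi * np.outer(t, k) / T
        return np.cos(ang) @ a + np.sin(ang) @ b

    tg = np.linspace(0.0, T, 4096)
    v = raw(tg)
    vmin, vmax = v.min(), v.max()
    scale = (hi - lo) / (vmax - vmin) if vmax > vmin else 0.0
    off = lo - scale * vmin

    def ev(t):
        t = np.asarray(t, float)
        out = off + scale * raw(np.atleast_1d(t))
        return out.reshape(np.shape(t))

    return from_expression(ev, T, label)


def gen_persistent_scenario(seed: int, T: float = 365.0,
                            amplitude: float = 0.4) -> TwoStageCoefficients:
    """Seeded random coefficient set satisfying the persistence hypotheses.

    All rates are smooth, strictly positive truncated Fourier series (so the
    zero-linkage conditions hold vacuously); egg death is constant; larval
    death is constructed as d_L(t) = r(t) b_E(t) with
    max r < inf h/(d_E + h), which enforces the gap condition — and hence
    R0 > 1 — by construction.  ``amplitude`` in [0, 1) scales the seasonal
    swing of each rate around its midpoint; amplitude 0 gives constants.
    """
    if not (0 <= amplitude < 1):
        raise ValueError("amplitude must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    dE_val = 0.05
    d_E = constant(dE_val, T, "d_E")

    def band(mid_lo, mid_hi):
        mid = rng.uniform(mid_lo, mid_hi)
        half = amplitude * mid
        return mid - half, mid + half

    h = _smooth_profile(rng, T, *band(0.25, 0.5), label="h")
    b_E = _smooth_profile(rng, T, *band(0.3, 1.2), label="b_E")
    c = _smooth_profile(rng, T, *band(0.05, 0.2), label="c")

    tg = np.linspace(0.0, T, 4096)
    hv = h(tg)
    inf_ratio = float(np.min(hv / (dE_val + hv)))
    frac = rng.uniform(0.3, 0.5)  # sup d_L/b_E = frac * inf h/(d_E+h)
    r = _smooth_profile(rng, T, (1.0 - 0.5 * amplitude) * frac * inf_ratio,
                        frac * inf_ratio, label="r")

    def dl_ev(t, r=r, b_E=b_E):
        return r(t) * b_E(t)

    d_L = from_expression(dl_ev, T, "d_L")
    return TwoStageCoefficients(b_E, d_E, d_L, h, c)


#: Day of peak for each rate in the climate-like presets (phase of the
#: raised cosine).  Tropical: oviposition/hatching peak in the wet season
#: while larval competition peaks in the dry season (opposite phase);
#: temperate: population rates peak in late summer, competition in winter.
_CLIMATE_PHASES = {
    "tropical": {"b_E": 355.0, "h": 355.0, "d_L": 250.0, "c": 172.0},
    "temperate": {"b_E": 250.0, "h": 235.0, "d_L": 220.0, "c": 40.0},
}


def gen_climate_like(preset: str, seed: int = 0, T: float = 365.0) -> TwoStageCoefficients:
    """Smooth seasonal coefficients confined to a climate preset's ranges.

    Each rate is a raised cosine with one peak per year,
    f(t) = lo + (hi - lo) (1 + cos(2 pi (t - peak)/T)) / 2, spanning exactly
    the preset's printed min-max interval; egg death is constant.  ``seed``
    jitters the peak days by up to +/-10 days, leaving the ranges untouched.
    """
    if preset not in CLIMATE_RANGES:
        raise ValueError(f"unknown preset {preset!r}")
    ranges = CLIMATE_RANGES[preset]
    phases = _CLIMATE_PHASES[preset]
    rng = np.random.default_rng(seed)

    def raised_cosine(name: str) -> PeriodicFunction:
        lo, hi = ranges[name]
        peak = phases[name] + rng.uniform(-10.0, 10.0)

        def ev(t, lo=lo, hi=hi, peak=peak):
            t = np.asarray(t, float)
            return lo + (hi - lo) * 0.5 * (1.0 + np.cos(2.0 * np.pi * (t - peak) / T))

        return from_expression(ev, T, name)

    b_E = raised_cosine("b_E")
    h = raised_cosine("h")
    d_L = raised_cosine("d_L")
    c = raised_cosine("c")
    d_E = constant(ranges["d_E"][0], T, "d_E")
    return TwoStageCoefficients(b_E, d_E, d_L, h, c)
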