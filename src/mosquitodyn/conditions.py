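"""Checkers for the structural hypotheses and explicit bounds of the models.

The persistent regime of the egg-larvae system is guaranteed by three
pointwise conditions on the coefficients:

* (zero-linkage, oviposition) whenever b_E vanishes, d_E and d_L vanish too;
* (zero-linkage, hatching) whenever h vanishes, b_E vanishes too;
* (gap condition) sup_{t in TT} d_L/b_E < inf_{t in TT} h/(d_E + h), where
  TT = {t : b_E(t) != 0 and h(t) != 0}.

Together they force the origin to be a saddle whose unstable direction points
into the positive quadrant, hence R0 > 1.  The extinction side has two easy
sufficient certificates: the constant-plateau inequality
d_L/h < b_E/(d_E + h) failing in the right way for the piecewise seasonal
construction, and the crude budget b_E^M + d_E^M - d_L^m < 0 under which the
total population decays outright.

Also here: the explicit dissipativity bounds — the eventual bound K on E + L
obtained by comparison with the scalar equation y' = -d_E(t) y + U_M, and its
four-stage analogue using the mortality floor M(t) = min of the four death
rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dynamics import simulate_four_stage
from .periodic import (DEFAULT_GRID_N, FourStageCoefficients, PeriodicFunction,
                       TwoStageCoefficients, average, extremes, zero_tolerance)

__all__ = [
    "ConditionReport",
    "DissipativityBounds",
    "check_h45",
    "check_h6",
    "check_eq8",
    "check_remark27",
    "dissipativity_bounds2",
    "dissipativity_bounds4",
    "positivity_3T_check",
    "check_m_average",
]


@dataclass
class ConditionReport:
    """Outcome of a single hypothesis check on a grid.

    ``margin`` is the signed slack in the condition's own units (positive
    when the condition holds strictly); ``witnesses`` lists grid times where
    it fails.
    """

    condition_id: str
    holds: bool
    margin: float
    witnesses: np.ndarray = field(default_factory=lambda: np.array([]))
    grid_n: int = DEFAULT_GRID_N
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.holds and len(self.witnesses):
            raise ValueError("a holding condition cannot have witnesses")


@dataclass
class DissipativityBounds:
    """Explicit eventual bound on the total population.

    ``U_M`` is the peak net inflow rate (individuals/day), ``K_bound`` the
    eventual bound (individuals, max of the attracting periodic solution of
    the scalar comparison equation plus ``epsilon``).
    """

    U_M: float
    K_bound: float
    epsilon: float
    horizon_hint: int = 50


def _grid(coeffs, grid_n: int) -> np.ndarray:
    t = np.linspace(0.0, coeffs.period_T, grid_n)
    bps = coeffs.breakpoints()
    if bps:
        t = np.union1d(t, np.asarray(bps, float))
    return t


def check_h45(coeffs: TwoStageCoefficients,
              grid_n: int = DEFAULT_GRID_N) -> tuple[ConditionReport, ConditionReport]:
    """Zero-linkage conditions tying the zero sets of b_E, h, d_E, d_L.

    First report: wherever b_E(t) = 0, both d_E(t) = 0 and d_L(t) = 0.
    Second report: wherever h(t) = 0, b_E(t) = 0.
    Both hold vacuously for strictly positive coefficients.
    """
    t = _grid(coeffs, grid_n)
    bE, dE, dL, h = (coeffs.b_E(t), coeffs.d_E(t), coeffs.d_L(t), coeffs.h(t))
    tol = {name: zero_tolerance(f, grid_n)
           for name, f in (("b_E", coeffs.b_E), ("d_E", coeffs.d_E),
                           ("d_L", coeffs.d_L), ("h", coeffs.h))}

    z_bE = np.abs(bE) <= tol["b_E"]
    bad4 = z_bE & ((np.abs(dE) > tol["d_E"]) | (np.abs(dL) > tol["d_L"]))
    w4 = t[bad4]
    viol4 = float(np.max(np.maximum(np.abs(dE), np.abs(dL))[z_bE])) if z_bE.any() else 0.0
    rep4 = ConditionReport("zero_linkage_bE", not w4.size,
                           -viol4 if w4.size else viol4, w4, grid_n)

    z_h = np.abs(h) <= tol["h"]
    bad5 = z_h & (np.abs(bE) > tol["b_E"])
    w5 = t[bad5]
    viol5 = float(np.max(np.abs(bE)[z_h])) if z_h.any() else 0.0
    rep5 = ConditionReport("zero_linkage_h", not w5.size,
                           -viol5 if w5.size else viol5, w5, grid_n)
    return rep4, rep5


def check_h6(coeffs: TwoStageCoefficients,
             grid_n: int = DEFAULT_GRID_N) -> ConditionReport:
    """Gap condition sup_{TT} d_L/b_E < inf_{TT} h/(d_E+h) on the grid.

    TT is the set of grid times where both b_E and h are numerically nonzero.
    Margin = inf - sup; a strict inequality is required, so margin 0 fails.
    """
    t = _grid(coeffs, grid_n)
    bE, dE, dL, h = (coeffs.b_E(t), coeffs.d_E(t), coeffs.d_L(t), coeffs.h(t))
    in_T = (np.abs(bE) > zero_tolerance(coeffs.b_E, grid_n)) & \
           (np.abs(h) > zero_tolerance(coeffs.h, grid_n))
    if not in_T.any():
        return ConditionReport("gap_condition", False, -np.inf,
                               np.array([]), grid_n,
                               detail={"undefined": True,
                                       "reason": "TT empty on the grid"})
    sup_ratio = float(np.max(dL[in_T] / bE[in_T]))
    inf_ratio = float(np.min(h[in_T] / (dE[in_T] + h[in_T])))
    margin = inf_ratio - sup_ratio
    holds = margin > 0
    witnesses = np.array([]) if holds else t[in_T][
        np.argmax(dL[in_T] / bE[in_T])][None]
    return ConditionReport("gap_condition", holds, margin, witnesses, grid_n,
                           detail={"sup_dL_over_bE": sup_ratio,
                                   "inf_h_over_dEh": inf_ratio})


def check_eq8(b_E: float, d_E: float, d_L: float, h: float) -> ConditionReport:
    """Constant-plateau gap condition d_L/h < b_E/(d_E + h).

    For constant coefficients this is equivalent to the grid gap condition:
    both reduce to d_L (d_E + h) < b_E h.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    lhs = d_L / h
    rhs = b_E / (d_E + h)
    margin = rhs - lhs
    return ConditionReport("plateau_gap", margin > 0, margin,
                           np.array([]) if margin > 0 else np.array([0.0]),
                           grid_n=1, detail={"dL_over_h": lhs,
                                             "bE_over_dEh": rhs})


def check_remark27(coeffs: TwoStageCoefficients,
                   grid_n: int = DEFAULT_GRID_N) -> ConditionReport:
    """Crude extinction budget: b_E^M + d_E^M - d_L^m < 0.

    When it holds, total inflow never exceeds outflow and the origin is
    globally stable (so any persistence classification would be
    contradictory).  It can never hold when d_L vanishes somewhere (d_L^m=0).
    """
    _, bEM = extremes(coeffs.b_E, grid_n)
    _, dEM = extremes(coeffs.d_E, grid_n)
    dLm, _ = extremes(coeffs.d_L, grid_n)
    B = bEM + dEM - dLm
    return ConditionReport("mortality_budget", B < 0, -B,
                           np.array([]) if B < 0 else np.array([0.0]),
                           grid_n, detail={"b_E_max": bEM, "d_E_max": dEM,
                                           "d_L_min": dLm})


def _periodic_scalar_max(decay: PeriodicFunction, inflow: float,
                         n_periods: int = 50,
                         grid_n: int = 512) -> float:
    """Max over one period of the attracting periodic solution of
    y' = -decay(t) y + inflow, by integrating to convergence."""
    from .dynamics import simulate

    T = decay.period_T

    def rhs(t, y):
        return np.array([-decay(t) * y[0] + inflow])

    avg = average(decay)
    y0 = np.array([inflow / avg if avg > 0 else 0.0])
    traj = simulate(rhs, y0, (0.0, n_periods * T),
                    breakpoints=decay.breakpoints, period_T=T,
                    t_eval=np.linspace((n_periods - 1) * T, n_periods * T,
                                       grid_n),
                    clip_nonnegative=False)
    return float(np.max(traj.states))


def dissipativity_bounds2(coeffs: TwoStageCoefficients,
                          epsilon: float | None = None) -> DissipativityBounds:
    """Eventual bound K on E + L for the egg-larvae system.

    d/dt (E+L) <= -d_E(t)(E+L) + U_M with
    U_M = max_{L>=0} (b_E^M + d_E^M - d_L^m) L - c^m L^2 = B^2/(4 c^m) when
    B > 0 (parabola vertex), else 0.  K is the max of the attracting periodic
    solution of y' = -d_E(t) y + U_M, inflated by epsilon.
    """
    if coeffs.is_linear:
        raise ValueError("bound needs the competition coefficient c")
    cm, _ = extremes(coeffs.c)
    if cm <= 0:
        raise ValueError("c^m must be positive for the bound to exist")
    _, bEM = extremes(coeffs.b_E)
    _, dEM = extremes(coeffs.d_E)
    dLm, _ = extremes(coeffs.d_L)
    B = bEM + dEM - dLm
    U_M = B * B / (4.0 * cm) if B > 0 else 0.0
    ymax = _periodic_scalar_max(coeffs.d_E, U_M)
    eps = epsilon if epsilon is not None else 1e-6 * max(1.0, ymax)
    return DissipativityBounds(U_M, ymax + eps, eps)


def dissipativity_bounds4(coeffs4: FourStageCoefficients,
                          epsilon: float | None = None) -> DissipativityBounds:
    """Eventual bound on E + L + P + A for the four-stage system.

    The total obeys d/dt (sum) <= K b^M - M(t) (sum), with M(t) the pointwise
    minimum of the four death rates; the bound is the max of the attracting
    periodic solution of the scalar comparison equation, plus epsilon.
    """
    _, bM = extremes(coeffs4.b)
    inflow = coeffs4.K_carry * bM
    ymax = _periodic_scalar_max(coeffs4.mortality_floor(), inflow)
    eps = epsilon if epsilon is not None else 1e-6 * max(1.0, ymax)
    return DissipativityBounds(inflow, ymax + eps, eps)


def check_m_average(coeffs4: FourStageCoefficients,
                    grid_n: int = DEFAULT_GRID_N) -> ConditionReport:
    """Positive average of the mortality floor M(t) over one period."""
    avg = average(coeffs4.mortality_floor(), grid_n)
    return ConditionReport("mortality_floor_average", avg > 0, avg,
                           np.array([]) if avg > 0 else np.array([0.0]),
                           grid_n, detail={"average": avg})


def positivity_3T_check(coeffs4: FourStageCoefficients,
                        boundary_states: Sequence,
                        check_2T: bool = False) -> ConditionReport:
    """All four stages strictly positive at t = 3T from boundary starts.

    A single positive stage propagates around the life cycle in at most
    three periods (eggs need the full three: hatch, pupate, emerge).  When
    ``check_2T`` is set, states whose nonzero component is not the egg stage
    are also required to be positive already at 2T.
    """
    T = coeffs4.period_T
    witnesses = []
    detail = {}
    for i, s in enumerate(boundary_states):
        s = np.asarray(s, float)
        if np.any(s < 0) or not np.any(s):
            raise ValueError("boundary states must be nonzero and nonnegative")
        traj = simulate_four_stage(coeffs4, s, (0.0, 3 * T),
                                   t_eval=[0.0, 2 * T, 3 * T])
        x2T, x3T = traj.states[-2], traj.states[-1]
        ok = bool(np.all(x3T > 0))
        if check_2T and s[0] == 0:
            ok &= bool(np.all(x2T > 0))
        detail[f"state_{i}"] = {"x0": s, "x_2T": x2T, "x_3T": x3T, "ok": ok}
        if not ok:
            witnesses.append(float(3 * T))
    w = np.asarray(witnesses)
    return ConditionReport("positivity_3T", not w.size,
                           1.0 if not w.size else -1.0, w, detail=detail)
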