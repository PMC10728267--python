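"""Hypothesis checkers and explicit dissipativity bounds."""

import numpy as np
import pytest

from mosquitodyn.conditions import (check_eq8, check_h45, check_h6,
                                    check_m_average, check_remark27,
                                    dissipativity_bounds2,
                                    dissipativity_bounds4, positivity_3T_check)
from mosquitodyn.dynamics import simulate_two_stage, simulate_four_stage
from mosquitodyn.periodic import (FourStageCoefficients, TwoStageCoefficients,
                                  constant, make_trapezoid_profile)
from mosquitodyn.scenarios import (build_extinction_coeffs,
                                   gen_persistent_scenario)


def const_bundle(b_E, d_E, d_L, h, c=0.01, T=50.0):
    return TwoStageCoefficients(constant(b_E, T), constant(d_E, T),
                                constant(d_L, T), constant(h, T),
                                constant(c, T))


class TestZeroLinkage:
    def test_all_positive_coefficients_hold_vacuously(self):
        r4, r5 = check_h45(const_bundle(0.1, 0.05, 0.02, 0.3))
        assert r4.holds and r5.holds

    def test_extinction_construction_breaks_first_linkage(self):
        # larval death stays positive on part of the window where the
        # oviposition rate is zero
        r4, r5 = check_h45(build_extinction_coeffs())
        assert not r4.holds
        assert len(r4.witnesses) > 0
        assert r5.holds  # h and b_E share their zero window exactly

    def test_shared_zero_window_satisfies_linkage(self):
        T = 200.0
        shared = dict(t1=2.0, t2=15.0, t4=199.0, t5=199.6)
        mk = lambda v: make_trapezoid_profile(v, T=T, **shared)
        cs = TwoStageCoefficients(mk(0.1), mk(0.05), mk(0.02), mk(0.3),
                                  constant(0.01, T))
        r4, r5 = check_h45(cs)
        assert r4.holds and r5.holds


class TestGapCondition:
    def test_constants_hand_arithmetic(self):
        rep = check_h6(const_bundle(0.1, 0.05, 0.02, 0.3))
        assert rep.holds
        assert rep.detail["sup_dL_over_bE"] == pytest.approx(0.2, rel=1e-9)
        assert rep.detail["inf_h_over_dEh"] == pytest.approx(0.3 / 0.35,
                                                             rel=1e-9)

    def test_boundary_margin_zero_fails_strictly(self):
        # exactly representable boundary: sup d_L/b_E = inf h/(d_E+h) = 1/2
        rep = check_h6(const_bundle(1.0, 0.5, 0.5, 0.5))
        assert not rep.holds
        assert rep.margin == 0.0

    def test_agrees_with_plateau_form_on_random_constants(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            b_E, d_E, d_L, h = rng.uniform(0.01, 1.0, 4)
            grid_rep = check_h6(const_bundle(b_E, d_E, d_L, h))
            const_rep = check_eq8(b_E, d_E, d_L, h)
            # both reduce to d_L (d_E + h) < b_E h
            assert grid_rep.holds == const_rep.holds == \
                (d_L * (d_E + h) < b_E * h)

    def test_empty_active_set_is_undefined(self):
        # b_E and h numerically zero everywhere -> the active set is empty
        # (a stub stands in because the bundle constructor rightly rejects
        # identically-zero rates)
        from types import SimpleNamespace

        T = 200.0
        zeroish = make_trapezoid_profile(1e-30, 2.0, 15.0, 199.0, 199.6, T)
        cs = SimpleNamespace(b_E=zeroish, d_E=constant(0.05, T),
                             d_L=constant(0.02, T), h=zeroish,
                             period_T=T, breakpoints=lambda: ())
        rep = check_h6(cs)
        assert not rep.holds and rep.detail.get("undefined")


class TestPlateauGap:
    def test_extinction_plateau_values_satisfy_inequality(self):
        rep = check_eq8(0.1, 0.05, 0.02, 0.3)
        assert rep.holds
        assert rep.detail["dL_over_h"] == pytest.approx(0.0667, abs=5e-5)
        assert rep.detail["bE_over_dEh"] == pytest.approx(0.2857, abs=5e-5)

    def test_boundary_fails(self):
        d_L = 0.3 * 0.1 / 0.35
        rep = check_eq8(0.1, 0.05, d_L, 0.3)
        assert not rep.holds
        assert rep.margin == pytest.approx(0.0, abs=1e-12)

    def test_margin_monotone_in_oviposition(self):
        m1 = check_eq8(0.1, 0.05, 0.02, 0.3).margin
        m2 = check_eq8(0.2, 0.05, 0.02, 0.3).margin
        assert m2 > m1

    def test_nonpositive_hatching_rejected(self):
        with pytest.raises(ValueError):
            check_eq8(0.1, 0.05, 0.02, 0.0)


class TestMortalityBudget:
    def test_holds_when_larval_death_dominates(self):
        rep = check_remark27(const_bundle(0.1, 0.05, 0.2, 0.3))
        assert rep.holds and rep.margin == pytest.approx(0.05, rel=1e-9)

    def test_vanishing_larval_death_cannot_hold(self):
        rep = check_remark27(build_extinction_coeffs())
        assert not rep.holds
        assert rep.detail["d_L_min"] == 0.0

    def test_cross_check_with_sign_test(self):
        from mosquitodyn.floquet import r0_sign_test

        cs = const_bundle(0.1, 0.05, 0.2, 0.3)
        assert check_remark27(cs).holds
        assert r0_sign_test(cs).classification == "below_one"


class TestDissipativityTwoStage:
    def test_parabola_vertex(self):
        # B = b_E^M + d_E^M - d_L^m = 2, c^m = 1 -> U_M = 1
        cs = const_bundle(1.5, 0.6, 0.1, 0.3, c=1.0)
        b = dissipativity_bounds2(cs)
        assert b.U_M == pytest.approx((1.5 + 0.6 - 0.1) ** 2 / 4.0, rel=1e-9)

    def test_nonpositive_net_inflow_gives_zero(self):
        cs = const_bundle(0.05, 0.02, 0.5, 0.3)
        assert dissipativity_bounds2(cs).U_M == 0.0

    def test_constant_decay_closed_form(self):
        # y' = -delta y + U_M has periodic solution U_M / delta
        cs = const_bundle(0.1, 0.05, 0.02, 0.3, c=0.01)
        b = dissipativity_bounds2(cs, epsilon=1e-6)
        B = 0.1 + 0.05 - 0.02
        U = B * B / (4 * 0.01)
        assert b.K_bound == pytest.approx(U / 0.05 + 1e-6, rel=1e-6)

    def test_simulated_total_respects_bound(self):
        for seed in (0, 1):
            cs = gen_persistent_scenario(seed, T=30.0, amplitude=0.3)
            b = dissipativity_bounds2(cs)
            T = cs.period_T
            traj = simulate_two_stage(cs, [1.0, 1.0], (0.0, 30 * T),
                                      t_eval=np.linspace(20 * T, 30 * T, 300))
            assert np.all(traj.states.sum(axis=1) <= b.K_bound)

    def test_linear_bundle_rejected(self):
        with pytest.raises(ValueError):
            dissipativity_bounds2(build_extinction_coeffs())


class TestFourStageBounds:
    def test_constant_floor_closed_form(self, four_stage_const):
        b = dissipativity_bounds4(four_stage_const, epsilon=1e-6)
        # floor = min(0.05, 0.05, 0.05, 0.1) = 0.05; inflow = K b^M
        assert b.K_bound == pytest.approx(100.0 * 5.0 / 0.05 + 1e-6,
                                          rel=1e-6)

    def test_simulated_total_respects_bound(self, four_stage_seasonal):
        b = dissipativity_bounds4(four_stage_seasonal)
        T = four_stage_seasonal.period_T
        traj = simulate_four_stage(four_stage_seasonal, [1.0, 1.0, 1.0, 1.0],
                                   (0.0, 20 * T),
                                   t_eval=np.linspace(10 * T, 20 * T, 200))
        assert np.all(traj.states.sum(axis=1) <= b.K_bound)

    def test_mortality_floor_average(self, four_stage_const):
        rep = check_m_average(four_stage_const)
        assert rep.holds and rep.margin == pytest.approx(0.05, rel=1e-9)

    def test_zero_adult_death_fails_floor(self):
        T = 40.0
        with pytest.raises(Exception):
            FourStageCoefficients(
                b=constant(5.0, T), d_E=constant(0.05, T),
                d_L=constant(0.05, T), d_P=constant(0.05, T),
                d_A=constant(0.0, T), h=constant(0.3, T),
                tau_L=constant(0.1, T), tau_P=constant(0.2, T),
                c=constant(0.001, T), sigma=0.5, K_carry=100.0)


class TestPositivityAfterThreePeriods:
    def test_single_stage_starts_become_fully_positive(self, four_stage_seasonal):
        states = [np.eye(4)[i] for i in range(4)]
        rep = positivity_3T_check(four_stage_seasonal, states, check_2T=True)
        assert rep.holds

    def test_origin_start_rejected(self, four_stage_seasonal):
        with pytest.raises(ValueError):
            positivity_3T_check(four_stage_seasonal, [np.zeros(4)])


class TestSoundnessChain:
    def test_hypotheses_imply_persistence_and_attracting_orbit(self):
        # the full qualitative chain on a handful of seeded synthetic sets
        from mosquitodyn.floquet import r0_sign_test
        from mosquitodyn.orbits import find_periodic_orbit

        for seed in range(3):
            cs = gen_persistent_scenario(seed, T=30.0, amplitude=0.4)
            r4, r5 = check_h45(cs)
            assert r4.holds and r5.holds and check_h6(cs).holds
            assert r0_sign_test(cs).classification == "above_one"
            res = find_periodic_orbit(cs, transient_periods=15)
            assert res.converged and res.stability == "attracting"
            assert np.all(res.fixed_point > 0)
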