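"""Poincaré maps, periodic-orbit shooting, monotonicity and subhomogeneity."""

import numpy as np
import pytest

from mosquitodyn.orbits import (attraction_experiment, check_strong_monotonicity,
                                check_subhomogeneity, find_periodic_orbit,
                                four_stage_orbit, poincare_jacobian,
                                poincare_map)
from mosquitodyn.scenarios import (gen_persistent_scenario,
                                   make_extinction_construction,
                                   solve_return_factor)

from conftest import four_stage_equilibrium_oracle


@pytest.fixture(scope="module")
def persistent():
    return gen_persistent_scenario(11, T=30.0, amplitude=0.3)


class TestPoincareMap:
    def test_origin_is_fixed(self, const_coeffs):
        assert np.allclose(poincare_map(const_coeffs, [0.0, 0.0]), 0.0)

    def test_equilibrium_is_fixed_for_constant_coefficients(
            self, const_coeffs, const_equilibrium):
        img = poincare_map(const_coeffs, const_equilibrium)
        assert np.allclose(img, const_equilibrium, atol=1e-6)

    def test_nonlinear_map_dominated_by_linear_flow(self):
        # the competition term only removes larvae, so the nonlinear period
        # map sits componentwise below the linear one from the same start
        con = make_extinction_construction()
        coeffs_lin = con.coefficients()
        x0 = np.array(con.P0)
        lin = poincare_map(coeffs_lin, x0, model="linear")
        from mosquitodyn.periodic import TwoStageCoefficients, constant

        with_c = TwoStageCoefficients(coeffs_lin.b_E, coeffs_lin.d_E,
                                      coeffs_lin.d_L, coeffs_lin.h,
                                      constant(0.01, con.T))
        nonlin = poincare_map(with_c, x0, model="two_stage")
        assert np.all(nonlin <= lin + 1e-10)


class TestPoincareJacobian:
    def test_origin_jacobian_matches_linearization_monodromy(self, const_coeffs):
        from mosquitodyn.floquet import fv_jacobian, monodromy

        D = poincare_jacobian(const_coeffs, [0.0, 0.0])
        M = monodromy(fv_jacobian(const_coeffs), const_coeffs.period_T,
                      period_T=const_coeffs.period_T)
        assert np.allclose(D, M.matrix, rtol=1e-7, atol=1e-9)

    def test_finite_difference_oracle_at_interior_point(self, persistent):
        x0 = np.array([0.8, 0.6])
        D = poincare_jacobian(persistent, x0)
        eps = 1e-6
        for j in range(2):
            e = np.zeros(2)
            e[j] = eps
            col = (poincare_map(persistent, x0 + e) -
                   poincare_map(persistent, x0 - e)) / (2 * eps)
            assert np.allclose(D[:, j], col, rtol=1e-4, atol=1e-5)

    def test_all_entries_positive_at_nonzero_states(self, persistent):
        for x0 in ([1.0, 0.0], [0.0, 1.0], [0.5, 2.0]):
            D = poincare_jacobian(persistent, x0)
            assert np.all(D > 0)


class TestFindPeriodicOrbit:
    def test_constant_coefficients_recover_equilibrium(
            self, const_coeffs, const_equilibrium):
        res = find_periodic_orbit(const_coeffs, transient_periods=10)
        assert res.converged
        assert np.allclose(res.fixed_point, const_equilibrium, atol=1e-6)
        assert res.stability == "attracting"
        assert np.all(np.abs(res.multipliers) < 1)

    def test_unique_orbit_from_multiple_guesses(self, persistent):
        ref = find_periodic_orbit(persistent, transient_periods=15)
        assert ref.converged and ref.stability == "attracting"
        rng = np.random.default_rng(0)
        for _ in range(4):
            guess = ref.fixed_point * rng.uniform(0.3, 3.0, 2)
            res = find_periodic_orbit(persistent, guess=guess)
            assert np.allclose(res.fixed_point, ref.fixed_point, atol=1e-6)

    def test_subcritical_orbit_search_collapses_to_origin(self):
        con = make_extinction_construction()
        res = find_periodic_orbit(con.coefficients(), guess=[1.0, 1.0],
                                  model="linear", transient_periods=10)
        assert np.allclose(res.fixed_point, 0.0, atol=1e-6)


class TestFourStageOrbit:
    def test_constant_coefficients_match_scalar_root_oracle(
            self, four_stage_const):
        expected = four_stage_equilibrium_oracle(four_stage_const)
        res = four_stage_orbit(four_stage_const, tol=1e-6,
                               transient_periods=20)
        assert res.converged
        assert np.allclose(res.fixed_point, expected, rtol=1e-6)
        assert np.all(res.fixed_point > 0)

    def test_seasonal_orbit_is_T_periodic(self, four_stage_seasonal):
        res = four_stage_orbit(four_stage_seasonal, tol=1e-6,
                               transient_periods=20)
        x = res.fixed_point
        xT = poincare_map(four_stage_seasonal, x, 1)
        assert np.max(np.abs(xT - x)) <= 1e-6
        assert res.stability == "attracting"

    def test_heavy_mortality_collapses_to_origin(self):
        from mosquitodyn.periodic import FourStageCoefficients, constant

        T = 40.0
        heavy = FourStageCoefficients(
            b=constant(0.5, T), d_E=constant(1.0, T), d_L=constant(1.0, T),
            d_P=constant(1.0, T), d_A=constant(1.0, T), h=constant(0.3, T),
            tau_L=constant(0.1, T), tau_P=constant(0.2, T),
            c=constant(0.001, T), sigma=0.5, K_carry=100.0)
        res = find_periodic_orbit(heavy, guess=[1, 1, 1, 1],
                                  transient_periods=10)
        assert np.allclose(res.fixed_point, 0.0, atol=1e-8)


class TestAttraction:
    def test_five_starts_converge_to_common_point(self, persistent):
        ref = find_periodic_orbit(persistent, transient_periods=15)
        starts = [ref.fixed_point * f for f in (0.2, 0.5, 2.0, 5.0)]
        starts.append(np.array([1.0, 1.0]))
        rep = attraction_experiment(persistent, starts, n_periods=200,
                                    tol=1e-6)
        assert rep["converged"]
        assert np.allclose(rep["common_point"], ref.fixed_point, atol=1e-4)

    def test_subcritical_starts_decay_geometrically(self):
        con = make_extinction_construction()
        lam, con, _ = solve_return_factor(con, "measured")
        coeffs = con.coefficients()
        x = np.array(con.P0)
        norms = [np.linalg.norm(x)]
        for _ in range(4):
            x = poincare_map(coeffs, x, model="linear")
            norms.append(np.linalg.norm(x))
        ratios = np.diff(np.log(norms))
        assert np.all(np.exp(ratios) < 1.0)

    def test_fixed_point_start_is_stationary(self, const_coeffs,
                                             const_equilibrium):
        rep = attraction_experiment(const_coeffs,
                                    [const_equilibrium, const_equilibrium],
                                    n_periods=3, tol=1e-6)
        assert rep["converged"] and rep["periods"] == 1

    def test_rejects_zero_start(self, const_coeffs):
        with pytest.raises(ValueError):
            attraction_experiment(const_coeffs, [np.zeros(2)])


class TestStructuralProperties:
    def test_strong_monotonicity_on_ordered_pairs(self, persistent):
        rep = check_strong_monotonicity(
            persistent,
            sample_pairs=[((2.0, 1.0), (1.0, 1.0)), ((1.0, 1.0), (1.0, 0.5)),
                          ((0.5, 0.5), (0.0, 0.0))],
            jacobian_points=[(1.0, 1.0), (0.1, 2.0)])
        assert rep["holds"]
        assert rep["jacobians_positive"]

    def test_equal_pair_maps_to_equal_images(self, persistent):
        rep = check_strong_monotonicity(persistent,
                                        sample_pairs=[((1.0, 1.0), (1.0, 1.0))])
        assert rep["holds"]

    def test_two_stage_subhomogeneity_gap(self, const_coeffs):
        # at (1, 1), alpha = 0.5: the L-component gap is c(alpha - alpha^2)
        rep = check_subhomogeneity(const_coeffs, samples=[(1.0, 1.0)],
                                   alphas=[0.5])
        assert rep["holds"]
        from mosquitodyn.dynamics import rhs_two_stage

        gap = (rhs_two_stage(0.0, (0.5, 0.5), const_coeffs) -
               0.5 * rhs_two_stage(0.0, (1.0, 1.0), const_coeffs))
        assert gap[1] == pytest.approx(0.01 * (0.5 - 0.25), rel=1e-12)

    def test_alpha_one_gives_equality(self, const_coeffs):
        rep = check_subhomogeneity(const_coeffs, samples=[(2.0, 3.0)],
                                   alphas=[1.0])
        assert rep["holds"]

    def test_four_stage_subhomogeneity(self, four_stage_seasonal):
        rep = check_subhomogeneity(four_stage_seasonal,
                                   samples=[(1.0, 1.0, 1.0, 5.0)],
                                   alphas=[0.3, 0.7], times=[0.0, 13.0])
        assert rep["holds"]


class TestExtinctionDecayLaw:
    def test_linear_system_period_ends_follow_lambda_powers(self):
        con = make_extinction_construction()
        lam, con, _ = solve_return_factor(con, "exact")
        coeffs = con.coefficients()
        P0 = np.array(con.P0)
        x = P0.copy()
        for k in range(1, 4):
            x = poincare_map(coeffs, x, model="linear")
            assert np.allclose(x, lam ** k * P0, rtol=1e-6)
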