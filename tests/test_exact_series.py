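"""Series solution: coefficients, evaluation routes, and conservation oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import quad, simpson
from scipy.linalg import expm

import growdom as gd
from growdom.errors import InvalidParameterError, OutOfDomainError
from growdom.exact_series import (
    converged_truncation,
    expansion_from_ic,
    evaluate_uncoupled,
)

from conftest import four_generation_problem


# ---------------------------------------------------------------------------
# Fourier coefficients
# ---------------------------------------------------------------------------

class TestBlockCoefficients:
    def test_closed_form_values(self):
        ic = gd.InitialCondition.block(1.0, 0.2)
        psi = gd.block_ic_coefficients(ic, 1.0, 4)
        assert psi[0] == pytest.approx(0.2)
        assert psi[1] == pytest.approx(2.0 / math.pi * math.sin(0.2 * math.pi))
        assert psi[1] == pytest.approx(0.37420, abs=5e-6)

    def test_matches_quadrature_projection(self):
        C0, gamma, L0 = 1.3, 0.45, 1.7
        ic = gd.InitialCondition.block(C0, gamma)
        psi = gd.block_ic_coefficients(ic, L0, 8)
        f = lambda x: C0 if x < gamma else 0.0
        for n in range(9):
            val, _ = quad(lambda x: f(x) * math.cos(n * math.pi * x / L0),
                          0.0, L0, points=[gamma], epsabs=1e-13)
            scale = 1.0 / L0 if n == 0 else 2.0 / L0
            assert psi[n] == pytest.approx(scale * val, abs=1e-10)

    def test_uniform_block_has_mean_mode_only(self):
        ic = gd.InitialCondition.block(2.5, 1.0)
        psi = gd.block_ic_coefficients(ic, 1.0, 6)
        assert psi[0] == pytest.approx(2.5)
        np.testing.assert_allclose(psi[1:], 0.0, atol=1e-14)

    def test_zero_amplitude_gives_zero_coefficients(self):
        psi = gd.block_ic_coefficients(gd.InitialCondition.block(0.0, 0.3), 1.0, 5)
        np.testing.assert_array_equal(psi, 0.0)

    def test_gamma_outside_domain_rejected(self):
        with pytest.raises(InvalidParameterError):
            gd.block_ic_coefficients(gd.InitialCondition.block(1.0, 1.5), 1.0, 5)
        with pytest.raises(InvalidParameterError):
            gd.InitialCondition.block(1.0, -0.2)


class TestGeneralCoefficients:
    def test_block_profile_reproduces_closed_form(self):
        C0, gamma, L0 = 1.0, 0.2, 1.0
        block = gd.InitialCondition.block(C0, gamma)
        general = gd.InitialCondition.general(
            [lambda x: C0 if x < gamma else 0.0, None, None, None])
        psi_block = gd.block_ic_coefficients(block, L0, 12)
        psi_general = gd.general_ic_coefficients(general, L0, 12, 4)
        np.testing.assert_allclose(psi_general[0], psi_block, atol=1e-10)
        np.testing.assert_allclose(psi_general[1:], 0.0)

    def test_cosine_eigenfunction_projects_to_single_mode(self):
        L0 = 1.0
        ic = gd.InitialCondition.general([lambda x: math.cos(math.pi * x / L0)])
        psi = gd.general_ic_coefficients(ic, L0, 5, 1)
        expected = np.zeros(6)
        expected[1] = 1.0
        np.testing.assert_allclose(psi[0], expected, atol=1e-10)

    def test_zero_profile_gives_zero_coefficients(self):
        ic = gd.InitialCondition.general([lambda x: 0.0, None])
        psi = gd.general_ic_coefficients(ic, 1.0, 5, 2)
        np.testing.assert_allclose(psi, 0.0, atol=1e-14)


class TestPropagateCoefficients:
    def test_second_generation_scaling(self):
        model = gd.LineageModel(k=(0.1, 0.2), m=2)
        psi1 = np.array([0.2, 0.37, 0.1])
        expn = gd.propagate_coefficients(psi1, model)
        np.testing.assert_allclose(expn.Psi[1], -2.0 * psi1)

    def test_single_generation_unchanged(self):
        model = gd.LineageModel(k=(0.1,), m=2)
        psi1 = np.array([0.2, 0.37, 0.1])
        np.testing.assert_array_equal(
            gd.propagate_coefficients(psi1, model).Psi[0], psi1)

    def test_fourth_generation_product_by_independent_loop(self):
        k, m = (0.1, 0.2, 0.3, 0.0), 2
        model = gd.LineageModel(k=k, m=m)
        psi1 = np.array([0.2, 0.37])
        expn = gd.propagate_coefficients(psi1, model)
        factor = 1.0
        for l in range(3):
            factor *= m * k[l] / (k[l] - k[3])
        assert factor == pytest.approx(8.0)
        np.testing.assert_allclose(expn.Psi[3], factor * psi1, rtol=1e-13)


# ---------------------------------------------------------------------------
# Uncoupled-field evaluation
# ---------------------------------------------------------------------------

class TestEvaluateUncoupled:
    def test_uniform_ic_single_generation_spatially_flat(self):
        # only the mean mode survives, giving C * exp(-(alpha + k) t)
        C0, alpha, k1 = 1.5, 0.1, 0.25
        p = gd.Problem(growth=gd.make_exponential(1.0, alpha),
                       lineage=gd.LineageModel(k=(k1,), m=2),
                       D=1e-2, ic=gd.InitialCondition.block(C0, 1.0))
        expn = expansion_from_ic(p, 50)
        t = 7.0
        x = np.linspace(0.0, p.growth.length(t), 11)
        a1 = evaluate_uncoupled(p, expn, 1, x, t)
        np.testing.assert_allclose(
            a1, C0 * math.exp(-(alpha + k1) * t), rtol=1e-12)

    def test_initial_profile_recovered_away_from_jump(self, success_problem):
        # partial-sum error decays like 1/(N * distance): at N = 20000 the
        # mismatch outside a 0.02*L0-wide window around the jump is < 1e-3
        p = success_problem
        x = np.linspace(0.0, 1.0, 801)
        mask = np.abs(x - p.ic.gamma) >= 0.01
        target = np.where(x < p.ic.gamma, p.ic.C0, 0.0)
        errs = {}
        for N in (1000, 20000):
            a1 = evaluate_uncoupled(p, expansion_from_ic(p, N), 1, x, 0.0)
            errs[N] = np.max(np.abs(a1 - target)[mask])
        assert errs[20000] < 1e-3
        assert errs[20000] < errs[1000] / 5  # ~O(1/N) decay

    def test_zero_flux_at_both_boundaries(self, success_problem):
        p = success_problem
        expn = expansion_from_ic(p, 200)
        t, L = 10.0, float(p.growth.length(10.0))
        h = 1e-4 * L
        for i in range(1, 5):
            f = lambda x: evaluate_uncoupled(p, expn, i, x, t)
            # second-order one-sided stencils; O(h^2) truncation
            left = (-3 * f(0.0) + 4 * f(h) - f(2 * h)) / (2 * h)
            right = (3 * f(L) - 4 * f(L - h) + f(L - 2 * h)) / (2 * h)
            assert abs(left) < 1e-6
            assert abs(right) < 1e-6

    def test_position_outside_domain_rejected(self, success_problem):
        expn = expansion_from_ic(success_problem, 10)
        with pytest.raises(OutOfDomainError):
            evaluate_uncoupled(success_problem, expn, 1, 1.5, 0.0)  # L(0) = 1


# ---------------------------------------------------------------------------
# Coupled evaluation: conservation, limits and dispatch
# ---------------------------------------------------------------------------

def series_mass_totals(problem, t, N=200, n_pts=2001):
    """Quadrature oracle: M_i(t) = L(t) * int_0^1 C_i dxi via Simpson."""
    xi = np.linspace(0.0, 1.0, n_pts)
    sol = gd.evaluate_coupled(problem, xi, [t], N=N)
    L = float(problem.growth.length(t))
    return np.array([L * simpson(sol.C[0, i], x=xi) for i in range(problem.lineage.G)])


class TestMassBalance:
    def test_totals_follow_compartment_ode(self, success_problem):
        # diffusion and dilution conserve totals; only the reaction chain
        # moves mass between generations: dM/dt = K M
        p = success_problem
        M0 = np.array([p.ic.C0 * p.ic.gamma, 0.0, 0.0, 0.0])
        for t in (5.0, 20.0):
            expected = expm(p.lineage.reaction_matrix() * t) @ M0
            np.testing.assert_allclose(series_mass_totals(p, t), expected, rtol=1e-6)

    def test_first_generation_decays_exponentially(self, success_problem):
        p = success_problem
        for t in (3.0, 12.0):
            M1 = series_mass_totals(p, t)[0]
            assert M1 == pytest.approx(
                p.ic.C0 * p.ic.gamma * math.exp(-p.lineage.k[0] * t), rel=1e-6)


class TestClassicalLimits:
    def test_nongrowing_unreactive_matches_heat_kernel_series(self):
        """Static domain, one inert generation: the classical Neumann heat series."""
        L0, D, C0, gamma = 1.3, 5e-2, 0.8, 0.5
        p = gd.Problem(growth=gd.make_linear(L0, 0.0),
                       lineage=gd.LineageModel(k=(0.0,), m=2),
                       ic=gd.InitialCondition.block(C0, gamma), D=D)
        x = np.linspace(0.0, L0, 41)
        t = 0.8
        sol = gd.evaluate_coupled(p, x, [t], N=400, grid_kind="x")
        # independently coded classical solution u_t = D u_xx, u_x(0)=u_x(L)=0
        u = np.full_like(x, C0 * gamma / L0)
        for n in range(1, 401):
            An = 2.0 * C0 / (n * math.pi) * math.sin(n * math.pi * gamma / L0)
            u += (An * np.cos(n * math.pi * x / L0)
                  * math.exp(-D * (n * math.pi / L0) ** 2 * t))
        np.testing.assert_allclose(sol.C[0, 0], u, atol=1e-10)

    def test_repeated_rate_limit_reached_from_distinct_rates(self):
        """k_2 -> k_1: the distinct-rate route converges to the L'Hopital form."""
        k1, t = 0.1, 10.0
        xi = np.linspace(0.0, 1.0, 21)
        equal = four_generation_problem(1e-2, k=(k1, k1, 0.3, 0.0))
        # closed form for C_2 when k_2 = k_1 (all-equal limit of the pair)
        C2_limit = gd.evaluate_coupled(equal, xi, [t], N=200).C[0, 1]
        errors = {}
        for eps in (1e-2, 1e-3, 1e-4):
            pert = four_generation_problem(1e-2, k=(k1, k1 + eps, 0.3, 0.0))
            C2 = gd.evaluate_coupled(pert, xi, [t], N=200).C[0, 1]
            errors[eps] = np.max(np.abs(C2 - C2_limit))
        assert errors[1e-3] < errors[1e-2]
        assert errors[1e-4] < errors[1e-3]
        # error is O(eps); extrapolating the last two to eps = 0 lands on the limit
        assert errors[1e-4] * (1e-3 / (1e-3 - 1e-4)) - errors[1e-3] * (
            1e-4 / (1e-3 - 1e-4)) < 1e-6


class TestRatePatternDispatch:
    def test_triple_plus_one_matches_modal_oracle(self):
        p = four_generation_problem(1e-2, k=(0.1, 0.1, 0.1, 0.0))
        xi = np.linspace(0.0, 1.0, 51)
        closed = gd.evaluate_coupled(p, xi, [10.0, 20.0], N=200)
        modal = gd.evaluate_modal(p, xi, [10.0, 20.0], N=200)
        np.testing.assert_allclose(closed.C, modal.C, atol=1e-12)

    def test_all_equal_matches_modal_oracle(self, equal_rates_problem):
        xi = np.linspace(0.0, 1.0, 51)
        closed = gd.evaluate_coupled(equal_rates_problem, xi, [10.0], N=200)
        modal = gd.evaluate_modal(equal_rates_problem, xi, [10.0], N=200)
        np.testing.assert_allclose(closed.C, modal.C, atol=1e-12)

    def test_unprinted_pattern_delegates_to_modal(self):
        p = four_generation_problem(1e-2, k=(0.1, 0.2, 0.2, 0.3))
        xi = np.linspace(0.0, 1.0, 51)
        sol = gd.evaluate_coupled(p, xi, [10.0], N=100)
        modal = gd.evaluate_modal(p, xi, [10.0], N=100)
        np.testing.assert_array_equal(sol.C, modal.C)

    def test_total_density_is_generation_sum(self, success_problem):
        sol = gd.evaluate_coupled(success_problem, np.linspace(0, 1, 11), [10.0], N=100)
        np.testing.assert_allclose(sol.S, sol.C.sum(axis=1))


class TestGeneralGrowthDecay:
    def test_linear_growth_series_matches_fd(self):
        """The general reaction+dilution factor e^{-k t} L0/L(t) is validated
        against the finite-difference solution on a linearly growing domain."""
        p = gd.Problem(growth=gd.make_linear(1.0, 0.2),
                       lineage=gd.LineageModel(k=(0.1, 0.2), m=2),
                       D=1e-2, ic=gd.InitialCondition.block(1.0, 0.2))
        fd = gd.solve_fd(p, gd.FDConfig(dxi=1e-2, dt=1e-3), [5.0])
        ex = gd.evaluate_coupled(p, fd.xi[0], [5.0], N=400)
        assert np.max(np.abs(fd.C - ex.C)) < 1e-2 * ex.S.max()


# ---------------------------------------------------------------------------
# Truncation study
# ---------------------------------------------------------------------------

class TestTruncation:
    def test_reference_level_gives_exact_zero(self, success_problem):
        errs = gd.truncation_error(success_problem, 200, [200], 0.0, 20.0)
        assert errs[200] == 0.0

    def test_errors_nonincreasing_in_terms(self, success_problem):
        errs = gd.truncation_error(success_problem, 1000, [1, 2, 5, 100], 0.0, 20.0)
        seq = [errs[1], errs[2], errs[5], errs[100]]
        assert all(a >= b for a, b in zip(seq, seq[1:]))

    def test_iterative_doubling_finds_small_truncation(self, success_problem):
        N = converged_truncation(success_problem, 0.0, 20.0, tol=1e-12)
        assert N <= 64
        errs = gd.truncation_error(success_problem, 1000, [N], 0.0, 20.0)
        assert errs[N] < 1e-12

    def test_reference_below_requested_levels_rejected(self, success_problem):
        with pytest.raises(InvalidParameterError):
            gd.truncation_error(success_problem, 10, [100], 0.0, 20.0)


class TestProblemValidation:
    def test_dirichlet_boundaries_not_implemented(self):
        with pytest.raises(NotImplementedError):
            gd.Problem(growth=gd.make_exponential(1.0, 0.1),
                       lineage=gd.LineageModel(k=(0.1,), m=2),
                       D=1e-2, ic=gd.InitialCondition.block(1.0, 0.2),
                       boundary="dirichlet")

    def test_nonpositive_diffusivity_rejected(self):
        with pytest.raises(InvalidParameterError):
            gd.Problem(growth=gd.make_exponential(1.0, 0.1),
                       lineage=gd.LineageModel(k=(0.1,), m=2),
                       D=0.0, ic=gd.InitialCondition.block(1.0, 0.2))
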