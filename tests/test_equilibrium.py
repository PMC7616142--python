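"""Equilibrium solver: ground states, stationarity, model agreement and
continuation behavior."""

import dataclasses

import numpy as np
import pytest

from mshell import (ScenarioParams, compatible_sphere_intrinsic, continue_branch,
                    pole_displacement, solve_equilibrium, volvox_intrinsic)
from mshell.equilibrium import Discretization
from mshell.errors import ConstrictionLimitError


class TestGroundStates:
    def test_identity_scenario_recovers_sphere(self, grid201):
        intr = compatible_sphere_intrinsic(1.0, grid201)
        sol = solve_equilibrium(intr)
        assert sol.energy.total < 1e-8
        assert abs(sol.d) < 1e-3
        assert sol.diagnostics["closure_residual"] < 1e-10

    def test_compatible_sphere_stress_free(self, grid201):
        intr = compatible_sphere_intrinsic(1.2, grid201)
        sol = solve_equilibrium(intr)
        assert sol.energy.total < 1e-8
        assert sol.shape.r.max() == pytest.approx(1.2, rel=1e-4)
        assert np.allclose(sol.shape.kappa_s[1:-1], 1 / 1.2, atol=1e-3)

    def test_deterministic(self, grid201):
        intr = compatible_sphere_intrinsic(1.1, grid201)
        a = solve_equilibrium(intr)
        b = solve_equilibrium(intr)
        assert np.array_equal(a.shape.psi, b.shape.psi)
        assert a.energy.total == b.energy.total

    def test_constriction_refusal(self, grid201):
        p = ScenarioParams(kappa_b=-11.0, w=0.5, eps_h=0.15)
        intr = volvox_intrinsic(p, grid201)
        with pytest.raises(ConstrictionLimitError):
            solve_equilibrium(intr, model="large_bending")


class TestGradient:
    def test_analytic_gradient_matches_fd(self, fig5a_params, grid201, rng):
        intr = volvox_intrinsic(fig5a_params, grid201)
        disc = Discretization(intr, "large_bending")
        x = disc.identity_x() + 0.01 * rng.standard_normal(2 * 201 - 2)
        E, g = disc.energy_grad(x)
        h = 1e-6
        for _ in range(10):
            v = rng.standard_normal(x.size)
            v /= np.linalg.norm(v)
            fd = (disc.energy_grad(x + h * v)[0] - disc.energy_grad(x - h * v)[0]) / (2 * h)
            assert fd == pytest.approx(float(g @ v), rel=1e-5, abs=1e-10)

    def test_closure_gradient_matches_fd(self, fig5a_params, grid201, rng):
        intr = volvox_intrinsic(fig5a_params, grid201)
        disc = Discretization(intr)
        x = disc.identity_x() + 0.01 * rng.standard_normal(2 * 201 - 2)
        gval, gg = disc.closure_grad(x)
        h = 1e-6
        v = rng.standard_normal(x.size)
        v /= np.linalg.norm(v)
        fd = (disc.closure_grad(x + h * v)[0] - disc.closure_grad(x - h * v)[0]) / (2 * h)
        assert fd == pytest.approx(float(gg @ v), rel=1e-6, abs=1e-12)


class TestFig5aScenario:
    @pytest.fixture(scope="class")
    def solutions(self):
        p = ScenarioParams(kappa_p=1.0, kappa_b=-2.0, kappa_a=1.0, f_p=0.8,
                           f_a=1.0, s0=1.5, w=0.2, eps_h=0.15)
        s = np.linspace(0, np.pi, 401)
        intr = volvox_intrinsic(p, s)
        return {m: solve_equilibrium(intr, model=m)
                for m in ("large_bending", "classical")}

    def test_models_agree_closely(self, solutions):
        d_big = solutions["large_bending"].d
        d_cls = solutions["classical"].d
        assert d_big > 0.1  # the sheet does invaginate
        assert abs(d_big - d_cls) / d_big < 0.05

    def test_stationarity_in_random_directions(self, solutions, rng):
        sol = solutions["large_bending"]
        p = ScenarioParams(kappa_p=1.0, kappa_b=-2.0, kappa_a=1.0, f_p=0.8,
                           f_a=1.0, s0=1.5, w=0.2, eps_h=0.15)
        intr = volvox_intrinsic(p, np.linspace(0, np.pi, 401))
        disc = Discretization(intr, "large_bending")
        x, lam = sol._x, sol._lam
        h = 1e-5
        for _ in range(20):
            v = rng.standard_normal(x.size)
            v /= np.linalg.norm(v)

            def L(z):
                E, _ = disc.energy_grad(z)
                g, _ = disc.closure_grad(z)
                return E + lam * g

            fd = (L(x + h * v) - L(x - h * v)) / (2 * h)
            assert abs(fd) < 1e-7

    def test_energy_breakdown_consistent_with_objective(self, solutions):
        """The reported split integrates (same quadrature) to the scalar
        objective the solver minimized."""
        p = ScenarioParams(kappa_p=1.0, kappa_b=-2.0, kappa_a=1.0, f_p=0.8,
                           f_a=1.0, s0=1.5, w=0.2, eps_h=0.15)
        intr = volvox_intrinsic(p, np.linspace(0, np.pi, 401))
        for model, sol in solutions.items():
            disc = Discretization(intr, model)
            E, _ = disc.energy_grad(sol._x)
            assert sol.energy.total == pytest.approx(E, rel=1e-10)

    def test_grid_convergence(self, solutions):
        p = ScenarioParams(kappa_p=1.0, kappa_b=-2.0, kappa_a=1.0, f_p=0.8,
                           f_a=1.0, s0=1.5, w=0.2, eps_h=0.15)
        d_coarse = solve_equilibrium(volvox_intrinsic(p, np.linspace(0, np.pi, 201))).d
        d_fine = solutions["large_bending"].d
        assert abs(d_coarse - d_fine) / d_fine < 0.005


def test_small_eta_model_agreement(grid201):
    """With the thickness reduced so max|eta| < 0.05, the two models give
    the same displacement to better than 1%."""
    p = ScenarioParams(kappa_p=1.0, kappa_b=-2.0, kappa_a=1.0, f_p=0.8,
                       f_a=1.0, s0=1.5, w=0.2, eps_h=0.03)
    intr = volvox_intrinsic(p, grid201)
    assert intr.max_abs_eta < 0.05
    d_big = solve_equilibrium(intr, model="large_bending").d
    d_cls = solve_equilibrium(intr, model="classical").d
    assert abs(d_big - d_cls) / abs(d_big) < 0.01


def test_pole_displacement_reads_posterior_pole(grid201):
    intr = compatible_sphere_intrinsic(1.0, grid201)
    sol = solve_equilibrium(intr)
    ref = None
    assert pole_displacement(sol) == pytest.approx(sol.d)
    assert pole_displacement(sol) == pytest.approx(
        sol.shape.z[0] - (-1.0), abs=1e-12)


class TestContinuation:
    def test_short_branch_monotone(self, fig5a_params):
        br = continue_branch(fig5a_params, (1.5, 2.5), n_grid=121,
                             ds0=0.2, ds_max=0.4)
        assert br.n_folds == 0
        assert br.terminated_reason == "completed"
        assert np.all(np.diff(br.k) > 0)
        assert np.all(np.diff(br.d) > 0)  # pre-fold branch: d grows with k

    def test_branch_points_are_equilibria(self, fig5a_params):
        br = continue_branch(fig5a_params, (1.5, 2.0), n_grid=121,
                             ds0=0.2, ds_max=0.4)
        # d at the endpoint matches a direct solve at that k
        s = np.linspace(0, np.pi, 121)
        p = fig5a_params.with_k(br.k[-1])
        sol = solve_equilibrium(volvox_intrinsic(p, s))
        assert sol.d == pytest.approx(br.d[-1], rel=1e-6)

    def test_critical_width_requires_bracket(self, fig5a_params):
        with pytest.raises(ValueError, match="does not fold"):
            from mshell import critical_width

            # a k-window this small contains no fold at any width
            critical_width(fig5a_params, (0.3, 0.4), k_range=(0.5, 1.0),
                           n_grid=101, tol=0.2)
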