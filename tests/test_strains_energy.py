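"""Strain measures, energy densities, splits, and excess formulas."""

import numpy as np
import pytest

from mshell import (compatible_sphere_intrinsic, energy_density, energy_excess,
                    shell_strains, total_energy, shape_from_tangent_fields,
                    undeformed_sphere)
from mshell.strains_energy import StrainField


def _random_strains(rng, n=200, eta_max=0.9):
    return StrainField(
        s=np.linspace(0, np.pi, n),
        es=rng.uniform(-0.1, 0.1, n),
        ephi=rng.uniform(-0.1, 0.1, n),
        Ks=rng.uniform(-3, 3, n),
        Kphi=rng.uniform(-3, 3, n),
        Ls=np.zeros(n),
        Lphi=np.zeros(n),
        eta=rng.uniform(-eta_max, eta_max, n),
    )


class TestShellStrains:
    def test_identity_strains_vanish(self, sphere201, grid201):
        intr = compatible_sphere_intrinsic(1.0, grid201)
        st = shell_strains(sphere201, intr)
        for f in (st.es, st.ephi, st.Ks, st.Kphi, st.Ls, st.Lphi):
            assert np.max(np.abs(f)) < 1e-10

    def test_inflated_sphere_pure_stretch(self, sphere201, grid201):
        """Sphere R -> fR with identity intrinsic data: K vanishes (pure
        stretching) while L does not."""
        f = 1.1
        intr = compatible_sphere_intrinsic(1.0, grid201)
        sh = shape_from_tangent_fields(sphere201.psi, np.full(201, f), sphere201)
        st = shell_strains(sh, intr)
        assert np.max(np.abs(st.Ks)) < 1e-9
        assert np.max(np.abs(st.Kphi)) < 1e-4
        assert np.min(np.abs(st.Ls)) > 1e-3  # (1/f - 1) = -0.0909...

    def test_small_inflation_L_linearization(self, sphere201, grid201):
        delta = 1e-3
        intr = compatible_sphere_intrinsic(1.0, grid201)
        sh = shape_from_tangent_fields(sphere201.psi, np.full(201, 1 + delta),
                                       sphere201)
        st = shell_strains(sh, intr)
        assert np.allclose(st.Ls, -delta, rtol=0.05)
        assert np.allclose(st.Lphi, -delta, rtol=0.05)

    def test_L_K_exact_relation(self, fig5a_params, grid201, sphere201):
        """L_s (1 + e_s) = K_s - (2 eta / t) e_s identically."""
        from mshell import volvox_intrinsic

        intr = volvox_intrinsic(fig5a_params, grid201)
        sh = shape_from_tangent_fields(sphere201.psi + 0.05 * np.sin(sphere201.s),
                                       np.full(201, 1.02), sphere201)
        st = shell_strains(sh, intr)
        lhs = st.Ls * (1.0 + st.es)
        rhs = st.Ks - (2.0 * st.eta / intr.t) * st.es
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_grid_mismatch_raises(self, sphere201):
        intr = compatible_sphere_intrinsic(1.0, np.linspace(0, np.pi, 101))
        with pytest.raises(ValueError, match="grid"):
            shell_strains(sphere201, intr)


class TestEnergyDensity:
    def test_zero_strains_zero_density(self, rng):
        st = _random_strains(rng)
        st.es[:] = st.ephi[:] = st.Ks[:] = st.Kphi[:] = 0.0
        bd = energy_density(st, t=0.15)
        assert np.all(bd.density_total == 0.0)

    def test_classical_limit_as_eta_vanishes(self, rng):
        """large-bending density -> classical density as eta -> 0; the
        leading difference is the coupling term, linear in eta (the
        coupling moduli are odd), and vanishes identically at eta = 0."""
        st = _random_strains(rng)
        diffs = []
        for eta in (2e-2, 1e-2):
            st.eta = np.full(st.s.size, eta)
            big = energy_density(st, 0.15, "large_bending").density_total
            cls = energy_density(st, 0.15, "classical").density_total
            diffs.append(np.max(np.abs(big - cls)))
        ratio = diffs[0] / diffs[1]
        assert ratio == pytest.approx(2.0, rel=0.1)
        st.eta = np.zeros(st.s.size)
        assert np.allclose(
            energy_density(st, 0.15, "large_bending").density_total,
            energy_density(st, 0.15, "classical").density_total, rtol=1e-12)

    def test_special_deformations_bounded_near_constriction(self):
        """e_phi = -2 e_s, K_phi = -3 K_s keeps the density bounded even
        at eta = 0.99, unlike a generic direction."""
        n = 3
        s = np.linspace(0, 1, n)
        eta = np.full(n, 0.99)
        special = StrainField(s, es=np.full(n, 0.05), ephi=np.full(n, -0.10),
                              Ks=np.full(n, 1.0), Kphi=np.full(n, -3.0),
                              Ls=np.zeros(n), Lphi=np.zeros(n), eta=eta)
        generic = StrainField(s, es=np.full(n, 0.05), ephi=np.full(n, 0.05),
                              Ks=np.full(n, 1.0), Kphi=np.full(n, 1.0),
                              Ls=np.zeros(n), Lphi=np.zeros(n), eta=eta)
        e_special = energy_density(special, 0.15).density_total.max()
        e_generic = energy_density(generic, 0.15).density_total.max()
        assert np.isfinite(e_special)
        assert e_special < 0.05 * e_generic
        # bounded: pushing eta further toward 1 barely changes it
        special.eta = np.full(n, 0.999)
        e_closer = energy_density(special, 0.15).density_total.max()
        assert e_closer == pytest.approx(e_special, rel=0.05)

    def test_total_is_sum_of_split(self, rng):
        st = _random_strains(rng)
        bd = energy_density(st, 0.15)
        assert np.allclose(bd.density_total, bd.stretch + bd.couple + bd.bend)

    def test_density_nonnegative_and_parts_signed(self, rng):
        """total >= 0 and stretch, bend >= 0 pointwise for |eta| < 1."""
        for _ in range(50):
            st = _random_strains(rng, n=2000, eta_max=0.95)
            bd = energy_density(st, 0.15)
            scale = np.max(bd.stretch + bd.bend) + 1e-30
            assert bd.density_total.min() >= -1e-12 * scale
            assert bd.stretch.min() >= -1e-14 * scale
            assert bd.bend.min() >= -1e-14 * scale

    def test_no_coupling_in_classical(self, rng):
        st = _random_strains(rng)
        bd = energy_density(st, 0.15, "classical")
        assert np.all(bd.couple == 0.0)

    def test_bookkeeping_equivalence(self, rng):
        """The physical form (t = eps*h, e = eps*E) equals the asymptotic
        bookkeeping form eps^3/2 {h[...E...] + 2h^2[...] + h^3[...]}
        symbol by symbol."""
        from mshell.coefficients import coefficient_set

        eps, h = 0.05, 3.0
        n = 50
        E_s = rng.uniform(-1, 1, n)
        E_p = rng.uniform(-1, 1, n)
        K_s = rng.uniform(-3, 3, n)
        K_p = rng.uniform(-3, 3, n)
        eta = rng.uniform(-0.9, 0.9, n)
        c = coefficient_set(eta)
        bookkeeping = 0.5 * eps**3 * (
            h * (c.alpha_bar_ss * E_s**2 + 2 * c.alpha_bar_sphi * E_s * E_p
                 + c.alpha_phiphi * E_p**2)
            + 2 * h**2 * (c.beta_bar_ss * E_s * K_s + c.beta_bar_sphi * E_s * K_p
                          + c.beta_phis * E_p * K_s + c.beta_phiphi * E_p * K_p)
            + h**3 * (c.gamma_ss * K_s**2 + 2 * c.gamma_sphi * K_s * K_p
                      + c.gamma_phiphi * K_p**2))
        st = StrainField(np.linspace(0, 1, n), es=eps * E_s, ephi=eps * E_p,
                         Ks=K_s, Kphi=K_p, Ls=np.zeros(n), Lphi=np.zeros(n),
                         eta=eta)
        physical = energy_density(st, t=eps * h).density_total
        assert np.allclose(physical, bookkeeping, rtol=1e-13)


class TestTotalEnergy:
    def test_identity_scenario_zero(self, sphere201, grid201):
        intr = compatible_sphere_intrinsic(1.0, grid201)
        assert abs(total_energy(sphere201, intr)) < 1e-12

    def test_compatible_sphere_zero_at_target(self, grid201):
        f = 1.2
        intr = compatible_sphere_intrinsic(f, grid201)
        sph = undeformed_sphere(n_grid=201)
        target = shape_from_tangent_fields(sph.psi, np.full(201, f), sph)
        # quadrature reconstruction of r gives O(grid^2) strain noise only
        assert abs(total_energy(target, intr)) < 1e-7

    def test_quadrature_convergence(self):
        """Simpson integration of an analytic strain field converges at
        fourth order."""
        from mshell.intrinsic_profiles import IntrinsicConfig

        energies = []
        for n in (101, 201):
            s = np.linspace(0, np.pi, n)
            sph = undeformed_sphere(n_grid=n)
            fs0 = 1.0 + 0.1 * np.sin(s) ** 2
            intr = IntrinsicConfig(s, fs0, np.ones(n), np.ones(n), np.ones(n),
                                   t=0.15)
            # analytic deformed shape: the unit sphere itself
            energies.append(total_energy(sph, intr))
        # both values are close; the refinement changes the quadrature
        # result far below the integrand scale
        assert abs(energies[0] - energies[1]) < 1e-8 * abs(energies[1])


class TestEnergyExcess:
    def test_excess_matches_direct_difference(self, rng):
        """Closed forms of the stretch/bend excess equal the direct
        large-minus-classical differences of the split."""
        st = _random_strains(rng, n=5000, eta_max=0.95)
        big = energy_density(st, 0.15, "large_bending")
        cls = energy_density(st, 0.15, "classical")
        s_x, b_x = energy_excess(st, 0.15)
        scale_s = np.max(np.abs(big.stretch)) + 1e-30
        scale_b = np.max(np.abs(big.bend)) + 1e-30
        assert np.max(np.abs(big.stretch - cls.stretch - s_x)) / scale_s < 1e-9
        assert np.max(np.abs(big.bend - cls.bend - b_x)) / scale_b < 1e-9

    def test_stretch_excess_nonnegative(self, rng):
        st = _random_strains(rng, n=5000, eta_max=0.95)
        s_x, _ = energy_excess(st, 0.15)
        assert s_x.min() >= 0.0

    def test_stretch_excess_zero_iff_special_direction(self, rng):
        st = _random_strains(rng, n=100, eta_max=0.9)
        st.ephi = -2.0 * st.es
        s_x, _ = energy_excess(st, 0.15)
        assert np.max(np.abs(s_x)) == 0.0
        st.ephi = -2.0 * st.es + 1e-3
        s_x, _ = energy_excess(st, 0.15)
        assert np.all(s_x[np.abs(st.eta) > 1e-3] > 0.0)

    def test_bend_excess_negative_in_window(self):
        """bend excess < 0 exactly when K_s K_phi < 0 and
        k(eta)|K_s| < |K_phi| < 3|K_s|."""
        from mshell import k_of_eta

        n = 1
        eta = np.array([0.5])
        k = float(k_of_eta(0.5))
        for ratio, expect_neg in [(-(k + 3) / 2, True), (-(k - 0.1), False),
                                  (-3.5, False), (2.0, False)]:
            st = StrainField(np.zeros(n), es=np.zeros(n), ephi=np.zeros(n),
                             Ks=np.ones(n), Kphi=np.array([ratio]),
                             Ls=np.zeros(n), Lphi=np.zeros(n), eta=eta)
            _, b_x = energy_excess(st, 0.15)
            assert (b_x[0] < 0) == expect_neg, ratio
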