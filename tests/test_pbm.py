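"""Aggregation population-balance model: kernel, growth, transport, grouping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from biosos.pbm import (AggregateSizeDensity, GrowthParams, KernelParams,
                        coalescence_kernel, evolve_pbm, gompertz_rate,
                        group_aggregates, population_counts, single_cell_size,
                        to_radius_density)
from biosos.fixtures import lognormal_radius_density, point_mass_density

X0 = single_cell_size()  # 7.5^3 under the x = R^3 convention


class TestCoalescenceKernel:
    def test_closed_form_at_single_cell_size(self):
        """Kernel at (x0, x0) equals an independent evaluation of the formula."""
        p = KernelParams()
        x0 = (4 * np.pi / 3) * 7.5**3
        expected = p.k * np.exp(-p.k1 * x0**p.a) * (2 * x0 ** (1 / 3)) ** (7 / 3)
        assert coalescence_kernel(x0, x0, p) == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(x=st.floats(min_value=X0, max_value=1e8),
           xp=st.floats(min_value=X0, max_value=1e8))
    def test_symmetric_finite_nonnegative(self, x, xp):
        p = KernelParams()
        k1 = coalescence_kernel(x, xp, p)
        k2 = coalescence_kernel(xp, x, p)
        assert k1 == pytest.approx(k2, rel=1e-12)
        assert np.isfinite(k1) and k1 >= 0

    def test_rejects_sub_cell_sizes(self):
        with pytest.raises(ValueError):
            coalescence_kernel(1.0, X0, KernelParams())

    def test_parameters_must_be_positive(self):
        with pytest.raises(ValueError):
            KernelParams(k=-1.0)


class TestGompertzRate:
    def test_zero_at_asymptote(self):
        p = GrowthParams()
        assert gompertz_rate(p.M, p) == 0.0

    def test_value_at_M_over_e(self):
        p = GrowthParams()
        assert gompertz_rate(p.M / np.e, p) == pytest.approx(p.alpha_G * p.M / np.e)

    def test_value_at_single_cell_size(self):
        p = GrowthParams()
        expected = p.alpha_G * X0 * np.log(p.M / X0)  # independent scalar arithmetic
        assert gompertz_rate(X0, p) == pytest.approx(expected, rel=1e-12)

    def test_clamps_above_asymptote_with_warning(self):
        p = GrowthParams()
        with pytest.warns(UserWarning):
            assert gompertz_rate(2 * p.M, p) == 0.0


class TestEvolvePBM:
    def test_no_dynamics_leaves_density_unchanged(self):
        init = lognormal_radius_density(median_um=30, sigma=0.3, n_aggregates=100, r_max=150)
        snaps, _ = evolve_pbm(init, kernel=None, growth=None, dt=0.1, horizon=5.0,
                              save_every=50)
        np.testing.assert_allclose(snaps[-1].values, init.values)

    def test_pure_coalescence_conserves_mass_and_loses_count(self):
        """Coalescence moves mass between sizes without creating or destroying it."""
        init = lognormal_radius_density(median_um=40, sigma=0.3, n_aggregates=1e4,
                                        r_max=300)
        snaps, diags = evolve_pbm(init, KernelParams(), None, dt=0.1, horizon=72.0,
                                  save_every=120)
        masses = [s.total_mass() for s in snaps]
        counts = [s.total_count() for s in snaps]
        assert abs(masses[-1] / masses[0] - 1) < 0.005
        assert all(c2 <= c1 + 1e-9 for c1, c2 in zip(counts, counts[1:]))

    def test_growth_follows_gompertz_characteristic(self):
        """Method-of-characteristics oracle: a narrow pulse advects along the
        trajectory of dx/dt = alpha_G x log(M/x) solved by a high-accuracy
        integrator, and the aggregate count stays constant."""
        gp = GrowthParams()
        init = point_mass_density(20.0, 1.0, r_max=300)
        start_x = init.size_grid[np.argmax(init.values)]
        snaps, _ = evolve_pbm(init, None, gp, dt=0.1, horizon=48.0, save_every=480)
        sol = solve_ivp(lambda t, x: [gompertz_rate(x[0], gp)], (0, 48), [start_x],
                        rtol=1e-10, atol=1e-6)
        mean_x = snaps[-1].total_mass() / snaps[-1].total_count()
        assert mean_x == pytest.approx(sol.y[0, -1], rel=0.08)  # first-order upwind
        assert snaps[-1].total_count() == pytest.approx(snaps[0].total_count(), rel=1e-9)

    def test_cfl_violation_raises(self):
        init = point_mass_density(20.0, 1.0, r_max=300)
        with pytest.raises(ValueError, match="CFL"):
            evolve_pbm(init, None, GrowthParams(), dt=50.0, horizon=100.0)


class TestRadiusTransform:
    def test_preserves_total_count(self):
        dens = lognormal_radius_density(median_um=50, sigma=0.4, n_aggregates=123.0)
        phi_R = to_radius_density(dens)
        assert phi_R.total_count() == pytest.approx(123.0, rel=1e-3)

    def test_point_mass_maps_27_to_radius_3(self):
        grid = np.linspace(1.0, 10.0, 1000)
        vals = np.zeros_like(grid)
        vals[np.argmin(np.abs(grid**3 - 27.0))] = 1.0
        dens = AggregateSizeDensity(size_grid=grid**3, values=vals)
        phi_R = to_radius_density(dens)
        assert phi_R.radius_grid[np.argmax(phi_R.values)] == pytest.approx(3.0, abs=0.01)

    def test_third_moment_identity(self):
        """Quadrature oracle: int R^3 phi_R dR = int x phi dx for smooth phi."""
        R = np.linspace(10.0, 200.0, 4000)
        phi = np.exp(-((R - 60.0) / 20.0) ** 2) / (3 * R**2)
        dens = AggregateSizeDensity(size_grid=R**3, values=phi)
        phi_R = to_radius_density(dens)
        lhs = np.trapezoid(phi_R.radius_grid**3 * phi_R.values, phi_R.radius_grid)
        rhs = np.trapezoid(dens.size_grid * dens.values, dens.size_grid)
        assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_printed_jacobian_scales_by_two_thirds(self):
        dens = lognormal_radius_density(median_um=50, sigma=0.4, n_aggregates=1.0)
        calc = to_radius_density(dens, jacobian="calculus")
        printed = to_radius_density(dens, jacobian="printed")
        np.testing.assert_allclose(printed.values, calc.values * 2.0 / 3.0)


class TestPopulationCounts:
    def test_single_cell_population(self):
        """All aggregates at the porosity-adjusted single-cell size: one cell each."""
        eps = 0.27
        x_cell = (4 * np.pi / 3) * 7.5**3
        x_sc = x_cell / (1 - eps)
        grid = x_sc * np.array([0.8, 0.9, 1.0, 1.1, 1.2])
        vals = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        dens = AggregateSizeDensity(size_grid=grid, values=vals)
        pc = population_counts(dens, porosity=eps, X=5e5, V=2.0)
        assert pc.z_cell == pytest.approx(1.0, rel=1e-3)
        assert pc.z_density == pytest.approx(5e5, rel=1e-3)
        assert pc.z_total == pytest.approx(1e6, rel=1e-3)

    def test_bimodal_matches_quadrature_oracle(self):
        R = np.linspace(7.5, 300.0, 2000)
        phi = np.exp(-((R - 40) / 10) ** 2) + 0.5 * np.exp(-((R - 120) / 15) ** 2)
        dens = AggregateSizeDensity(size_grid=R**3, values=phi)
        eps, X = 0.27, 1e6
        pc = population_counts(dens, porosity=eps, X=X)
        # brute-force midpoint quadrature oracle
        w = dens.bin_widths()
        count = np.sum(phi * w)
        m1 = (1 - eps) * np.sum(dens.size_grid * phi * w) / count
        z_cell = m1 / ((4 * np.pi / 3) * 7.5**3)
        assert pc.z_cell == pytest.approx(z_cell, rel=1e-12)
        assert pc.z_density == pytest.approx(X / z_cell, rel=1e-12)

    def test_warns_when_less_than_one_cell(self):
        grid = np.linspace(X0, 2 * X0, 100)
        dens = AggregateSizeDensity(size_grid=grid, values=np.ones_like(grid))
        with pytest.warns(UserWarning, match="z_cell"):
            population_counts(dens, porosity=0.27, X=1e6)


class TestGroupAggregates:
    def test_single_group_captures_everything(self):
        dens = lognormal_radius_density(median_um=50, sigma=0.3, n_aggregates=1.0)
        phi_R = to_radius_density(dens)
        groups = group_aggregates(phi_R, [7.5, 600.0], z_density=42.0)
        assert groups.group_density[0] == pytest.approx(42.0, rel=1e-6)

    def test_triangular_density_matches_trapezoid_oracle(self):
        R = np.linspace(10.0, 100.0, 2000)
        tri = np.maximum(0.0, 1 - np.abs(R - 50.0) / 30.0)
        phi_R = to_radius_density(
            AggregateSizeDensity(size_grid=R**3, values=tri / (3 * R**2)))
        bounds = np.array([10.0, 40.0, 70.0, 100.0])
        groups = group_aggregates(phi_R, bounds, z_density=1.0)
        total = np.trapezoid(tri, R)
        for l in range(3):
            mask = (R >= bounds[l]) & (R <= bounds[l + 1])
            expected = np.trapezoid(tri[mask], R[mask]) / total
            assert groups.group_density[l] == pytest.approx(expected, rel=5e-3)
        assert groups.group_density.sum() == pytest.approx(1.0, rel=1e-6)

    def test_warns_on_escaped_mass(self):
        dens = lognormal_radius_density(median_um=50, sigma=0.3, n_aggregates=1.0)
        phi_R = to_radius_density(dens)
        with pytest.warns(UserWarning, match="outside"):
            group_aggregates(phi_R, [40.0, 60.0], z_density=1.0)
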