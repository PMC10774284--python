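"""Variance decomposition, RSD, standardization, health classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biosos.heterogeneity import (HealthCriteria, classify_health,
                                  decompose_population_variance, group_variance,
                                  inner_outer_heterogeneity, rsd,
                                  standardize_fluxes, unhealthy_fraction_sweep)
from biosos.rdm import ShellDecomposition, shell_profile


def _profile(radius, rho_by_species, u_bulk, D=None):
    sh = ShellDecomposition.equal_width(radius)
    rho = np.tile(np.asarray(rho_by_species, float), (sh.n_shells, 1))
    if D is None:
        D = np.full(len(u_bulk), 4.3e5)
    return shell_profile(rho, np.asarray(D, float), sh, np.asarray(u_bulk, float))


class TestGroupVariance:
    def test_zero_rates_give_zero_moments(self):
        s2, mu = group_variance(np.zeros((3, 4)), np.array([1.0, -1, 0, 2]), 0.1)
        assert s2 == 0.0 and mu == 0.0

    def test_single_unit_channel_poisson_identity(self):
        """One reaction, one shell, coefficient +1: sigma^2 = mu = vbar dt."""
        s2, mu = group_variance(np.array([[5.0]]), np.array([1.0]), 0.2)
        assert s2 == pytest.approx(1.0)
        assert mu == pytest.approx(1.0)

    def test_analytic_matches_empirical_within_3se(self, rng):
        v_bar = np.array([[3.0, 1.0, 0.5], [2.0, 0.0, 4.0]])
        N_row = np.array([1.0, -2.0, 1.0])
        dt, omega, n = 0.5, 10.0, 10_000
        s2_a, mu = group_variance(v_bar, N_row, dt, omega)
        s2_e, mu_e = group_variance(v_bar, N_row, dt, omega, mode="empirical",
                                    rng=rng, n_replicates=n)
        assert mu_e == pytest.approx(mu)
        se_var = s2_a * np.sqrt(2.0 / (n - 1))
        assert abs(s2_e - s2_a) < 3 * se_var

    def test_empirical_needs_replicates(self):
        with pytest.raises(ValueError):
            group_variance(np.ones((1, 1)), np.ones(1), 0.1, mode="empirical",
                           n_replicates=1)


class TestRSD:
    def test_sigma_equals_mu_gives_one(self):
        assert rsd(4.0, 2.0) == pytest.approx(1.0)

    def test_single_channel_inverse_sqrt_law(self):
        """Poisson single channel: RSD = 1 / sqrt(vbar dt omega)."""
        v_bar, dt, omega = 7.0, 0.1, 500.0
        s2, mu = group_variance(np.array([[v_bar]]), np.array([1.0]), dt, omega)
        assert rsd(s2, mu) == pytest.approx(1.0 / np.sqrt(v_bar * dt * omega))

    def test_zero_mean_reported_missing(self):
        with pytest.warns(UserWarning):
            assert np.isnan(rsd(1.0, 0.0))


class TestVarianceDecomposition:
    def test_single_group_share_is_one(self):
        total, shares = decompose_population_variance([3.0])
        assert total == 3.0 and shares[0] == 1.0

    def test_equal_groups_equal_shares(self):
        _, shares = decompose_population_variance([2.0, 2.0, 2.0, 2.0])
        np.testing.assert_allclose(shares, 0.25)

    def test_additivity_matches_pooled_empirical(self, rng):
        """Sum of group variances vs variance of pooled independent draws."""
        lams = [4.0, 9.0, 2.5]
        n = 20_000
        pooled = sum(rng.poisson(lam, n) for lam in lams)
        total, _ = decompose_population_variance(lams)  # Poisson: sigma2 = lam
        emp = pooled.var(ddof=1)
        se = total * np.sqrt(2.0 / (n - 1))
        assert abs(emp - total) < 4 * se

    def test_exact_additivity_in_analytic_mode(self):
        parts = np.array([0.1, 0.7, 0.2])
        total, shares = decompose_population_variance(parts)
        assert total == parts.sum()
        assert shares.sum() == pytest.approx(1.0)


class TestStandardizeFluxes:
    def test_identical_groups_flagged_zero(self):
        z, flat = standardize_fluxes(np.full((3, 2), 5.0))
        assert np.all(z == 0.0) and np.all(flat)

    def test_two_groups_closed_form(self):
        """Two points a < b: z = -/+ (b-a)/2 / (sd with L-1) = -/+ 1/sqrt(2)."""
        z, flat = standardize_fluxes(np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(z.ravel(), [-1 / np.sqrt(2), 1 / np.sqrt(2)])
        assert not flat[0]

    @settings(deadline=None, max_examples=30)
    @given(st.integers(min_value=2, max_value=8), st.integers(min_value=0, max_value=2**31 - 1))
    def test_mean_zero_sd_one(self, L, seed):
        V = np.random.default_rng(seed).uniform(0, 10, size=(L, 3))
        z, flat = standardize_fluxes(V)
        for j in range(3):
            if not flat[j]:
                assert z[:, j].mean() == pytest.approx(0.0, abs=1e-10)
                assert z[:, j].std(ddof=1) == pytest.approx(1.0, rel=1e-10)


class TestClassifyHealth:
    SPECIES = ["GLC", "LAC"]

    def test_flat_healthy_profile(self):
        prof = _profile(60.0, [0.0, 0.0], [20.0, 0.0])
        _, frac = classify_health(prof, self.SPECIES)
        assert frac == 0.0

    def test_hand_built_three_shell_fraction(self):
        """Cell-count-weighted share of shells straddling the glucose threshold."""
        sh = ShellDecomposition(aggregate_radius=45.0,
                                boundaries=np.array([0.0, 15.0, 30.0, 45.0]))
        prof = shell_profile(np.zeros((3, 2)), np.array([4e5, 4e5]), sh,
                             np.array([20.0, 0.0]))
        prof.c_mid = np.array([[1.0, 0.0], [2.0, 0.0], [20.0, 0.0]])  # inner 2 starve
        flags, frac = classify_health(prof, self.SPECIES)
        weights = np.diff(sh.boundaries**3)
        expected = (weights[0] + weights[1]) / weights.sum()
        assert list(flags) == [True, True, False]
        assert frac == pytest.approx(expected)

    def test_monotone_in_bulk_conditions(self):
        """Raising glucose never raises the unhealthy fraction; raising lactate
        never lowers it."""
        rho = [-400.0, 350.0]
        fracs_g = [classify_health(_profile(240.0, rho, [g, 5.0]), self.SPECIES)[1]
                   for g in (2.0, 5.0, 10.0, 25.0)]
        assert all(b <= a + 1e-12 for a, b in zip(fracs_g, fracs_g[1:]))
        fracs_l = [classify_health(_profile(240.0, rho, [25.0, l]), self.SPECIES)[1]
                   for l in (0.0, 20.0, 35.0, 45.0)]
        assert all(b >= a - 1e-12 for a, b in zip(fracs_l, fracs_l[1:]))

    def test_missing_species_rejected(self):
        prof = _profile(60.0, [0.0], [20.0])
        with pytest.raises(ValueError):
            classify_health(prof, ["GLC"])

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            HealthCriteria(glucose_min=-1.0)


class TestInnerOuter:
    def test_single_shell_ratios_all_one(self):
        res = inner_outer_heterogeneity(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(res["ratios"], 1.0)
        assert res["index"] == 0.0

    def test_flat_profile_gives_unit_ratios(self):
        v = np.tile([4.0, 7.0], (5, 1))
        res = inner_outer_heterogeneity(v)
        np.testing.assert_allclose(res["ratios"], 1.0)
        assert res["index"] == 0.0

    def test_zero_outer_flux_excluded_with_flag(self):
        v = np.array([[1.0, 2.0], [3.0, 0.0]])
        res = inner_outer_heterogeneity(v, reaction_ids=["a", "b"])
        assert np.isnan(res["ratios"][1]) and res["excluded"][1]
        assert res["index"] == pytest.approx(abs(1 - 3) + abs(2 - 0))

    def test_index_grows_with_radius_at_fixed_bulk(self, network, flux_model):
        """Deterministic quasi-steady fluxes: the summed inner-outer deviation
        is non-decreasing over the 60-360 um radius sweep."""
        from biosos.assembly import SimulationConfig, solve_group_profile
        from biosos.rdm import _assemble_state
        init = network.initial_state()
        u = init[network.ext_index]
        idxs = []
        for R in (60.0, 120.0, 240.0, 360.0):
            n_sh = ShellDecomposition.equal_width(R).n_shells
            s = np.tile(init[network.int_index], (n_sh, 1))
            prof = solve_group_profile(network, flux_model, R, u, s,
                                       SimulationConfig())
            U = _assemble_state(network, network.ext_index, prof.c_mid, s)
            idxs.append(inner_outer_heterogeneity(flux_model.rates(U))["index"])
        assert all(b >= a - 1e-9 for a, b in zip(idxs, idxs[1:]))


class TestUnhealthySweep:
    def test_low_glucose_everything_unhealthy(self, network, flux_model):
        df = unhealthy_fraction_sweep(network, flux_model, [30.0, 300.0],
                                      {"GLC": 2.0, "LAC": 0.0},
                                      __import__("biosos.assembly",
                                                 fromlist=["SimulationConfig"]
                                                 ).SimulationConfig())
        assert np.allclose(df["unhealthy_percent"], 100.0)
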