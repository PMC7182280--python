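"""Alternative-hypothesis theory: noncentralities, mixtures, analytic power."""

import numpy as np
import pytest
from scipy import stats

from dotgsa import (EffectModel, alt_statistic_correlation, binary_attenuation,
                    dot_power, equicorr_noncentralities, equicorrelation,
                    noncentrality_from_effects, random_pd_correlation,
                    simulate_regression_statistics, standardized_effect_correlations,
                    tq_alt_mixture, tq_asymptotic_power, tq_ceiling_noncentrality,
                    tq_equicorr_power, tq_onedf_null_approx, tq_onedf_power,
                    tq_power, tq_power_approx)

SIMILAR_MU = (2.3, 2.4)    # equally spaced means, near-homogeneous effects
HETERO_MU = (1.0, 2.3)     # heterogeneous effects


def mu_grid(lo_hi, L):
    return np.linspace(lo_hi[0], lo_hi[1], L)


class TestBinaryAttenuation:
    def test_zero_threshold(self):
        assert binary_attenuation(0.0) == pytest.approx(2 * stats.norm.pdf(0), abs=1e-7)
        assert binary_attenuation(0.0) == pytest.approx(0.7978846, abs=1e-6)

    def test_symmetry(self):
        assert binary_attenuation(1.5) == pytest.approx(binary_attenuation(-1.5), abs=1e-14)

    def test_closed_form_at_unit_threshold(self):
        l = 1.0
        expected = stats.norm.pdf(l) / np.sqrt(stats.norm.cdf(l) * (1 - stats.norm.cdf(l)))
        assert binary_attenuation(l) == pytest.approx(expected, abs=1e-12)


class TestNoncentralities:
    def test_two_snp_moderate_ld_separates_means(self):
        m = EffectModel(beta=[0.3, 0.0], sigma=equicorrelation(2, 0.5), n=500)
        b = standardized_effect_correlations(m)
        assert b[0] == pytest.approx(0.29, abs=0.005)
        assert b[1] == pytest.approx(0.14, abs=0.005)

    def test_two_snp_high_ld_equalizes_means(self):
        m = EffectModel(beta=[0.3, 0.0], sigma=equicorrelation(2, 0.99), n=500)
        b = standardized_effect_correlations(m)
        assert b[0] == pytest.approx(0.29, abs=0.01)
        assert b[1] == pytest.approx(0.29, abs=0.01)

    def test_null_effects_give_zero_means(self):
        m = EffectModel(beta=[0.0, 0.0, 0.0], sigma=equicorrelation(3, 0.4), n=1000)
        np.testing.assert_array_equal(noncentrality_from_effects(m), np.zeros(3))

    def test_binary_trait_attenuates(self):
        cont = EffectModel(beta=[0.2, 0.1], sigma=equicorrelation(2, 0.3), n=800)
        bino = EffectModel(beta=[0.2, 0.1], sigma=equicorrelation(2, 0.3), n=800,
                           trait="binary", threshold=1.0)
        ratio = noncentrality_from_effects(bino) / noncentrality_from_effects(cont)
        np.testing.assert_allclose(ratio, binary_attenuation(1.0), atol=1e-12)


class TestAltCorrelation:
    def test_reduces_to_sigma_under_null(self):
        sigma = random_pd_correlation(5, seed=2)
        m = EffectModel(beta=np.zeros(5), sigma=sigma, n=1000)
        np.testing.assert_allclose(alt_statistic_correlation(m).values, sigma.values,
                                   atol=1e-14)

    def test_unlinked_associated_snps_correlate_negatively(self):
        # no LD, both SNPs associated with positive effects: the statistics
        # pick up a negative correlation through the shared outcome
        m = EffectModel(beta=[0.3, 0.2], sigma=np.eye(2), n=1000)
        r = alt_statistic_correlation(m).values[0, 1]
        b = standardized_effect_correlations(m)
        assert r < 0 and np.sign(r) == -np.sign(b[0] * b[1])

    def test_matches_regression_simulation(self):
        """Delta-method mean and correlation reproduce simulated marginal
        statistics from actual regressions (the joint-distribution oracle)."""
        m = EffectModel(beta=[0.3, 0.2], sigma=equicorrelation(2, 0.5), n=1000)
        mu = noncentrality_from_effects(m)
        r_alt = alt_statistic_correlation(m).values[0, 1]
        n_reps = 30_000
        zs = simulate_regression_statistics(m, seed=99, n_reps=n_reps)
        se_mean = zs.std(axis=0) / np.sqrt(n_reps)
        assert np.all(np.abs(zs.mean(axis=0) - mu) < 3 * se_mean)
        r_emp = np.corrcoef(zs, rowvar=False)[0, 1]
        se_r = (1 - r_emp**2) / np.sqrt(n_reps)
        assert abs(r_emp - r_alt) < 3 * se_r


class TestMixtureAndConservation:
    def test_null_means_give_zero_noncentralities(self):
        spec = tq_alt_mixture(np.zeros(6), random_pd_correlation(6, seed=3))
        np.testing.assert_array_equal(spec.gammas, np.zeros(6))

    def test_equal_means_concentrate_on_leading_component(self):
        spec = tq_alt_mixture(np.full(10, 1.7), equicorrelation(10, 0.6))
        assert spec.gammas[0] == pytest.approx(spec.gamma_c, abs=1e-9)
        np.testing.assert_allclose(spec.gammas[1:], 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_conservation_of_noncentrality(self, seed):
        """sum gamma_i (TQ mixture) = gamma_c (DOT) = mu' R^-1 mu."""
        rng = np.random.default_rng(seed)
        L = 7
        R = random_pd_correlation(L, seed=seed + 50)
        mu = rng.normal(scale=1.5, size=L)
        spec = tq_alt_mixture(mu, R)
        direct = mu @ np.linalg.solve(R.values, mu)
        assert spec.gamma_c == pytest.approx(direct, rel=1e-8)

    def test_helmert_closed_form_matches_inversion(self):
        rng = np.random.default_rng(4)
        mu = rng.normal(size=7)
        rho = 0.4
        spec = equicorr_noncentralities(mu, rho)
        direct = mu @ np.linalg.solve(equicorrelation(7, rho).values, mu)
        assert spec.gamma_c == pytest.approx(direct, abs=1e-10)
        assert spec.helmert_deltas.sum() == pytest.approx(spec.gamma_c, abs=1e-10)
        assert spec.delta_s == pytest.approx(spec.helmert_deltas[1:].sum(), abs=1e-10)

    def test_equal_means_have_no_contrast_mass(self):
        spec = equicorr_noncentralities(np.full(12, 2.0), 0.5)
        assert spec.delta_s == pytest.approx(0.0, abs=1e-12)
        assert spec.gamma_c == pytest.approx(12 * 4.0 / (1 + 11 * 0.5), abs=1e-10)

    def test_average_per_snp_noncentrality(self):
        assert equicorr_noncentralities(mu_grid(SIMILAR_MU, 20), 0.7).gamma_c / 20 == \
            pytest.approx(0.39, abs=0.005)
        assert equicorr_noncentralities(mu_grid(SIMILAR_MU, 500), 0.7).gamma_c / 500 == \
            pytest.approx(0.02, abs=0.005)


class TestPower:
    def test_null_power_is_alpha(self):
        R = equicorrelation(5, 0.3)
        assert dot_power(np.zeros(5), R, 0.05).power == pytest.approx(0.05, abs=1e-9)
        assert tq_power(np.zeros(5), R, 0.05).power == pytest.approx(0.05, abs=1e-6)

    def test_two_component_reduction_matches_full_mixture(self):
        for L in (20, 100, 500):
            mu = mu_grid(SIMILAR_MU, L)
            full = tq_power(mu, equicorrelation(L, 0.7), 0.05).power
            reduced = tq_equicorr_power(mu, 0.7, 0.05).power
            assert reduced == pytest.approx(full, abs=1e-6)

    def test_zero_correlation_limit_is_noncentral_chi2(self):
        mu = mu_grid(SIMILAR_MU, 10)
        got = tq_equicorr_power(mu, 1e-12, 0.05).power
        expected = stats.ncx2.sf(stats.chi2.isf(0.05, 10), 10, mu @ mu)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_dot_power_increases_with_noncentrality(self):
        R = equicorrelation(20, 0.7)
        powers = [dot_power(np.full(20, s), R, 0.05).power for s in (0.5, 1.0, 2.0)]
        assert powers[0] < powers[1] < powers[2]

    def test_dot_gains_with_l_under_heterogeneity_while_tq_plateaus(self):
        # heterogeneous effects: decorrelation converts added SNPs into
        # noncentrality, the raw sum saturates at its ceiling
        dots, tqs = [], []
        for L in (20, 100, 300):
            mu = mu_grid(HETERO_MU, L)
            dots.append(dot_power(mu, equicorrelation(L, 0.7), 0.05).power)
            tqs.append(tq_equicorr_power(mu, 0.7, 0.05).power)
        assert dots[0] < dots[1] < dots[2]
        ceiling = tq_asymptotic_power(np.mean(np.abs(mu_grid(HETERO_MU, 300)))**2,
                                      0.7, 0.05).power
        assert abs(tqs[2] - tqs[1]) < 0.005          # plateau
        assert ceiling == pytest.approx(tqs[2], abs=0.03)  # one-df ceiling nearby

    def test_tq_beats_dot_under_homogeneous_effects(self):
        mu = mu_grid(SIMILAR_MU, 50)
        assert tq_equicorr_power(mu, 0.7, 0.05).power > \
            dot_power(mu, equicorrelation(50, 0.7), 0.05).power

    def test_dot_beats_tq_under_strong_heterogeneity(self):
        mu = mu_grid(HETERO_MU, 300)
        assert dot_power(mu, equicorrelation(300, 0.7), 0.05).power > \
            tq_equicorr_power(mu, 0.7, 0.05).power


class TestOneDfApproximations:
    def test_null_rejection_rate_matches_alpha(self):
        """Location-scale one-df approximation calibrates the null (Eq-16
        style check by simulating the exact two-eigenvalue mixture)."""
        rng = np.random.default_rng(8)
        L, rho, n = 100, 0.7, 10**5
        lam1, lam2 = 1 + (L - 1) * rho, 1 - rho
        tq_null = lam1 * rng.chisquare(1, n) + lam2 * rng.chisquare(L - 1, n)
        rej = np.fromiter(
            (tq_onedf_null_approx(L, rho, t, 0.05)[1] for t in tq_null), bool, n)
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(rej.mean() - 0.05) < 3 * se + 0.003   # approximation slack

    def test_power_column_values(self):
        # one-df "P-approximation" power for the heterogeneous-effects table
        assert tq_onedf_power(mu_grid(HETERO_MU, 500), 0.7, 0.05).power == \
            pytest.approx(0.526, abs=0.002)

    def test_approx_power_reproduces_reference_column(self):
        assert tq_power_approx(mu_grid(SIMILAR_MU, 20), 0.7, 0.05).power == \
            pytest.approx(0.794, abs=0.002)
        assert tq_power_approx(mu_grid(SIMILAR_MU, 500), 0.7, 0.05).power == \
            pytest.approx(0.802, abs=0.002)

    def test_approx_close_to_exact_for_large_l(self):
        for L in (100, 300):
            mu = np.full(L, 1.8)
            approx = tq_power_approx(mu, 0.6, 0.05).power
            exact = tq_equicorr_power(mu, 0.6, 0.05).power
            assert approx == pytest.approx(exact, abs=0.01)

    def test_rms_correlation_used_for_rho_star(self):
        # heterogeneous LD: rho* is the root-mean-square off-diagonal
        from dotgsa import perturbed_equicorrelation, rms_correlation
        R = perturbed_equicorrelation(30, 0.5, 0.0, 2.0, seed=1)
        off = R.values[~np.eye(30, dtype=bool)]
        assert rms_correlation(R) == pytest.approx(np.sqrt(np.mean(off**2)), abs=1e-12)


class TestCeiling:
    def test_reference_asymptotic_powers(self):
        assert tq_asymptotic_power(2.35**2, 0.7, 0.05).power == pytest.approx(0.802, abs=0.001)
        assert tq_asymptotic_power(2.35**2, 0.3, 0.05).power == pytest.approx(0.99, abs=0.005)

    def test_null_ceiling_is_alpha(self):
        assert tq_asymptotic_power(0.0, 0.7, 0.05).power == pytest.approx(0.05)

    def test_gamma_star(self):
        assert tq_ceiling_noncentrality(2.35**2, 0.7) == pytest.approx(2.35**2 / 0.7)
        with pytest.raises(ValueError, match="ceiling"):
            tq_ceiling_noncentrality(1.0, 0.0)
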