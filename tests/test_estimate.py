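import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

import fastla as fl
from fastla.estimate import EstimationError, equal_count_bins

from conftest import brute_force_mla


class TestEqualCountBins:
    @pytest.mark.parametrize("n, expected", [
        (9, [3, 3, 3]),
        (73, [25, 24, 24]),
        (74, [25, 24, 25]),
    ])
    def test_sizes_outer_first(self, n, expected, rng):
        bins = equal_count_bins(rng.normal(size=n), 3)
        assert [b.size for b in bins] == expected

    def test_values_ordered_across_bins(self, rng):
        x = rng.normal(size=40)
        bins = equal_count_bins(x, 4)
        for a, b in zip(bins, bins[1:]):
            assert x[a].max() <= x[b].min()

    def test_too_few_errors(self):
        with pytest.raises(EstimationError):
            equal_count_bins(np.arange(8.0), 3)


class TestMlaDirect:
    def test_independent_genes_near_zero(self, rng):
        n = 10_000
        x1, x2, x3 = rng.standard_normal((3, n))
        assert abs(fl.mla_direct(x1, x2, x3)) < 3 / np.sqrt(n)

    def test_constant_coexpression_gives_controller_mean(self, rng):
        # x1 == x2: within-bin products are (x1*)^2 with bin mean 1, so the
        # estimate collapses to mean(x3) -- no liquid association
        x1 = rng.standard_normal(200)
        x3 = rng.standard_normal(200)
        est = fl.mla_direct(x1, x1.copy(), x3)
        assert est == pytest.approx(x3.mean(), abs=1e-12)
        z3 = (x3 - x3.mean()) / x3.std(ddof=1)
        assert fl.mla_direct(x1, x1.copy(), z3) == pytest.approx(0.0, abs=1e-12)

    def test_twelve_sample_toy_matches_loop_oracle(self):
        x1 = np.array([0.2, -1.1, 0.5, 1.7, -0.3, 0.9,
                       -1.5, 0.1, 2.0, -0.7, 0.4, -0.2])
        x2 = np.array([-0.5, 0.8, 1.2, -0.1, 0.3, -1.9,
                       0.6, -0.4, 1.1, 0.0, -1.3, 0.7])
        x3 = np.array([1.5, -0.2, 0.9, -1.1, 0.4, 0.1,
                       -0.8, 1.9, -1.4, 0.6, -0.5, 1.0])
        assert fl.mla_direct(x1, x2, x3) == pytest.approx(
            brute_force_mla(x1, x2, x3), abs=1e-12)

    def test_missing_values_dropped(self, rng):
        x1, x2, x3 = rng.standard_normal((3, 60))
        x1m = x1.copy()
        x1m[5] = np.nan
        keep = np.ones(60, bool)
        keep[5] = False
        assert fl.mla_direct(x1m, x2, x3) == pytest.approx(
            fl.mla_direct(x1[keep], x2[keep], x3[keep]))

    def test_zero_within_bin_variance_errors(self):
        x1 = np.ones(30)
        x2 = np.random.default_rng(0).normal(size=30)
        x3 = np.arange(30.0)
        with pytest.raises(EstimationError):
            fl.mla_direct(x1, x2, x3)

    def test_sign_agreement_with_rho_diff_on_null(self, null50):
        from fastla.simulate import all_triplet_stats
        rho, mla = all_triplet_stats(null50)
        agreement = np.mean(np.sign(rho) == np.sign(mla))
        assert agreement >= 0.98


class TestWaldPvalue:
    @pytest.mark.parametrize("wald, expected", [
        (49.050, 2.501e-12),
        (46.720, 8.194e-12),
    ])
    def test_published_values(self, wald, expected):
        # printed Wald statistics are rounded, so agreement is ~0.3%
        assert fl.wald_pvalue(wald) == pytest.approx(expected, rel=3e-3)

    def test_null_value(self):
        assert fl.wald_pvalue(0.0) == 1.0

    def test_strictly_decreasing(self):
        grid = np.linspace(0.0, 60.0, 200)
        p = np.array([fl.wald_pvalue(w) for w in grid])
        assert np.all(np.diff(p) < 0)

    def test_negative_errors(self):
        with pytest.raises(EstimationError):
            fl.wald_pvalue(-1.0)


class TestFitCnm:
    def test_full_model_parameter_recovery(self):
        true = dict(mean_coefs=(0.0, 0.2, 0.0, -0.2),
                    logvar_coefs=(0.3, 0.1, 0.0, 0.0), c0=0.0, c1=0.4)
        x1, x2, z = fl.simulate_la_triplet(
            10_000, true["c0"], true["c1"], true["mean_coefs"],
            true["logvar_coefs"], seed=42)
        fit = fl.fit_cnm(x1, x2, z, "full")
        assert fit.converged
        est = np.array([*fit.mean_coefs, *fit.logvar_coefs, *fit.corr_coefs])
        truth = np.array([*true["mean_coefs"], *true["logvar_coefs"],
                          true["c0"], true["c1"]])
        se = np.sqrt(np.diag(fit.cov))
        assert np.all(np.abs(est - truth) < 3 * se)

    def test_null_slope_near_zero(self):
        x1, x2, z = fl.simulate_la_triplet(5_000, 0.3, 0.0, seed=9)
        fit = fl.fit_cnm(x1, x2, z, "full")
        assert abs(fit.corr_coefs[1]) < 0.05
        assert fit.wald < 4.0

    def test_simple_nested_in_full(self):
        # data with no mean/variance dependence: full adds 4 parameters,
        # so the log-likelihood gap behaves like chi2 with 4 df
        x1, x2, z = fl.simulate_la_triplet(2_000, 0.2, 0.3, seed=5)
        full = fl.fit_cnm(x1, x2, z, "full")
        simple = fl.fit_cnm(x1, x2, z, "simple")
        assert simple.mean_coefs[1] == simple.mean_coefs[3] == 0.0
        assert simple.logvar_coefs[1] == simple.logvar_coefs[3] == 0.0
        lrt = 2 * (full.loglik - simple.loglik)
        assert lrt >= -1e-6
        assert lrt < 20.0  # chi2_4 0.9995 quantile

    def test_simple_loglik_never_exceeds_full(self, rng):
        for seed in range(3):
            x1, x2, z = fl.simulate_la_triplet(
                500, 0.1, 0.2, (0.1, 0.3, -0.1, 0.2), (0.0, 0.2, 0.1, -0.1),
                seed=seed)
            full = fl.fit_cnm(x1, x2, z, "full")
            simple = fl.fit_cnm(x1, x2, z, "simple")
            assert simple.loglik <= full.loglik + 1e-6

    def test_degenerate_input_errors(self):
        with pytest.raises(EstimationError):
            fl.fit_cnm(np.ones(50), np.arange(50.0), np.arange(50.0), "full")
        with pytest.raises(EstimationError):
            fl.fit_cnm(np.arange(10.0), np.arange(10.0), np.arange(10.0), "full")


class TestMlaFromCnm:
    def test_zero_slope_gives_zero(self):
        x1, x2, z = fl.simulate_la_triplet(200, 0.5, 0.3, seed=1)
        fit = fl.fit_cnm(x1, x2, z, "simple")
        fit.corr_coefs = (fit.corr_coefs[0], 0.0)
        assert fl.mla_from_cnm(fit, z) == 0.0

    def test_matches_gaussian_quadrature(self):
        x1, x2, z = fl.simulate_la_triplet(10_000, 0.0, 0.6, seed=3)
        fit = fl.fit_cnm(x1, x2, z, "full")
        c0, c1 = fit.corr_coefs

        def integrand(t):
            return c1 * (1 - np.tanh(c0 + c1 * t) ** 2) * norm.pdf(t)

        expected, _ = integrate.quad(integrand, -10, 10)
        assert fl.mla_from_cnm(fit, z) == pytest.approx(expected, abs=0.02)

    def test_linearization_limit(self, rng):
        z = rng.standard_normal(5_000)
        x1, x2, _ = fl.simulate_la_triplet(5_000, 0.0, 0.05, seed=4)
        fit = fl.fit_cnm(x1, x2, z, "simple")
        c1 = fit.corr_coefs[1]
        assert fl.mla_from_cnm(fit, z) == pytest.approx(c1, abs=0.01)


class TestLackOfFit:
    def test_well_specified_data_passes(self):
        false_count = 0
        reps = 40
        for seed in range(reps):
            x1, x2, z = fl.simulate_la_triplet(
                1_000, 0.1, 0.3, (0.0, 0.2, 0.0, -0.1), (0.0, 0.1, 0.0, 0.0),
                seed=100 + seed)
            fit = fl.fit_cnm(x1, x2, z, "full")
            if not fl.lack_of_fit(fit, x1, x2, z):
                false_count += 1
        assert false_count / reps >= 0.90

    def test_u_shaped_correlation_flagged(self, rng):
        # correlation +0.8 in both outer tertiles, -0.8 in the middle:
        # no tanh(c0 + c1 z) can describe it
        n = 600
        z = np.sort(rng.standard_normal(n))
        r = np.where((np.arange(n) < n // 3) | (np.arange(n) >= 2 * n // 3),
                     0.8, -0.8)
        u1 = rng.standard_normal(n)
        u2 = r * u1 + np.sqrt(1 - r ** 2) * rng.standard_normal(n)
        fit = fl.fit_cnm(u1, u2, z, "full")
        assert fl.lack_of_fit(fit, u1, u2, z)

    def test_clean_linear_data_passes(self):
        x1, x2, z = fl.simulate_la_triplet(1_000, 0.0, 0.4, seed=77)
        fit = fl.fit_cnm(x1, x2, z, "full")
        assert not fl.lack_of_fit(fit, x1, x2, z)


class TestRobustEstimate:
    def test_same_seed_bit_identical(self, rng):
        x1, x2, x3 = rng.standard_normal((3, 150))
        a = fl.robust_estimate(x1, x2, x3, n_boot=200, seed=11)
        b = fl.robust_estimate(x1, x2, x3, n_boot=200, seed=11)
        assert a.se_boot == b.se_boot
        assert a.pvalue == b.pvalue

    def test_planted_signal_power(self):
        hits = 0
        reps = 20
        for seed in range(reps):
            x1, x2, z = fl.simulate_la_triplet(300, 0.0, 0.5, seed=200 + seed)
            r = fl.robust_estimate(x1, x2, z, n_boot=200, seed=seed)
            hits += r.pvalue < 0.05
        assert hits / reps >= 0.80

    def test_small_n_boot_errors(self, rng):
        x1, x2, x3 = rng.standard_normal((3, 100))
        with pytest.raises(EstimationError):
            fl.robust_estimate(x1, x2, x3, n_boot=50, seed=0)

    def test_estimate_matches_mla_direct(self, rng):
        x1, x2, x3 = rng.standard_normal((3, 120))
        r = fl.robust_estimate(x1, x2, x3, n_boot=100, seed=0)
        assert r.mla_estimate == fl.mla_direct(x1, x2, x3)
        assert r.se_boot > 0
        assert 0 < r.pvalue <= 1


class TestCascade:
    def test_clean_cnm_data_uses_full_model(self):
        x1, x2, z = fl.simulate_la_triplet(1_000, 0.0, 0.4, seed=13)
        est = fl.estimate_triplet(x1, x2, z, n_boot=100, seed=1)
        assert est.model == "F"
        assert est.pvalue < 0.01

    def test_u_shape_falls_back(self, rng):
        n = 600
        z = np.sort(rng.standard_normal(n))
        r = np.where((np.arange(n) < n // 3) | (np.arange(n) >= 2 * n // 3),
                     0.8, -0.8)
        u1 = rng.standard_normal(n)
        u2 = r * u1 + np.sqrt(1 - r ** 2) * rng.standard_normal(n)
        est = fl.estimate_triplet(u1, u2, z, n_boot=100, seed=1)
        assert est.model in ("S", "R")
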