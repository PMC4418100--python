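"""Wrapped-Cauchy synchrony model: densities, likelihood, DIC machinery."""

import numpy as np
import pytest
from scipy import integrate, stats

import movespec as ms
from movespec._mcmc import circular_mean
from movespec.synchrony import (
    LOG_TWO_PI,
    McmcConfig,
    SynchronyModel,
    beta_mode_shape_log_density,
    beta_mode_shape_params,
    compute_dic,
    run_synchrony_mcmc,
    scan_cutoff,
    synchrony_log_likelihood,
    wcd_log_density,
)


class TestWcdDensity:
    def test_uniform_limit(self):
        for theta in (-3.0, 0.0, 2.5):
            assert wcd_log_density(theta, 1.0, 0.0) == pytest.approx(
                -np.log(2 * np.pi)
            )

    def test_closed_form_at_mode(self):
        # (1 - rho^2)/(1 - rho)^2 = (1 + rho)/(1 - rho) = 3 at rho = 0.5
        assert wcd_log_density(0.7, 0.7, 0.5) == pytest.approx(
            np.log(3.0 / (2 * np.pi))
        )

    @pytest.mark.parametrize("rho", [0.0, 0.3, 0.9])
    def test_integrates_to_one(self, rho):
        val, _ = integrate.quad(
            lambda t: np.exp(wcd_log_density(t, 0.4, rho)), -np.pi, np.pi,
            epsabs=1e-12,
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_periodicity(self):
        assert wcd_log_density(0.3 + 2 * np.pi, -0.2, 0.6) == pytest.approx(
            wcd_log_density(0.3, -0.2 + 4 * np.pi, 0.6), abs=1e-12
        )

    def test_invalid_rho(self):
        with pytest.raises(ValueError):
            wcd_log_density(0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            wcd_log_density(0.0, 0.0, -0.1)


class TestBetaModeShape:
    def test_symmetric_case_is_beta22(self):
        # M = 0.5, nu = 4 -> Beta(2, 2), density 1.5 at the mode
        a, b = beta_mode_shape_params(0.5, 4.0)
        assert (a, b) == (2.0, 2.0)
        assert np.exp(beta_mode_shape_log_density(0.5, 0.5, 4.0)) == pytest.approx(1.5)

    def test_argmax_equals_mode(self):
        grid = np.linspace(1e-4, 1 - 1e-4, 20001)
        dens = beta_mode_shape_log_density(grid, 0.2, 10.0)
        assert grid[np.argmax(dens)] == pytest.approx(0.2, abs=1e-3)
        a, b = beta_mode_shape_params(0.2, 10.0)
        assert (a - 1) / (a + b - 2) == pytest.approx(0.2)

    def test_integrates_to_one(self):
        val, _ = integrate.quad(
            lambda r: np.exp(beta_mode_shape_log_density(r, 0.3, 7.0)), 0, 1,
            epsabs=1e-12,
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_shape_must_exceed_two(self):
        with pytest.raises(ValueError):
            beta_mode_shape_params(0.5, 2.0)


class TestLikelihood:
    def test_cutoff_zero_is_uniform_constant(self):
        rng = np.random.default_rng(0)
        theta = rng.uniform(-np.pi, np.pi, size=(5, 4))
        model = SynchronyModel(mu=np.zeros(5), rho=np.zeros(5), cutoff=0)
        assert synchrony_log_likelihood(theta, model) == pytest.approx(
            -4 * 5 * LOG_TWO_PI
        )

    def test_full_cutoff_with_zero_rho_degenerates_to_uniform(self):
        rng = np.random.default_rng(1)
        theta = rng.uniform(-np.pi, np.pi, size=(5, 4))
        model = SynchronyModel(mu=np.zeros(5), rho=np.zeros(5), cutoff=5)
        assert synchrony_log_likelihood(theta, model) == pytest.approx(
            -4 * 5 * LOG_TWO_PI
        )

    def test_matches_brute_force_product(self):
        theta = np.array([[0.3, -1.2], [2.9, 0.4]])
        mu = np.array([0.1, -0.5])
        rho = np.array([0.6, 0.2])
        model = SynchronyModel(mu=mu, rho=rho, cutoff=1)
        brute = sum(
            wcd_log_density(theta[0, n], mu[0], rho[0]) for n in range(2)
        ) - 2 * 1 * LOG_TWO_PI
        assert synchrony_log_likelihood(theta, model) == pytest.approx(
            brute, abs=1e-10
        )
        model2 = SynchronyModel(mu=mu, rho=rho, cutoff=2)
        brute2 = sum(
            wcd_log_density(theta[f, n], mu[f], rho[f])
            for f in range(2)
            for n in range(2)
        )
        assert synchrony_log_likelihood(theta, model2) == pytest.approx(
            brute2, abs=1e-10
        )

    def test_common_rotation_only_shifts_mu(self):
        rng = np.random.default_rng(2)
        theta = rng.uniform(-np.pi, np.pi, size=(3, 6))
        mu = rng.uniform(-np.pi, np.pi, size=3)
        rho = np.array([0.5, 0.7, 0.2])
        shift = 1.234
        rotated = theta.copy()
        rotated[1] = np.angle(np.exp(1j * (theta[1] + shift)))
        mu_shifted = mu.copy()
        mu_shifted[1] = np.angle(np.exp(1j * (mu[1] + shift)))
        m1 = SynchronyModel(mu=mu, rho=rho, cutoff=3)
        m2 = SynchronyModel(mu=mu_shifted, rho=rho, cutoff=3)
        assert synchrony_log_likelihood(theta, m1) == pytest.approx(
            synchrony_log_likelihood(rotated, m2), abs=1e-10
        )

    def test_cutoff_beyond_l_rejected(self):
        theta = np.zeros((3, 2))
        model = SynchronyModel(mu=np.zeros(4), rho=np.zeros(4), cutoff=4)
        with pytest.raises(ValueError):
            synchrony_log_likelihood(theta, model)


class TestComputeDic:
    def test_degenerate_posterior_has_zero_pd(self):
        theta = np.random.default_rng(3).uniform(-np.pi, np.pi, size=(2, 4))
        mu = np.array([0.5, -0.3])
        rho = np.array([0.4, 0.1])
        samples = {"mu": np.tile(mu, (200, 1)), "rho": np.tile(rho, (200, 1))}

        def ll(m, r):
            return synchrony_log_likelihood(
                theta, SynchronyModel(mu=m, rho=r, cutoff=2)
            )

        dic, p_d, dev = compute_dic(samples, ll)
        assert p_d == pytest.approx(0.0, abs=1e-10)
        assert dic == pytest.approx(dev)
        assert dev == pytest.approx(-2 * ll(mu, rho))

    def test_recomputation_matches_definition(self, priors, fast_mcmc):
        rng = np.random.default_rng(4)
        theta = rng.uniform(-np.pi, np.pi, size=(4, 6))
        fit = run_synchrony_mcmc(theta, 2, priors, fast_mcmc)
        mu = fit.samples["mu"].reshape(-1, 2)
        rho = fit.samples["rho"].reshape(-1, 2)

        def ll(m, r):
            return synchrony_log_likelihood(
                theta, SynchronyModel(mu=np.r_[m, 0, 0], rho=np.r_[r, 0, 0], cutoff=2)
            )

        # independent recomputation from stored draws, without the cached logliks
        dic, p_d, dev = compute_dic({"mu": mu[::20], "rho": rho[::20]}, ll)
        dev_draws = np.array([-2 * ll(mu[i], rho[i]) for i in range(0, len(mu), 20)])
        assert dev == pytest.approx(
            -2 * ll(circular_mean(mu[::20], axis=0), rho[::20].mean(axis=0))
        )
        assert p_d == pytest.approx(dev_draws.mean() - dev, abs=1e-8)
        assert dic == pytest.approx(2 * p_d + dev, abs=1e-12)
        # the fit's own DIC obeys the identity too
        assert fit.dic == pytest.approx(2 * fit.p_d + fit.deviance_at_mean, abs=1e-10)

    def test_circular_mean_respects_wraparound(self):
        m = circular_mean(np.array([-3.0, 3.0]))
        assert abs(m) > 3.0  # near +/- pi, nowhere near 0

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            compute_dic({"mu": np.empty((0, 1)), "rho": np.empty((0, 1))}, None)


class TestSampler:
    def test_null_model_is_analytic(self, priors, fast_mcmc):
        theta = np.random.default_rng(5).uniform(-np.pi, np.pi, size=(31, 6))
        fit = run_synchrony_mcmc(theta, 0, priors, fast_mcmc)
        assert fit.p_d == 0.0
        assert fit.dic == pytest.approx(2 * 6 * 31 * LOG_TWO_PI, abs=1e-12)
        assert fit.deviance_at_mean == fit.dic

    def test_posterior_concentrates_on_true_synchrony(self, priors):
        # strong synchrony at f <= 3 with N = 20 individuals
        cfg = ms.SyntheticConfig(seed=77, n_individuals=20, cutoff=3, rho=0.9)
        panel, truth, _ = ms.simulate_panel(cfg)
        dec = ms.decompose(panel)
        fit = run_synchrony_mcmc(
            dec.phases, 3, priors, McmcConfig(chains=2, iterations=3000, seed=8)
        )
        rho = fit.samples["rho"].reshape(-1, 3)
        lo = np.quantile(rho, 0.025, axis=0)
        hi = np.quantile(rho, 0.975, axis=0)
        assert np.all(fit.mean_rho > 0.6)
        # credible intervals bracket strong synchrony for all three frequencies
        assert np.all(hi > 0.8) and np.all(lo < 0.97)
        mu_err = np.abs(np.angle(np.exp(1j * (fit.mean_mu - truth.mu))))
        assert np.all(mu_err < 0.5)

    def test_prior_only_run_recovers_uniform_mode_prior(self, priors):
        theta = np.random.default_rng(6).uniform(-np.pi, np.pi, size=(5, 6))
        cfg = McmcConfig(chains=2, iterations=6000, seed=9, prior_only=True)
        fit = run_synchrony_mcmc(theta, 5, priors, cfg)
        m = fit.samples["M"].ravel()
        # posterior of M should match its Uniform(0,1) prior
        qs = np.quantile(m, [0.25, 0.5, 0.75])
        assert np.allclose(qs, [0.25, 0.5, 0.75], atol=0.06)
        d = stats.kstest(m[::10], "uniform").statistic
        assert d < 0.08


class TestScan:
    def test_scan_table_structure(self, priors, fast_mcmc):
        theta = np.random.default_rng(10).uniform(-np.pi, np.pi, size=(5, 6))
        scan = scan_cutoff(theta, priors, fast_mcmc)
        assert len(scan.table) == 6  # l + 1 rows including the phi = 0 null
        delta = scan.delta_dic
        assert np.all(delta >= 0)
        assert int((delta == 0).sum()) == 1
        assert scan.table.loc[scan.selected, "delta_dic"] == 0.0

    def test_synchronous_data_selects_true_cutoff(self, priors):
        cfg = ms.SyntheticConfig(
            seed=21, n_individuals=20, n_days=16, cutoff=2, rho=0.95
        )
        panel, _, _ = ms.simulate_panel(cfg)
        dec = ms.decompose(panel)
        scan = scan_cutoff(
            dec.phases, priors, McmcConfig(chains=2, iterations=2000, seed=3)
        )
        # both synchronous frequencies must be inside the selected band, and
        # models that miss them must be decisively rejected
        assert scan.selected >= 2
        dic = scan.table["dic"].to_numpy()
        assert dic[0] - dic[2] > 50  # null far worse than the true model
        assert dic[1] - dic[2] > 50  # cutting off below the truth is far worse
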