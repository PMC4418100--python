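"""Hierarchical 1/f colour model: likelihood, sampler, predictive checks."""

import numpy as np
import pytest
from scipy import stats

import movespec as ms
from movespec.colour import (
    ColourFit,
    ColourModel,
    gammabar_conditional,
    posterior_predictive_periodogram,
    residual_diagnostics,
    run_colour_mcmc,
    whittle_log_likelihood,
)
from movespec.synchrony import McmcConfig


def _fit_from_draws(a, gamma, m):
    """Wrap fixed (a, gamma) draws as a ColourFit for the predictive helpers."""
    a = np.asarray(a, float)
    gamma = np.asarray(gamma, float)
    samples = {
        "gamma": gamma[None],  # (1, S, N)
        "log_a": np.log(a)[None],
    }
    return ColourFit(samples=samples, summaries=None, m=m)


class TestWhittleLikelihood:
    def test_white_noise_unit_scale(self):
        psi = np.abs(np.random.default_rng(0).normal(size=(5, 3)))
        model = ColourModel(scale=np.ones(3), colour=np.zeros(3))
        assert whittle_log_likelihood(psi, model) == pytest.approx(-psi.sum())

    def test_residuals_at_their_mean(self):
        model = ColourModel(scale=np.array([2.0, 0.5]), colour=np.array([1.0, -0.3]))
        y = model.spectrum(6)
        assert whittle_log_likelihood(y, model) == pytest.approx(
            -(1.0 + np.log(y)).sum()
        )

    def test_matches_brute_force_sum(self):
        psi = np.array([[1.0, 0.2], [0.7, 2.0], [0.1, 0.5]])
        a = np.array([1.5, 0.8])
        g = np.array([0.9, -0.2])
        model = ColourModel(scale=a, colour=g)
        brute = 0.0
        for n in range(2):
            for f in range(1, 4):
                y = a[n] * f ** (-g[n])
                brute += -np.log(y) - psi[f - 1, n] / y
        assert whittle_log_likelihood(psi, model) == pytest.approx(brute, abs=1e-10)

    def test_nonpositive_spectrum_rejected(self):
        model = ColourModel(scale=np.array([1.0, -1.0]), colour=np.zeros(2))
        with pytest.raises(ValueError, match="positive"):
            whittle_log_likelihood(np.ones((3, 2)), model)


class TestGibbsConditional:
    def test_matches_numeric_posterior(self, priors):
        """Conditional of the population mean vs a brute-force grid posterior."""
        gamma = np.array([0.9, 0.6, 0.8, 0.7, 1.1, 0.5])
        sg2 = 0.09
        mean, var = gammabar_conditional(gamma, sg2, priors)
        grid = np.linspace(-3, 4, 140001)
        logp = stats.norm.logpdf(
            gamma[:, None], loc=grid[None], scale=np.sqrt(sg2)
        ).sum(axis=0) + stats.norm.logpdf(
            grid, priors.gammabar_mean, np.sqrt(priors.gammabar_var)
        )
        w = np.exp(logp - logp.max())
        w /= w.sum()
        num_mean = float(np.sum(grid * w))
        num_var = float(np.sum((grid - num_mean) ** 2 * w))
        assert mean == pytest.approx(num_mean, abs=1e-6)
        assert var == pytest.approx(num_var, rel=1e-3)


class TestSampler:
    def test_population_colour_recovery(self, priors):
        """Posterior locates a known red-noise colour with N=6 individuals."""
        cfg = ms.SyntheticConfig(seed=314, gamma=np.full(6, 1.0), a=np.ones(6))
        panel, _, _ = ms.simulate_panel(cfg)
        dec = ms.decompose(panel)
        fit = run_colour_mcmc(
            dec.ordinates, priors, McmcConfig(chains=2, iterations=4000, seed=4)
        )
        lo = fit.summaries.loc["gammabar", "lo95"]
        hi = fit.summaries.loc["gammabar", "hi95"]
        assert lo < 1.0 < hi
        assert fit.summaries.loc["gammabar", "mean"] == pytest.approx(1.0, abs=0.35)
        # interval endpoints are the 2.5/97.5% sample quantiles by contract
        draws = fit.samples["gammabar"].ravel()
        assert lo == pytest.approx(np.quantile(draws, 0.025))
        assert hi == pytest.approx(np.quantile(draws, 0.975))
        assert lo < fit.summaries.loc["gammabar", "mean"] < hi

    def test_scale_equivariance(self, priors):
        """Rescaling ordinates shifts log a posteriors and leaves colour alone.

        Scaling every individual by k is an exact translation of the log-scale
        block (the flat hyperprior is translation invariant); scaling a single
        individual shifts its log a_n by roughly log k, attenuated by
        hierarchical shrinkage toward the population mean.
        """
        cfg = ms.SyntheticConfig(seed=15)
        panel, _, _ = ms.simulate_panel(cfg)
        psi = ms.decompose(panel).ordinates
        k = 50.0
        mc = McmcConfig(chains=2, iterations=4000, seed=5)
        f1 = run_colour_mcmc(psi, priors, mc)

        f_all = run_colour_mcmc(k * psi, priors, mc)
        d_all = f_all.samples["log_a"].mean(axis=(0, 1)) - f1.samples["log_a"].mean(
            axis=(0, 1)
        )
        np.testing.assert_allclose(d_all, np.log(k), atol=0.15)
        d_gamma = f_all.samples["gamma"].mean(axis=(0, 1)) - f1.samples["gamma"].mean(
            axis=(0, 1)
        )
        np.testing.assert_allclose(d_gamma, 0.0, atol=0.15)

        psi_one = psi.copy()
        psi_one[:, 2] *= k
        f_one = run_colour_mcmc(psi_one, priors, mc)
        d_one = (
            f_one.samples["log_a"][:, :, 2].mean() - f1.samples["log_a"][:, :, 2].mean()
        )
        assert 0.7 * np.log(k) < d_one <= 1.1 * np.log(k)

    def test_unit_exponential_residuals_under_truth(self):
        rng = np.random.default_rng(8)
        m, n = 512, 4
        a = np.array([1.0, 2.0, 0.5, 3.0])
        g = np.array([0.5, 1.0, 0.0, 0.8])
        f = np.arange(1, m + 1, dtype=float)[:, None]
        y = a * f ** (-g)
        psi = rng.exponential(y)
        z = psi / y
        assert z.mean() == pytest.approx(1.0, abs=0.1)
        assert z.var() == pytest.approx(1.0, abs=0.15)

    def test_too_few_individuals_rejected(self, priors):
        with pytest.raises(ValueError, match="at least 3"):
            run_colour_mcmc(np.ones((8, 2)), priors)


class TestPosteriorPredictive:
    def test_degenerate_posterior_gives_exponential_band(self):
        fit = _fit_from_draws(np.ones((150, 2)), np.zeros((150, 2)), m=4)
        band = posterior_predictive_periodogram(fit, n_reps=200_000, seed=2)
        # Exp(1) quantiles: 0.0253 and 3.689
        np.testing.assert_allclose(band["lo95"], 0.02532, atol=0.004)
        np.testing.assert_allclose(band["hi95"], 3.6889, atol=0.08)
        np.testing.assert_allclose(band["mean"], 1.0, atol=0.02)

    def test_band_mean_obeys_law_of_large_numbers(self):
        rng = np.random.default_rng(3)
        a = rng.lognormal(0, 0.3, size=(300, 3))
        g = rng.normal(0.7, 0.2, size=(300, 3))
        fit = _fit_from_draws(a, g, m=5)
        band = posterior_predictive_periodogram(fit, n_reps=10_000, seed=4)
        expected = np.stack(
            [(a * ff ** (-g)).mean(axis=0) for ff in range(1, 6)], axis=0
        )
        np.testing.assert_allclose(band["mean"], expected, rtol=0.05)

    def test_calibration_on_model_simulated_data(self, priors):
        cfg = ms.SyntheticConfig(seed=31)
        panel, _, _ = ms.simulate_panel(cfg)
        psi = ms.decompose(panel).ordinates
        fit = run_colour_mcmc(psi, priors, McmcConfig(chains=2, iterations=3000, seed=6))
        band = posterior_predictive_periodogram(fit, n_reps=4000, seed=7)
        inside = np.mean((psi >= band["lo95"]) & (psi <= band["hi95"]))
        assert inside == pytest.approx(0.95, abs=0.05)


class TestResidualDiagnostics:
    def test_nominal_false_positive_rate_under_truth(self, priors):
        cfg = ms.SyntheticConfig(seed=11)
        panel, _, _ = ms.simulate_panel(cfg)
        psi = ms.decompose(panel).ordinates
        fit = run_colour_mcmc(psi, priors, McmcConfig(chains=2, iterations=3000, seed=9))
        rep = residual_diagnostics(psi, fit, n_realizations=400, seed=10)
        assert not rep.verdicts.to_numpy().any()
        assert np.all(np.abs(rep.fractions.to_numpy() - 0.05) <= 0.05)

    def test_constructed_misfit_triggers_lag_one_verdict(self):
        # ordinates of an exact 1/f spectrum modulated by a slow sinusoid in f:
        # the fitted-model residuals inherit the sinusoid and correlate at lag 1
        m, n = 31, 6
        f = np.arange(1, m + 1, dtype=float)[:, None]
        y = 1.0 * f ** (-0.75) * np.ones((1, n))
        modulation = 1.0 + 0.9 * np.sin(2 * np.pi * np.arange(m) / 14.0)[:, None]
        psi = y * modulation
        fit = _fit_from_draws(
            np.ones((200, n)), np.full((200, n), 0.75), m=m
        )
        rep = residual_diagnostics(psi, fit, n_realizations=200, seed=12)
        assert rep.verdicts["lag1"].all()

    def test_lag_bounds_validated(self):
        fit = _fit_from_draws(np.ones((120, 2)), np.zeros((120, 2)), m=5)
        with pytest.raises(ValueError, match="lag"):
            residual_diagnostics(np.ones((5, 2)), fit, n_realizations=120, lags=(5,))
        with pytest.raises(ValueError, match="realizations"):
            residual_diagnostics(np.ones((5, 2)), fit, n_realizations=10)
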