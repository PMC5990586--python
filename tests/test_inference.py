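import numpy as np
import pytest
from scipy import stats

from cogreg.bayesfactor import conjugate_posterior_alpha
from cogreg.diagnostics import gelman_rubin, rhat_table
from cogreg.linear import gibbs_jzs_linear, sample_regression_layer_prior
from cogreg.models import RegressionModelSpec, center_covariates
from cogreg.sampling import (
    InsufficientChainsError,
    SamplerConfig,
    initialize_latents,
    sample_posterior,
)
from cogreg.simulate import ScenarioConfig, generate_dataset


class TestSamplerConfig:
    def test_defaults_mirror_simulation_protocol(self):
        cfg = SamplerConfig()
        assert (cfg.n_chains, cfg.n_iterations, cfg.n_burnin, cfg.thin) == \
            (2, 45_000, 5_000, 5)
        assert cfg.n_retained == 8_000

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_iterations=100, n_burnin=100)
        with pytest.raises(ValueError):
            SamplerConfig(thin=0)


class TestInitializeLatents:
    def test_distributional_properties(self):
        spec = RegressionModelSpec()
        rng = np.random.default_rng(0)
        design = center_covariates(rng.normal(size=(200, 2)))
        draws = [initialize_latents(spec, 200, 2, np.random.default_rng(i),
                                    design=design) for i in range(300)]
        mus = np.array([d.mu for d in draws])
        sigmas = np.sqrt(np.array([d.sigma2 for d in draws]))
        coefs = np.array([d.coef for d in draws])
        assert abs(mus.mean()) < 0.1 and abs(mus.std() - 1) < 0.1
        assert np.all(sigmas > 0)
        assert abs(sigmas.mean() - 1.0) < 0.15  # Exponential(1) mean
        assert abs(coefs.std() - 2.0) < 0.15  # weights drawn with SD 2
        assert np.all(np.array([d.g for d in draws]) == 1.0)

    def test_seeds_differ(self):
        spec = RegressionModelSpec()
        design = center_covariates(np.random.default_rng(0).normal(size=(5, 1)))
        a = initialize_latents(spec, 5, 1, np.random.default_rng(1),
                               design=design)
        b = initialize_latents(spec, 5, 1, np.random.default_rng(2),
                               design=design)
        assert not np.allclose(a.mu, b.mu)


class TestGelmanRubin:
    def test_identical_chains_near_one(self, rng):
        x = rng.normal(size=2000)
        chains = np.stack([x, x])
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_flagged(self, rng):
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)])
        assert gelman_rubin(chains) > 1.1

    def test_single_chain_error(self, rng):
        with pytest.raises(InsufficientChainsError):
            gelman_rubin(rng.normal(size=(1, 100)))


class TestConjugateShrinkage:
    """Closed-form checks of the conditional posterior of the weights."""

    def test_posterior_mean_is_shrunk_ols(self, rng):
        x = rng.normal(size=(60, 2))
        y = x @ np.array([0.8, -0.3]) + rng.normal(size=60)
        for g in (0.1, 1.0, 10.0):
            mean, shrink = conjugate_posterior_alpha(y, x, g)
            assert shrink == pytest.approx(g / (1 + g))
            xc = x - x.mean(axis=0)
            ols = np.linalg.lstsq(xc, y - y.mean(), rcond=None)[0]
            np.testing.assert_allclose(mean, g / (1 + g) * ols)

    def test_gibbs_matches_shrinkage_estimate(self, rng):
        # conjugate sub-case: observed criterion, fixed g
        x = rng.normal(size=(80, 1))
        y = 0.6 * x[:, 0] + rng.normal(size=80)
        g_over_n = 4.0 / 80  # effective Zellner g of 4 under X'X/N scaling
        d = gibbs_jzs_linear(y, x, n_draws=40_000, n_burnin=1000, seed=2,
                             fixed_g=g_over_n)
        expected, _ = conjugate_posterior_alpha(y, x, 4.0)
        assert d["alpha"][:, 0].mean() == pytest.approx(expected[0], abs=0.02)


class TestPosteriorSampling:
    def test_same_seed_identical_draws(self, tiny_dataset):
        dataset, cov, _ = tiny_dataset
        design = center_covariates(cov[["x1", "x2"]].to_numpy())
        cfg = SamplerConfig.test_scale(seed=5, n_iterations=150, n_burnin=50,
                                       max_treedepth=4)
        spec = RegressionModelSpec()
        a = sample_posterior(spec, dataset, design, cfg)
        b = sample_posterior(spec, dataset, design, cfg)
        for k in a.draws:
            np.testing.assert_array_equal(a.draws[k], b.draws[k])

    def test_retained_draw_count_and_domains(self, tiny_dataset):
        dataset, cov, _ = tiny_dataset
        design = center_covariates(cov[["x1", "x2"]].to_numpy())
        cfg = SamplerConfig.test_scale(seed=5, n_iterations=160, n_burnin=40,
                                       thin=3, max_treedepth=4)
        ps = sample_posterior(RegressionModelSpec(), dataset, design, cfg)
        assert ps.draws["mu"].shape == (2, 40, 4)
        assert np.all(ps.draws["sigma2"] > 0)
        assert np.all(ps.draws["g"] > 0)
        assert set(rhat_table(ps)) >= {"mu[0]", "sigma2[3]", "g[0]",
                                       "coef[0][0]"}

    def test_prior_only_regression_recovers_prior_quantiles(self):
        # no-data limit: group-level draws follow the prior
        rng = np.random.default_rng(0)
        design = center_covariates(rng.normal(size=(20, 2)))
        cfg = SamplerConfig.test_scale(seed=3, n_iterations=4000,
                                       n_burnin=500)
        ps = sample_posterior(RegressionModelSpec(), None, design, cfg,
                              method="gibbs")
        mu = ps.pooled("mu").ravel()
        # Gibbs draws are autocorrelated; allow ~3 MC standard errors
        assert abs(mu.mean()) < 0.08
        assert abs(mu.std() - 1.0) < 0.06
        s2 = ps.pooled("sigma2").ravel()
        q = np.percentile(s2, [25, 50, 75])
        expect = stats.invgamma(a=2, scale=0.5).ppf([0.25, 0.5, 0.75])
        np.testing.assert_allclose(q, expect, rtol=0.1)

    def test_backends_agree_on_small_posterior(self):
        # dual-route check: NUTS and Metropolis-within-Gibbs target the
        # same joint posterior; compare group-level means on a tame fit
        gv = {"A": (0.5, 0.0, 0.0, 0.6), "w": (0.0, -0.5, 0.3, 0.6),
              "a": (0.0, 0.0, 0.2, 0.6), "c": (0.0, 0.0, -0.3, 0.5)}
        cfg = ScenarioConfig(n_participants=12, n_trials=40, rho=0.0,
                             base_seed=21, generating_values=gv)
        dataset, cov, _ = generate_dataset(cfg, 0)
        design = center_covariates(cov[["x1", "x2"]].to_numpy())
        spec = RegressionModelSpec()
        hmc_cfg = SamplerConfig.test_scale(seed=1, n_iterations=900,
                                           n_burnin=300, max_treedepth=6)
        gibbs_cfg = SamplerConfig.test_scale(seed=2, n_iterations=12_000,
                                             n_burnin=3000, thin=3)
        a = sample_posterior(spec, dataset, design, hmc_cfg, method="hmc")
        b = sample_posterior(spec, dataset, design, gibbs_cfg, method="gibbs")
        np.testing.assert_allclose(a.pooled("mu").mean(axis=0),
                                   b.pooled("mu").mean(axis=0), atol=0.25)
        np.testing.assert_allclose(a.pooled("sigma2").mean(axis=0),
                                   b.pooled("sigma2").mean(axis=0), atol=0.3)


class TestSimulationBasedCalibration:
    def test_rank_uniformity_of_regression_layer(self):
        """SBC at reduced scale: draw the group level from its prior,
        generate probit-scale data directly, refit, and check that the
        rank of the true value among posterior draws is uniform."""
        rng = np.random.default_rng(11)
        design = center_covariates(rng.normal(size=(25, 2)))
        n_rep = 48
        n_rank = 24  # ranks 0..24 from 24 thinned posterior draws
        ranks = {"mu": [], "alpha0": []}
        for rep in range(n_rep):
            prior = sample_regression_layer_prior(design, rng=rng)
            y = (prior["mu"] + design.X @ prior["alpha"]
                 + np.sqrt(prior["sigma2"]) * rng.standard_normal(25))
            d = gibbs_jzs_linear(y, design, n_draws=720, n_burnin=300,
                                 seed=rep, priors="hierarchical")
            keep = slice(0, 720, 30)
            ranks["mu"].append((d["mu"][keep] < prior["mu"]).sum())
            ranks["alpha0"].append(
                (d["alpha"][keep, 0] < prior["alpha"][0]).sum())
        for name, r in ranks.items():
            counts = np.bincount(np.asarray(r) // 5, minlength=5)
            stat, p = stats.chisquare(counts)
            assert p > 0.001, f"SBC ranks non-uniform for {name}: {counts}"
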