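import numpy as np
import pytest
from scipy import integrate, stats

from cogreg.models import (
    BasicHierSpec,
    DesignError,
    Latents,
    MedianSplitModelSpec,
    RegressionModelSpec,
    center_covariates,
    effect_code,
    g_logprior,
    inverse_probit,
    joint_logdensity,
    probit_transform,
    regression_logprior,
)


class TestProbitTransform:
    @pytest.mark.parametrize("z,U,expected", [(0.5, 1, 0.0), (2.5, 5, 0.0)])
    def test_midpoint_maps_to_zero(self, z, U, expected):
        assert probit_transform(z, U) == pytest.approx(expected)

    @pytest.mark.parametrize("z,U", [(0.123, 1), (4.2, 5), (1e-4, 1)])
    def test_round_trip(self, z, U):
        assert inverse_probit(probit_transform(z, U), U) == \
            pytest.approx(z, abs=1e-10)

    def test_monotone(self):
        zs = np.linspace(0.01, 4.99, 50)
        assert np.all(np.diff(probit_transform(zs, 5)) > 0)

    @pytest.mark.parametrize("z,U", [(0.0, 1), (1.0, 1), (5.1, 5), (-0.2, 1)])
    def test_domain_errors(self, z, U):
        with pytest.raises(ValueError):
            probit_transform(z, U)


class TestCovariateDesign:
    def test_centering(self):
        d = center_covariates(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(d.X[:, 0], [-1, 0, 1])
        assert d.sd[0] == pytest.approx(np.sqrt(2 / 3))  # denominator-N

    def test_idempotent_on_centered_input(self, rng):
        raw = rng.normal(size=(20, 2))
        raw -= raw.mean(axis=0)
        d = center_covariates(raw)
        np.testing.assert_allclose(d.X, raw, atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(DesignError, match="degenerate"):
            center_covariates(np.array([[5.0, 1], [5.0, 2], [5.0, 3]]))

    def test_xtx_n_equals_variance_for_single_covariate(self, rng):
        x = rng.normal(size=(40, 1))
        d = center_covariates(x)
        assert d.xtx_n[0, 0] == pytest.approx(d.sd[0] ** 2)


class TestEffectCode:
    def test_even_split(self):
        codes = effect_code(np.array([[1.0], [2.0], [3.0], [4.0]]))
        np.testing.assert_array_equal(codes[:, 0], [-0.5, -0.5, 0.5, 0.5])

    def test_value_at_median_goes_low(self):
        codes = effect_code(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_array_equal(codes[:, 0], [-0.5, -0.5, 0.5])

    def test_code_sums_balance_without_median_ties(self, rng):
        x = rng.normal(size=(30, 1))  # continuous: no ties at the median
        assert effect_code(x).sum() == pytest.approx(0.0)


class TestPriors:
    def test_g_prior_integrates_to_one(self):
        val, err = integrate.quad(lambda g: np.exp(g_logprior(g, 1.0)),
                                  0, np.inf, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_alpha_zero_is_conditional_mode(self, rng):
        design = center_covariates(rng.normal(size=(25, 2)))
        at_zero = regression_logprior(np.zeros(2), 1.3, 0.7, design)
        for _ in range(20):
            assert regression_logprior(rng.normal(size=2) * 0.5, 1.3, 0.7,
                                       design) < at_zero

    def test_doubling_g_determinant_scaling(self, rng):
        design = center_covariates(rng.normal(size=(25, 2)))
        lo = regression_logprior(np.zeros(2), 1.0, 0.7, design)
        hi = regression_logprior(np.zeros(2), 2.0, 0.7, design)
        assert lo - hi == pytest.approx(design.p / 2 * np.log(2))


def _hand_joint_logdensity(dataset, design, lat, cauchy_scale=1.0):
    """Term-by-term recomputation with explicit formulas only."""
    from cogreg.pvl import PVLParams, log_likelihood

    total = 0.0
    # natural-scale parameters via the probit link
    zp = lat.zp
    nat = stats.norm.cdf(zp) * np.array([1.0, 5.0, 1.0, 5.0])
    for i, pid in enumerate(dataset.participants):
        rec = dataset.trials[dataset.trials["participant"] == pid]
        total += log_likelihood(PVLParams(*nat[i]), rec)
    # hierarchy: z' ~ N(mu + x'alpha, sigma^2), manual Gaussian density
    for j in range(4):
        mean = lat.mu[j] + design.X @ lat.coef[j]
        r = zp[:, j] - mean
        total += float((-0.5 * np.log(2 * np.pi * lat.sigma2[j])
                        - r ** 2 / (2 * lat.sigma2[j])).sum())
    # priors: mu ~ N(0,1); sigma^2 ~ IG(2, 1/2); alpha | g; g ~ IG(1/2, s^2/2)
    for j in range(4):
        total += -0.5 * np.log(2 * np.pi) - lat.mu[j] ** 2 / 2
        a, b = 2.0, 0.5
        import math
        total += (a * np.log(b) - np.log(math.factorial(int(a) - 1))
                  - (a + 1) * np.log(lat.sigma2[j]) - b / lat.sigma2[j])
        cov = lat.g[j] * lat.sigma2[j] * np.linalg.inv(design.xtx_n)
        k = design.p
        total += float(-k / 2 * np.log(2 * np.pi)
                       - 0.5 * np.log(np.linalg.det(cov))
                       - 0.5 * lat.coef[j] @ np.linalg.solve(cov, lat.coef[j]))
        ag, bg = 0.5, cauchy_scale ** 2 / 2
        from scipy.special import gammaln
        total += (ag * np.log(bg) - gammaln(ag)
                  - (ag + 1) * np.log(lat.g[j]) - bg / lat.g[j])
    return total


class TestJointLogDensity:
    def _latents(self, rng, n, p=1):
        return Latents(
            zp=rng.normal(size=(n, 4)),
            mu=rng.normal(size=4),
            sigma2=rng.uniform(0.3, 1.5, size=4),
            coef=rng.normal(size=(4, p)) * 0.5,
            g=rng.uniform(0.5, 3.0, size=4),
        )

    def test_matches_hand_coded_oracle(self, two_participant_trials, rng):
        design = center_covariates(np.array([[0.3], [-0.8]]))
        lat = self._latents(rng, 2)
        spec = RegressionModelSpec()
        ours = joint_logdensity(spec, two_participant_trials, design, lat)
        theirs = _hand_joint_logdensity(two_participant_trials, design, lat)
        assert ours == pytest.approx(theirs, abs=1e-8)

    def test_no_data_reduces_to_hierarchy_plus_priors(self, rng):
        design = center_covariates(rng.normal(size=(5, 2)))
        lat = self._latents(rng, 5, p=2)
        spec = RegressionModelSpec()
        full = joint_logdensity(spec, None, design, lat)
        assert np.isfinite(full)

    def test_location_invariance_of_covariates(self, two_participant_trials,
                                               rng):
        raw = np.array([[0.3], [-0.8]])
        lat = self._latents(rng, 2)
        spec = RegressionModelSpec()
        a = joint_logdensity(spec, two_participant_trials,
                             center_covariates(raw), lat)
        b = joint_logdensity(spec, two_participant_trials,
                             center_covariates(raw + 7.0), lat)
        assert a == pytest.approx(b, abs=1e-10)

    def test_median_split_spec_mean_structure(self, two_participant_trials,
                                              rng):
        codes = np.array([[0.5, -0.5], [-0.5, 0.5]])
        lat = self._latents(rng, 2, p=2)
        lat.g = None
        spec = MedianSplitModelSpec()
        val = joint_logdensity(spec, two_participant_trials, None, lat,
                               effect_codes=codes)
        # manual recomputation of the hierarchy block
        from cogreg.pvl import PVLParams, log_likelihood
        nat = stats.norm.cdf(lat.zp) * np.array([1.0, 5.0, 1.0, 5.0])
        manual = 0.0
        for i, pid in enumerate(two_participant_trials.participants):
            rec = two_participant_trials.trials[
                two_participant_trials.trials["participant"] == pid]
            manual += log_likelihood(PVLParams(*nat[i]), rec)
        for j in range(4):
            sd = np.sqrt(lat.sigma2[j])
            mean = lat.mu[j] + (codes @ lat.coef[j]) * sd
            manual += stats.norm.logpdf(lat.zp[:, j], mean, sd).sum()
            manual += stats.norm.logpdf(lat.mu[j], 0, 1)
            manual += stats.invgamma.logpdf(lat.sigma2[j], a=2, scale=0.5)
            manual += stats.cauchy.logpdf(lat.coef[j]).sum()
        assert val == pytest.approx(manual, abs=1e-8)

    def test_regression_with_zero_alpha_equals_intercept_hierarchy(
            self, two_participant_trials, rng):
        # null nesting: alpha = 0 makes the regression mean structure
        # identical to the intercept-only hierarchy
        design = center_covariates(np.array([[0.3], [-0.8]]))
        lat = self._latents(rng, 2)
        lat.coef = np.zeros((4, 1))
        spec = RegressionModelSpec()
        full = joint_logdensity(spec, two_participant_trials, design, lat)
        # subtracting the alpha and g prior terms leaves the basic
        # hierarchy with inverse-gamma variance prior
        correction = 0.0
        for j in range(4):
            correction += regression_logprior(lat.coef[j], lat.g[j],
                                              lat.sigma2[j], design)
            correction += g_logprior(lat.g[j], 1.0)
        base = full - correction
        lat_b = Latents(zp=lat.zp, mu=lat.mu, sigma2=lat.sigma2)
        manual = joint_logdensity(BasicHierSpec(), two_participant_trials,
                                  None, lat_b)
        # swap the uniform-sigma prior for the inverse-gamma one
        for j in range(4):
            manual -= -np.log(1.5)
            manual += stats.invgamma.logpdf(lat.sigma2[j], a=2, scale=0.5)
        assert base == pytest.approx(manual, abs=1e-8)
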