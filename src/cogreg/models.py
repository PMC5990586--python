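"""Hierarchical model layers over probit-scale PVL-Delta parameters.

Each bounded model parameter z in {A, w, a, c} with upper bound U is mapped
to the real line as z' = Phi^{-1}(z / U). Three group-level structures are
provided for the per-participant z'_i:

* basic hierarchy:   z'_i ~ N(mu, sigma^2), sigma ~ U(0, 1.5)
* regression:        z'_i ~ N(mu + x_i' alpha, sigma^2) with the JZS
  mixture-of-g prior alpha | g ~ N(0, g sigma^2 (X'X/N)^{-1}),
  g ~ InvGamma(1/2, s^2/2)
* median split:      z'_i ~ N(mu + delta' d_i sigma, sigma^2) with effect
  codes d_ij = +/- 0.5 and independent delta_j ~ Cauchy(0, 1)

The regression and median-split variants share mu ~ N(0, 1) and
sigma^2 ~ InvGamma(2, 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .pvl import UPPER_BOUNDS, log_likelihood_matrix


class DesignError(ValueError):
    """Degenerate or inconsistent covariate design."""


def probit_transform(z, upper):
    """Map z in (0, upper) to the real line: z' = Phi^{-1}(z / upper)."""
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0) or np.any(z >= upper):
        raise ValueError(f"values must lie strictly inside (0, {upper})")
    out = stats.norm.ppf(z / upper)
    return float(out) if out.ndim == 0 else out


def inverse_probit(z_probit, upper):
    """Map a real z' back to the bounded scale: z = upper * Phi(z')."""
    out = upper * stats.norm.cdf(np.asarray(z_probit, dtype=float))
    return float(out) if np.ndim(out) == 0 else out


def natural_from_probit(zp: np.ndarray) -> np.ndarray:
    """(..., 4) probit-scale draws -> natural-scale (A, w, a, c)."""
    return stats.norm.cdf(zp) * UPPER_BOUNDS


@dataclass
class CovariateDesign:
    """Centered covariate design for N participants x P covariates.

    ``sd`` holds the denominator-N standard deviation of each centered
    column, so X'X / N equals the sample covariance exactly.
    """

    raw: np.ndarray
    names: list = field(default_factory=list)

    def __post_init__(self):
        self.raw = np.atleast_2d(np.asarray(self.raw, dtype=float))
        if self.raw.ndim != 2:
            raise DesignError("covariate matrix must be 2-D")
        n, p = self.raw.shape
        if n < 2:
            raise DesignError("need at least 2 participants")
        if not self.names:
            self.names = [f"x{j + 1}" for j in range(p)]
        self.X = self.raw - self.raw.mean(axis=0)
        self.sd = self.X.std(axis=0)  # denominator-N
        if np.any(self.sd <= 0):
            j = int(np.argmin(self.sd))
            raise DesignError(f"degenerate (constant) covariate: {self.names[j]}")
        self.xtx_n = self.X.T @ self.X / n

    @property
    def n(self) -> int:
        return self.raw.shape[0]

    @property
    def p(self) -> int:
        return self.raw.shape[1]


def center_covariates(raw, names=None) -> CovariateDesign:
    """Center columns of a raw covariate matrix (means subtracted)."""
    return CovariateDesign(np.asarray(raw, dtype=float), names=list(names or []))


def effect_code(raw) -> np.ndarray:
    """Median-split effect codes: +0.5 strictly above the column median,
    -0.5 otherwise."""
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    med = np.median(raw, axis=0)
    return np.where(raw > med, 0.5, -0.5)


# ---------------------------------------------------------------------------
# Model specifications

@dataclass
class BasicHierSpec:
    """Intercept-only hierarchy: mu ~ N(0,1), sigma ~ U(0, 1.5)."""

    sigma_upper: float = 1.5
    kind: str = "basic"


@dataclass
class RegressionModelSpec:
    """Regression hierarchy with the JZS mixture-of-g prior.

    ``cauchy_scale`` is the scale s of the implied Cauchy prior on the
    standardized effect sizes (interquartile range of plausible beta).
    """

    cauchy_scale: float = 1.0
    kind: str = "regression"


@dataclass
class MedianSplitModelSpec:
    """Median-split hierarchy with independent Cauchy(0, 1) effect sizes."""

    cauchy_scale: float = 1.0
    kind: str = "median_split"


# ---------------------------------------------------------------------------
# Log-prior building blocks

def g_logprior(g, s):
    """Log-density of g ~ InvGamma(shape 1/2, scale s^2/2)."""
    if g <= 0:
        return -np.inf
    return stats.invgamma.logpdf(g, a=0.5, scale=s**2 / 2.0)


def sigma2_logprior(sigma2, shape=2.0, scale=0.5):
    """Log-density of sigma^2 ~ InvGamma(shape 2, scale 1/2)."""
    if sigma2 <= 0:
        return -np.inf
    return stats.invgamma.logpdf(sigma2, a=shape, scale=scale)


def regression_logprior(alpha, g, sigma2, design: CovariateDesign):
    """Log-density of alpha | g ~ N(0, g sigma^2 (X'X/N)^{-1})."""
    alpha = np.asarray(alpha, dtype=float)
    cov = g * sigma2 * np.linalg.inv(design.xtx_n)
    try:
        return float(
            stats.multivariate_normal.logpdf(alpha, mean=np.zeros(design.p), cov=cov)
        )
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise DesignError("singular X'X in regression prior") from exc


# ---------------------------------------------------------------------------
# Joint log-density (reference implementation; the sampler uses conjugate
# conditional updates derived from the same factorization)

@dataclass
class Latents:
    """Full set of latent values for a joint-density evaluation.

    zp : (N, 4) probit-scale participant parameters
    mu, sigma2 : length-4 group-level intercepts and residual variances
    coef : (4, P) regression weights alpha (regression spec) or
           standardized differences delta (median-split spec); None for basic
    g : length-4 latent g scalars (regression spec only)
    """

    zp: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray
    coef: np.ndarray | None = None
    g: np.ndarray | None = None


def group_means(spec, latents: Latents, design: CovariateDesign | None,
                effect_codes: np.ndarray | None) -> np.ndarray:
    """(N, 4) matrix of group-level means for each participant parameter."""
    n = latents.zp.shape[0]
    mean = np.tile(latents.mu, (n, 1))
    if spec.kind == "regression":
        mean = mean + design.X @ latents.coef.T
    elif spec.kind == "median_split":
        sigma = np.sqrt(latents.sigma2)
        mean = mean + (effect_codes @ latents.coef.T) * sigma
    return mean


def joint_logdensity(spec, dataset, design, latents: Latents,
                     effect_codes=None) -> float:
    """Joint log-density: PVL-Delta likelihood + hierarchy + group priors.

    ``dataset`` may be None (or have zero trials) to evaluate the hierarchy
    and priors alone.
    """
    zp = np.asarray(latents.zp, dtype=float)
    n = zp.shape[0]
    if zp.shape[1] != 4:
        raise ValueError("zp must be (N, 4)")
    total = 0.0

    # (i) choice likelihood at natural-scale parameters
    if dataset is not None:
        choices, nets = dataset.to_arrays()
        if choices.shape[0] != n:
            raise ValueError("participant count mismatch between data and latents")
        nat = natural_from_probit(zp)
        total += float(
            log_likelihood_matrix(
                nat[:, 0], nat[:, 1], nat[:, 2], nat[:, 3], choices, nets
            ).sum()
        )

    # (ii) hierarchy: z'_i ~ N(mean_i, sigma^2)
    mean = group_means(spec, latents, design, effect_codes)
    sd = np.sqrt(latents.sigma2)
    total += float(stats.norm.logpdf(zp, loc=mean, scale=sd).sum())

    # (iii) group-level priors
    total += float(stats.norm.logpdf(latents.mu, 0.0, 1.0).sum())
    if spec.kind == "basic":
        for s2 in latents.sigma2:
            sig = np.sqrt(s2)
            if not 0 < sig < spec.sigma_upper:
                return -np.inf
            total += -np.log(spec.sigma_upper)
    else:
        for s2 in latents.sigma2:
            total += sigma2_logprior(s2)
    if spec.kind == "regression":
        for j in range(4):
            total += regression_logprior(
                latents.coef[j], latents.g[j], latents.sigma2[j], design
            )
            total += g_logprior(latents.g[j], spec.cauchy_scale)
    elif spec.kind == "median_split":
        total += float(stats.cauchy.logpdf(latents.coef, 0.0, 1.0).sum())
    return total
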