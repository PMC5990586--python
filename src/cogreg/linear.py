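"""Plain JZS linear regression: conjugate Gibbs reference samplers.

These samplers cover the linear-model reduction of the hierarchy — the
criterion variable observed directly, no cognitive likelihood — where every
conditional is available in closed form. They serve two purposes: the
Savage-Dickey Bayes factor computed from their draws can be checked against
the analytic one-dimensional-integral Bayes factor
(:func:`cogreg.bayesfactor.jzs_linear_bf_oracle`), and with proper priors
they support simulation-based-calibration checks of the regression layer.
"""

from __future__ import annotations

import numpy as np

from .models import CovariateDesign


def _rinvgamma(rng, shape, scale):
    return scale / rng.gamma(shape, 1.0)


def gibbs_jzs_linear(y, X, s=1.0, n_draws=4000, n_burnin=500, seed=None,
                     priors="jeffreys", fixed_g=None):
    """Gibbs draws for y ~ N(mu + X alpha, sigma^2) under the JZS prior.

    The g-prior uses the X'X/N convention:
    alpha | g ~ N(0, g sigma^2 (X'X/N)^{-1}), g ~ InvGamma(1/2, s^2/2).

    Parameters
    ----------
    priors : str
        "jeffreys": p(mu, sigma^2) propto 1/sigma^2 (the default Bayes
        factor setting). "hierarchical": mu ~ N(0, 1),
        sigma^2 ~ InvGamma(2, 1/2) (the priors of the cognitive hierarchy's
        group level; proper, hence usable for calibration checks).
    fixed_g : float or None
        If given, g is held at this value instead of being resampled
        (conjugate sub-case used by the shrinkage closed-form check).

    Returns a dict of pooled draws: mu, sigma2, alpha (n, P), g, and the
    standardized effect sizes beta (n, P) with beta_j = alpha_j s_j / sigma.
    """
    if priors not in ("jeffreys", "hierarchical"):
        raise ValueError("priors must be 'jeffreys' or 'hierarchical'")
    y = np.asarray(y, dtype=float).ravel()
    design = X if isinstance(X, CovariateDesign) else CovariateDesign(np.asarray(X))
    n, p = design.n, design.p
    if y.size != n:
        raise ValueError("y length must match design rows")
    Xc = design.X
    xtx = Xc.T @ Xc
    xtx_inv = np.linalg.inv(xtx)
    chol = np.linalg.cholesky(xtx_inv)
    xtx_n = design.xtx_n

    rng = np.random.default_rng(seed)
    mu = float(y.mean())
    alpha = np.zeros(p)
    sigma2 = float(y.var() + 1e-12)
    g = 1.0 if fixed_g is None else float(fixed_g)

    out = {k: [] for k in ("mu", "sigma2", "alpha", "g")}
    for it in range(n_draws + n_burnin):
        # mu | .
        r = y - Xc @ alpha
        if priors == "jeffreys":
            mu = r.mean() + rng.standard_normal() * np.sqrt(sigma2 / n)
        else:
            prec = n / sigma2 + 1.0
            mu = r.sum() / sigma2 / prec + rng.standard_normal() / np.sqrt(prec)
        # alpha | . (shrinkage on OLS; X'X/N convention -> gN/(gN+1))
        gn = g * n
        shrink = gn / (gn + 1.0)
        r = y - mu
        a_mean = shrink * (xtx_inv @ (Xc.T @ r))
        alpha = a_mean + np.sqrt(sigma2 * shrink) * (chol @ rng.standard_normal(p))
        # sigma^2 | .
        resid = r - Xc @ alpha
        quad = alpha @ xtx_n @ alpha
        base_shape, base_scale = ((0.0, 0.0) if priors == "jeffreys"
                                  else (2.0, 0.5))
        shape = base_shape + (n + p) / 2.0
        scale = base_scale + resid @ resid / 2.0 + quad / (2.0 * g)
        sigma2 = _rinvgamma(rng, shape, scale)
        # g | .
        if fixed_g is None:
            g = _rinvgamma(rng, 0.5 + p / 2.0,
                           s * s / 2.0 + quad / (2.0 * sigma2))
        if it >= n_burnin:
            out["mu"].append(mu)
            out["sigma2"].append(sigma2)
            out["alpha"].append(alpha.copy())
            out["g"].append(g)
    out = {k: np.asarray(v) for k, v in out.items()}
    out["beta"] = out["alpha"] * design.sd / np.sqrt(out["sigma2"])[:, None]
    return out


def sample_regression_layer_prior(design, s=1.0, rng=None):
    """One draw of (mu, sigma2, alpha, g) from the proper group-level prior.

    Matches the "hierarchical" prior setting of :func:`gibbs_jzs_linear`.
    """
    rng = np.random.default_rng(rng)
    mu = rng.standard_normal()
    sigma2 = _rinvgamma(rng, 2.0, 0.5)
    g = _rinvgamma(rng, 0.5, s * s / 2.0)
    cov = g * sigma2 * np.linalg.inv(design.xtx_n)
    alpha = np.linalg.cholesky(cov) @ rng.standard_normal(design.p)
    return {"mu": mu, "sigma2": sigma2, "alpha": alpha, "g": g}
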