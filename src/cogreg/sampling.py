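"""Posterior sampling for the hierarchical PVL-Delta model variants.

The sampler is Metropolis-within-Gibbs. Given the per-participant
probit-scale parameters z', the group-level regression layer is a Gaussian
linear model, so mu, alpha, sigma^2 and g all have closed-form conditional
distributions (normal / multivariate normal / inverse-gamma) and are updated
by exact Gibbs draws. The participant-level z'_i blocks are updated with an
adaptive random-walk Metropolis step on the full 4-vector, with per-
participant proposal scales tuned toward a target acceptance rate during
burn-in and frozen afterwards. The median-split model's delta and sigma^2
conditionals are non-conjugate (sigma enters the mean structure) and use
random-walk Metropolis as well.

Any sampler producing draws from the same joint posterior is a conforming
replacement; correctness here is established by the conjugate closed-form,
prior-only, simulation-based-calibration and analytic-oracle checks in the
test suite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import CovariateDesign, Latents
from .pvl import PARAM_NAMES


#: acceptance target of the Gibbs backend's random-walk blocks
_RW_TARGET = 0.25


class InitializationError(RuntimeError):
    """Non-finite joint log-density at the initial state."""


class InsufficientChainsError(ValueError):
    """Convergence diagnostics require at least two chains."""


@dataclass
class SamplerConfig:
    """MCMC run settings.

    Defaults mirror the simulation protocol of the original study
    (2 chains x 45,000 iterations, 5,000 burn-in, thin 5 -> 8,000 retained
    draws per chain). Use :meth:`test_scale` for a desk-scale configuration.
    """

    n_chains: int = 2
    n_iterations: int = 45_000
    n_burnin: int = 5_000
    thin: int = 5
    seed: int | None = None
    #: NUTS target acceptance statistic (the Gibbs backend tunes its
    #: random-walk blocks to ~0.25 internally)
    target_accept: float = 0.8
    #: NUTS maximum doubling depth (2^depth leapfrog steps)
    max_treedepth: int = 8
    #: Gibbs backend: interleaved (participant-block, translation) update
    #: rounds per sweep
    mixing_repeats: int = 3
    #: Gibbs backend: group-level translation moves per round
    translation_repeats: int = 2

    def __post_init__(self):
        if self.n_burnin >= self.n_iterations:
            raise ValueError("n_burnin must be < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thin

    @classmethod
    def test_scale(cls, seed=None, **kw):
        """Short-chain configuration for desk-scale runs."""
        kw.setdefault("n_iterations", 3000)
        kw.setdefault("n_burnin", 1000)
        kw.setdefault("thin", 1)
        return cls(seed=seed, **kw)


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, indexed (chain, iteration, ...).

    ``draws`` maps quantity names ("mu", "sigma2", "coef", "g", optionally
    "zp") to arrays whose first two axes are chain and retained iteration.
    """

    draws: dict
    config: SamplerConfig
    model_kind: str
    param_names: tuple = PARAM_NAMES
    covariate_names: list = field(default_factory=list)
    accept_rates: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, arr in self.draws.items():
            if arr.shape[0] != self.config.n_chains:
                raise ValueError(f"{name}: chain axis mismatch")
            if arr.shape[1] != self.config.n_retained:
                raise ValueError(f"{name}: retained-draw count mismatch")

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled across chains (first two axes merged)."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long CSV-ready frame: quantity, chain, iteration, value."""
        rows = []
        for name, arr in self.draws.items():
            if name == "zp":
                continue
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            for k in range(flat.shape[2]):
                sub = np.unravel_index(k, arr.shape[2:]) if arr.ndim > 2 else ()
                label = name + "".join(f"[{i}]" for i in sub)
                for ch in range(flat.shape[0]):
                    rows.append(pd.DataFrame({
                        "quantity": label,
                        "chain": ch,
                        "iteration": np.arange(flat.shape[1]),
                        "value": flat[ch, :, k],
                    }))
        return pd.concat(rows, ignore_index=True)

    def save(self, path) -> None:
        """Binary cache of the draws (NumPy .npz)."""
        meta = {f"draw_{k}": v for k, v in self.draws.items()}
        np.savez_compressed(
            path, model_kind=self.model_kind,
            covariate_names=np.array(self.covariate_names, dtype=object),
            config=np.array([dataclasses.asdict(self.config)], dtype=object),
            **meta,
        )

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        with np.load(path, allow_pickle=True) as f:
            draws = {k[5:]: f[k] for k in f.files if k.startswith("draw_")}
            cfg = SamplerConfig(**f["config"][0])
            return cls(
                draws=draws, config=cfg, model_kind=str(f["model_kind"]),
                covariate_names=list(f["covariate_names"]),
            )


def initialize_latents(spec, n_participants: int, p_covariates: int, rng,
                       design: CovariateDesign | None = None,
                       effect_codes=None) -> Latents:
    """Draw initial values: mu ~ N(0,1), sigma ~ Exp(1), coefficients
    ~ N(0, 2^2), g = 1; z' starts at its implied conditional mean."""
    rng = np.random.default_rng(rng)
    mu = rng.standard_normal(4)
    sigma2 = rng.exponential(1.0, size=4) ** 2
    coef = None
    g = None
    if spec.kind in ("regression", "median_split"):
        coef = rng.normal(0.0, 2.0, size=(4, p_covariates))
    if spec.kind == "regression":
        g = np.ones(4)
    zp = np.tile(mu, (n_participants, 1))
    if spec.kind == "regression":
        zp = zp + design.X @ coef.T
    elif spec.kind == "median_split":
        zp = zp + (effect_codes @ coef.T) * np.sqrt(sigma2)
    return Latents(zp=zp, mu=mu, sigma2=sigma2, coef=coef, g=g)


def _rinvgamma(rng, shape, scale):
    """Inverse-gamma draw via 1 / Gamma."""
    return scale / rng.gamma(shape, 1.0)


def _cauchy_logpdf(x):
    return -np.log(np.pi * (1.0 + x * x))


class _AdaptiveRW:
    """Adaptive-covariance random-walk proposals for B independent blocks.

    Maintains a Welford running covariance of each block's draws during
    burn-in and proposes increments from N(0, s_b^2 * Cov_b) with the
    per-block scalar s_b tuned toward a target acceptance rate. The PVL
    posterior has a pronounced ridge (utility scale trades off against
    softmax sensitivity), so correlated proposals are essential for mixing.
    Adaptation is frozen after burn-in.
    """

    def __init__(self, n_blocks, dim, init_step=0.25):
        self.n = n_blocks
        self.dim = dim
        self.mean = np.zeros((n_blocks, dim))
        self.m2 = np.zeros((n_blocks, dim, dim))
        self.count = 0
        self.log_scale = np.full(n_blocks, np.log(init_step))
        self.chol = np.tile(np.eye(dim), (n_blocks, 1, 1))
        self.acc = np.zeros(n_blocks)
        self.nprop = 0

    def record(self, x):
        """Welford covariance update with one (B, dim) state per block."""
        self.count += 1
        delta = x - self.mean
        self.mean += delta / self.count
        self.m2 += np.einsum("bi,bj->bij", delta, x - self.mean)

    def refresh(self):
        """Rebuild proposal cholesky from the current window, then restart
        accumulation so early-transient variance is forgotten."""
        if self.count < 2 * self.dim + 10:
            return
        cov = self.m2 / (self.count - 1)
        # ridge floor keeps stuck blocks (near-zero windowed variance)
        # able to move again
        diag_mean = np.trace(cov, axis1=-2, axis2=-1) / self.dim
        ridge = np.maximum(1e-4, 0.01 * diag_mean)
        cov += ridge[..., None, None] * np.eye(self.dim)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:  # pragma: no cover
            return
        # fold the d-dimensional optimal-scaling factor into the proposal
        self.chol = chol * (2.38 / np.sqrt(self.dim))
        self.log_scale[:] = 0.0
        self.mean[:] = 0.0
        self.m2[:] = 0.0
        self.count = 0

    def propose(self, x, rng):
        eps = rng.standard_normal((self.n, self.dim))
        step = np.einsum("bij,bj->bi", self.chol, eps)
        return x + np.exp(self.log_scale)[:, None] * step

    def tally(self, accepted):
        self.acc += accepted
        self.nprop += 1

    def adapt(self, target):
        if self.nprop == 0:
            return
        rate = self.acc / self.nprop
        self.log_scale += np.clip(rate - target, -0.5, 0.5)
        self.log_scale = np.clip(self.log_scale, np.log(1e-4), np.log(10.0))
        self.acc[:] = 0.0
        self.nprop = 0


def _run_chain(spec, choices, nets, design, effect_codes, config, rng,
               store_zp, n_participants=None):
    """One Metropolis-within-Gibbs chain (see module docstring).

    Group-level conditionals are exact draws, vectorized across the four
    model parameters; participant blocks and the joint translation move are
    adaptive Metropolis with one likelihood evaluation each.
    """
    from scipy.special import ndtr

    from .pvl import _ll_kernel

    if choices is not None:
        n = choices.shape[0]
    elif design is not None:
        n = design.n
    elif effect_codes is not None:
        n = effect_codes.shape[0]
    else:
        n = n_participants or 10
    p = design.p if design is not None else (
        effect_codes.shape[1] if effect_codes is not None else 0)
    lat = initialize_latents(spec, n, p, rng, design=design,
                             effect_codes=effect_codes)
    has_data = choices is not None and choices.size > 0

    if has_data:
        choices = np.ascontiguousarray(choices, dtype=np.int64)
        nets = np.ascontiguousarray(nets, dtype=np.float64)

    def loglik_of(zp):
        nat = ndtr(zp)
        return _ll_kernel(
            np.ascontiguousarray(nat[:, 0]),
            np.ascontiguousarray(5.0 * nat[:, 1]),
            np.ascontiguousarray(nat[:, 2]),
            np.ascontiguousarray(np.power(3.0, 5.0 * nat[:, 3]) - 1.0),
            choices, nets)

    if has_data:
        loglik = loglik_of(lat.zp)
        if not np.all(np.isfinite(loglik)):
            raise InitializationError(
                "non-finite likelihood at initial state; "
                f"offending participants: {np.flatnonzero(~np.isfinite(loglik))}"
            )
    else:
        loglik = np.zeros(n)

    kept = {"mu": [], "sigma2": []}
    if spec.kind in ("regression", "median_split"):
        kept["coef"] = []
    if spec.kind == "regression":
        kept["g"] = []
    if store_zp:
        kept["zp"] = []

    # adaptive proposal machinery
    zp_rw = _AdaptiveRW(n, 4, init_step=0.25)
    tr_dim = 4 + 4 * p if spec.kind in ("regression", "median_split") else 4
    tr_rw = _AdaptiveRW(1, tr_dim, init_step=0.1)
    ms_step = np.full(4, np.log(0.3))
    ms_acc = np.zeros(4)
    ms_prop = 0
    sig_step = 0.4

    if design is not None:
        X = design.X
        xtx_n = design.xtx_n
        xtx_inv = np.linalg.inv(X.T @ X)
        chol_xtx_inv = np.linalg.cholesky(xtx_inv)

    s2_scale = spec.cauchy_scale ** 2 / 2.0 if spec.kind == "regression" else None
    log_2pi = np.log(2.0 * np.pi)

    def group_mean():
        mean = np.tile(lat.mu, (n, 1))
        if spec.kind == "regression":
            mean = mean + X @ lat.coef.T
        elif spec.kind == "median_split":
            mean = mean + (effect_codes @ lat.coef.T) * np.sqrt(lat.sigma2)
        return mean

    def hier_rows(zp, mean, s2):
        return (-0.5 * ((zp - mean) ** 2 / s2)
                - 0.5 * np.log(s2) - 0.5 * log_2pi).sum(axis=1)

    for it in range(config.n_iterations):
        in_burnin = it < config.n_burnin

        if not has_data:
            # no-likelihood limit: z' is conjugate given the hierarchy
            lat.zp = group_mean() + np.sqrt(lat.sigma2) * \
                rng.standard_normal((n, 4))

        for _round in range(config.mixing_repeats if has_data else 0):
            # --- participant-level z' update (adaptive RW-MH, 4-blocks) ---
            mean = group_mean()
            prop = zp_rw.propose(lat.zp, rng)
            loglik_prop = loglik_of(prop)
            logr = (loglik_prop - loglik
                    + hier_rows(prop, mean, lat.sigma2)
                    - hier_rows(lat.zp, mean, lat.sigma2))
            accept = np.log(rng.random(n)) < logr
            lat.zp[accept] = prop[accept]
            loglik[accept] = loglik_prop[accept]
            zp_rw.tally(accept)
            if in_burnin:
                zp_rw.record(lat.zp)

            # --- joint translation: shift (mu, coef) together with z' ---
            # Group mean and every z'_i move in lockstep, so the hierarchy
            # term cancels and only the likelihood and the (mu, coef)
            # priors enter the ratio; this decouples group-level mixing
            # from the participant random walk.
            for _ in range(config.translation_repeats):
                cur_vec = (np.concatenate([lat.mu, lat.coef.ravel()])
                           if lat.coef is not None else lat.mu.copy())
                new_vec = tr_rw.propose(cur_vec[None, :], rng)[0]
                dvec = new_vec - cur_vec
                dmu = dvec[:4]
                shift = np.tile(dmu, (n, 1))
                dcoef = None
                if spec.kind == "regression":
                    dcoef = dvec[4:].reshape(4, p)
                    shift = shift + X @ dcoef.T
                elif spec.kind == "median_split":
                    dcoef = dvec[4:].reshape(4, p)
                    shift = shift + (effect_codes @ dcoef.T) * \
                        np.sqrt(lat.sigma2)
                zp_prop = lat.zp + shift
                loglik_prop = loglik_of(zp_prop)
                mu_prop = lat.mu + dmu
                logr = (loglik_prop.sum() - loglik.sum()
                        - 0.5 * (mu_prop @ mu_prop - lat.mu @ lat.mu))
                if spec.kind == "regression":
                    coef_prop = lat.coef + dcoef
                    q_new = np.einsum("jp,pq,jq->j", coef_prop, xtx_n,
                                      coef_prop)
                    q_old = np.einsum("jp,pq,jq->j", lat.coef, xtx_n,
                                      lat.coef)
                    logr -= (0.5 * (q_new - q_old)
                             / (lat.g * lat.sigma2)).sum()
                elif spec.kind == "median_split":
                    coef_prop = lat.coef + dcoef
                    logr += (_cauchy_logpdf(coef_prop).sum()
                             - _cauchy_logpdf(lat.coef).sum())
                acc = np.log(rng.random()) < logr
                if acc:
                    lat.zp = zp_prop
                    loglik = loglik_prop
                    lat.mu = mu_prop
                    if dcoef is not None:
                        lat.coef = coef_prop
                tr_rw.tally(np.array([acc]))
                if in_burnin:
                    state = (np.concatenate([lat.mu, lat.coef.ravel()])
                             if lat.coef is not None else lat.mu.copy())
                    tr_rw.record(state[None, :])

        if has_data and in_burnin and (it + 1) % 50 == 0:
            zp_rw.adapt(_RW_TARGET)
            tr_rw.adapt(_RW_TARGET)
            if (it + 1) % 200 == 0:
                zp_rw.refresh()
                tr_rw.refresh()

        # --- group-level conjugate updates, vectorized over parameters ---
        s2 = lat.sigma2
        if spec.kind == "regression":
            # mu | . : conjugate normal, prior N(0, 1)
            resid_a = lat.zp - X @ lat.coef.T
            prec = n / s2 + 1.0
            lat.mu = (resid_a.sum(axis=0) / s2 / prec
                      + rng.standard_normal(4) / np.sqrt(prec))
            # alpha | . : conjugate MVN; shrinkage (gN)/(gN+1) on OLS
            gn = lat.g * n
            shrink = gn / (gn + 1.0)
            r = lat.zp - lat.mu
            a_mean = shrink * (xtx_inv @ (X.T @ r))  # (P, 4)
            lat.coef = (a_mean + np.sqrt(s2 * shrink)
                        * (chol_xtx_inv @ rng.standard_normal((p, 4)))).T
            # sigma^2 | . : conjugate IG (alpha prior contributes too)
            resid = r - X @ lat.coef.T
            quad = np.einsum("jp,pq,jq->j", lat.coef, xtx_n, lat.coef)
            shape = 2.0 + n / 2.0 + p / 2.0
            scale = 0.5 + (resid * resid).sum(axis=0) / 2.0 + quad / (2 * lat.g)
            lat.sigma2 = scale / rng.gamma(shape, 1.0, size=4)
            # g | . : conjugate IG
            g_scale = s2_scale + quad / (2.0 * lat.sigma2)
            lat.g = g_scale / rng.gamma(0.5 + p / 2.0, 1.0, size=4)
        elif spec.kind == "median_split":
            sig = np.sqrt(s2)
            dmean = effect_codes @ lat.coef.T  # (n, 4)
            # mu | . : conjugate normal
            prec = n / s2 + 1.0
            lat.mu = ((lat.zp - sig * dmean).sum(axis=0) / s2 / prec
                      + rng.standard_normal(4) / np.sqrt(prec))
            # delta | . : RW-MH per parameter, vectorized over the four
            prop_c = lat.coef + np.exp(ms_step)[:, None] * \
                rng.standard_normal((4, p))
            r_cur = lat.zp - lat.mu - sig * dmean
            r_new = lat.zp - lat.mu - sig * (effect_codes @ prop_c.T)
            logr = (-0.5 * ((r_new * r_new).sum(axis=0)
                            - (r_cur * r_cur).sum(axis=0)) / s2
                    + _cauchy_logpdf(prop_c).sum(axis=1)
                    - _cauchy_logpdf(lat.coef).sum(axis=1))
            acc = np.log(rng.random(4)) < logr
            lat.coef[acc] = prop_c[acc]
            ms_acc += acc
            ms_prop += 1
            # sigma^2 | . : RW-MH on log sigma^2 (enters the mean too)
            dmean = effect_codes @ lat.coef.T
            u = np.log(s2)
            u_prop = u + sig_step * rng.standard_normal(4)
            s2_prop = np.exp(u_prop)
            r_cur = lat.zp - lat.mu - np.sqrt(s2) * dmean
            r_new = lat.zp - lat.mu - np.sqrt(s2_prop) * dmean
            # IG(2, 1/2) prior plus log-scale Jacobian
            logr = (-0.5 * ((r_new * r_new).sum(axis=0) / s2_prop
                            - (r_cur * r_cur).sum(axis=0) / s2)
                    - 0.5 * n * (u_prop - u)
                    - 2.0 * (u_prop - u) - 0.5 * (1 / s2_prop - 1 / s2))
            acc = np.log(rng.random(4)) < logr
            lat.sigma2[acc] = s2_prop[acc]
            if in_burnin and (it + 1) % 50 == 0:
                rate = ms_acc / ms_prop
                ms_step += np.clip(rate - 0.35, -0.5, 0.5)
                ms_acc[:] = 0
                ms_prop = 0
        else:  # basic hierarchy
            prec = n / s2 + 1.0
            lat.mu = (lat.zp.sum(axis=0) / s2 / prec
                      + rng.standard_normal(4) / np.sqrt(prec))
            # sigma ~ U(0, upper) => p(sigma^2) propto (sigma^2)^{-1/2};
            # conditional is a truncated inverse-gamma
            ssr = ((lat.zp - lat.mu) ** 2).sum(axis=0)
            dist = stats.invgamma(a=(n - 1) / 2.0, scale=ssr / 2.0)
            hi = np.maximum(dist.cdf(spec.sigma_upper ** 2), 1e-300)
            lat.sigma2 = np.clip(dist.ppf(rng.uniform(0, 1, 4) * hi),
                                 1e-12, spec.sigma_upper ** 2)

        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
            kept["mu"].append(lat.mu.copy())
            kept["sigma2"].append(lat.sigma2.copy())
            if "coef" in kept:
                kept["coef"].append(lat.coef.copy())
            if "g" in kept:
                kept["g"].append(lat.g.copy())
            if store_zp:
                kept["zp"].append(lat.zp.copy())

    out = {k: np.asarray(v) for k, v in kept.items()}
    out["_accept_zp"] = (zp_rw.acc / max(zp_rw.nprop, 1)) if has_data else np.ones(n)
    return out



def _run_hmc(spec, choices, nets, design, effect_codes, config, rng,
             store_zp, n_participants=None):
    from .hmc import _Potential, run_nuts_chain

    pot = _Potential(spec, choices, nets, design=design,
                     effect_codes=effect_codes)
    n = pot.n
    p = pot.p
    lat = initialize_latents(spec, n, p, rng, design=design,
                             effect_codes=effect_codes)
    q0 = pot.pack(lat)
    try:
        qs, stats = run_nuts_chain(
            pot, q0, config, rng, max_depth=config.max_treedepth,
            target_accept=config.target_accept)
    except RuntimeError as exc:
        raise InitializationError(str(exc)) from exc
    out = {"mu": [], "sigma2": []}
    if spec.kind in ("regression", "median_split"):
        out["coef"] = []
    if spec.kind == "regression":
        out["g"] = []
    if store_zp:
        out["zp"] = []
    for q in qs:
        zp, mu, coef, sigma2, g = pot.unpack(q)
        out["mu"].append(mu)
        out["sigma2"].append(sigma2)
        if "coef" in out:
            out["coef"].append(coef)
        if "g" in out:
            out["g"].append(g)
        if store_zp:
            out["zp"].append(zp)
    out = {k: np.asarray(v) for k, v in out.items()}
    out["_accept_zp"] = np.full(n, stats["accept"])
    out["_stats"] = stats
    return out


def sample_posterior(spec, dataset, design, config: SamplerConfig,
                     effect_codes=None, store_zp=False,
                     n_participants=None, method="hmc") -> PosteriorSamples:
    """Draw from the joint posterior of a hierarchical model variant.

    Parameters
    ----------
    spec : BasicHierSpec | RegressionModelSpec | MedianSplitModelSpec
    dataset : IGTDataset or None
        None (or empty) samples the hierarchy-plus-prior alone.
    design : CovariateDesign or None
        Centered covariates (regression spec).
    effect_codes : ndarray or None
        (N, P) matrix of +/-0.5 codes (median-split spec).
    method : str
        "hmc" (default): gradient-based joint updates of all continuous
        latents. "gibbs": Metropolis-within-Gibbs with conjugate group
        updates; retained as an independent cross-check of the posterior.
    """
    if spec.kind == "regression" and design is None:
        raise ValueError("regression spec requires a covariate design")
    if spec.kind == "median_split" and effect_codes is None:
        raise ValueError("median-split spec requires effect codes")
    if method not in ("hmc", "gibbs"):
        raise ValueError("method must be 'hmc' or 'gibbs'")
    if dataset is not None:
        choices, nets = dataset.to_arrays()
    else:
        choices = nets = None
    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.n_chains)
    runner = _run_hmc if method == "hmc" else _run_chain
    chains = []
    for cs in chain_seeds:
        rng = np.random.default_rng(cs)
        chains.append(runner(spec, choices, nets, design, effect_codes,
                             config, rng, store_zp,
                             n_participants=n_participants))
    draws = {
        k: np.stack([c[k] for c in chains])
        for k in chains[0] if not k.startswith("_")
    }
    accept = {"zp": np.stack([c["_accept_zp"] for c in chains])}
    cov_names = design.names if design is not None else (
        [f"x{j+1}" for j in range(effect_codes.shape[1])]
        if effect_codes is not None else [])
    return PosteriorSamples(
        draws=draws, config=config, model_kind=spec.kind,
        covariate_names=cov_names, accept_rates=accept,
    )
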