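"""Synthetic-data generation and the dichotomization-bias study harness.

The generator emulates the study's generative process: per-participant
covariates are drawn from a bivariate normal with unit variances and
correlation rho (0 or 0.7); probit-scale PVL-Delta parameters are linear in
the covariates with the published generating weights; and each synthetic
participant plays T trials of the traditional IGT payoff schedule as a
PVL-Delta softmax agent. Each generated dataset is analyzed twice — with
the regression extension and with the median-split model — and the study
summary is the per-cell median/mean difference in log Bayes factors
log(BF10_RG) - log(BF10_MS).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .estimators import PVLDeltaMedianSplit, PVLDeltaRegression
from .models import natural_from_probit
from .pvl import PARAM_NAMES, PVLParams, simulate_agent
from .task import IGTDataset, build_traditional_schedule

#: Generating values per probit-scale model parameter:
#: (alpha_1, alpha_2, mu, sigma). The A' and w' rows carry the adjusted
#: effect sizes (1 / -0.9) and residual SDs used to generate synthetic data;
#: a' and c' keep the values estimated from the original empirical fit.
GENERATING_VALUES = {
    "A": (1.0, 0.0, 0.24, 1.06),
    "w": (0.0, -0.9, 0.38, 0.91),
    "a": (-0.08, 0.24, 0.30, 1.58),
    "c": (-0.02, -0.05, 1.34, 0.46),
}


@dataclass
class ScenarioConfig:
    """One simulation scenario.

    ``sigma_as`` selects whether the fourth generating value is read as a
    residual standard deviation ("sd", default) or a variance ("var").
    """

    n_participants: int = 150
    n_trials: int = 200
    rho: float = 0.0
    n_datasets: int = 50
    base_seed: int = 0
    cauchy_scale: float = 1.0
    generating_values: dict = field(default_factory=lambda: dict(GENERATING_VALUES))
    sigma_as: str = "sd"

    def __post_init__(self):
        if not -1.0 < self.rho < 1.0:
            raise ValueError("covariate correlation must satisfy |rho| < 1")
        if self.sigma_as not in ("sd", "var"):
            raise ValueError("sigma_as must be 'sd' or 'var'")

    def dataset_seed(self, index: int) -> np.random.SeedSequence:
        """Deterministic per-dataset seed: SeedSequence(base_seed, index)."""
        return np.random.SeedSequence((self.base_seed, index))


def generate_covariates(n: int, rho: float, rng) -> np.ndarray:
    """N draws from MVN(0, Sigma), unit variances, correlation rho."""
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be < 1")
    rng = np.random.default_rng(rng)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return rng.multivariate_normal(np.zeros(2), cov, size=n,
                                   method="cholesky")


def generate_participant_parameters(covariates, generating_values, rng,
                                    sigma_as="sd"):
    """Draw per-participant probit- and natural-scale PVL-Delta parameters.

    z'_i ~ N(mu + x_i' alpha, sigma^2) per model parameter; natural scale
    via the bound-scaled inverse probit. Returns (zp, natural), both (N, 4)
    in (A, w, a, c) order.
    """
    rng = np.random.default_rng(rng)
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    n = x.shape[0]
    zp = np.empty((n, 4))
    for j, name in enumerate(PARAM_NAMES):
        a1, a2, mu, sig = generating_values[name]
        sd = np.sqrt(sig) if sigma_as == "var" else sig
        mean = mu + x @ np.array([a1, a2])
        zp[:, j] = mean + sd * rng.standard_normal(n)
    return zp, natural_from_probit(zp)


def generate_dataset(config: ScenarioConfig, index: int):
    """Generate one full synthetic dataset.

    Returns ``(dataset, covariate_frame, truth)`` where ``truth`` records
    the generating parameters and seeds for recovery checks.
    """
    ss = config.dataset_seed(index)
    rngs = [np.random.default_rng(s) for s in ss.spawn(3)]
    x = generate_covariates(config.n_participants, config.rho, rngs[0])
    zp, nat = generate_participant_parameters(
        x, config.generating_values, rngs[1], sigma_as=config.sigma_as)
    schedule = build_traditional_schedule(
        max_draws=int(np.ceil(config.n_trials / 10.0)) * 10)
    agent_rng = rngs[2]
    frames = []
    for i in range(config.n_participants):
        params = PVLParams(*nat[i])
        df = simulate_agent(params, schedule, config.n_trials, agent_rng)
        df.insert(0, "participant", i + 1)
        frames.append(df)
    dataset = IGTDataset(pd.concat(frames, ignore_index=True))
    cov_frame = pd.DataFrame(x, columns=["x1", "x2"])
    cov_frame.insert(0, "participant", np.arange(1, config.n_participants + 1))
    truth = {
        "config": asdict(config), "dataset_index": index,
        "zp": zp, "natural": nat, "covariates": x,
    }
    return dataset, cov_frame, truth


def run_dataset(dataset, covariates, analysis: str, sampler_kwargs=None,
                cauchy_scale: float = 1.0, seed=None,
                collect_effect_draws=False):
    """Fit one analysis to one dataset and return its Bayes-factor table.

    ``analysis`` is "regression" or "median_split". The returned table has
    one row per (model parameter, covariate): 4 x P rows. When
    ``collect_effect_draws`` is set, the per-cell posterior effect-size
    draws are returned alongside for quantile averaging.
    """
    sampler_kwargs = dict(sampler_kwargs or {})
    sampler_kwargs.setdefault("seed", seed)
    cls = {"regression": PVLDeltaRegression,
           "median_split": PVLDeltaMedianSplit}.get(analysis)
    if cls is None:
        raise ValueError(f"unknown analysis: {analysis!r}")
    est = cls(cauchy_scale=cauchy_scale, **sampler_kwargs)
    est.fit(covariates, dataset)
    table = est.bayes_factors()
    table["max_rhat"] = est.max_rhat_
    table["converged"] = est.converged_
    # per-cell coefficient posterior summaries (alpha or delta), used by
    # ground-truth recovery checks
    coef = est.posterior_.pooled("coef")
    lo = np.percentile(coef, 2.5, axis=0)
    hi = np.percentile(coef, 97.5, axis=0)
    mean = coef.mean(axis=0)
    table["coef_mean"] = mean.ravel()
    table["coef_q025"] = lo.ravel()
    table["coef_q975"] = hi.ravel()
    if collect_effect_draws:
        cov_names = table["covariate"].unique()
        draws = {
            (param, cov): est.effect_size_draws(param, j)
            for param in PARAM_NAMES
            for j, cov in enumerate(cov_names)
        }
        return table, draws
    return table


def run_study(config: ScenarioConfig, sampler_kwargs=None,
              collect_effect_draws=False, progress=None):
    """Run both analyses over all datasets of a scenario.

    Returns a long DataFrame with one row per
    (dataset, analysis, parameter, covariate) cell, and optionally the
    per-cell effect-size draws keyed (dataset, analysis, parameter,
    covariate).
    """
    tables = []
    all_draws = {}
    for d in range(config.n_datasets):
        dataset, cov_frame, _ = generate_dataset(config, d)
        fit_seeds = config.dataset_seed(d).spawn(5)
        for a_idx, analysis in enumerate(("regression", "median_split")):
            seed = int(fit_seeds[3 + a_idx].generate_state(1)[0] % (2**31))
            out = run_dataset(
                dataset, cov_frame, analysis,
                sampler_kwargs=sampler_kwargs,
                cauchy_scale=config.cauchy_scale, seed=seed,
                collect_effect_draws=collect_effect_draws,
            )
            if collect_effect_draws:
                table, draws = out
                for key, arr in draws.items():
                    all_draws[(d, analysis) + key] = arr
            else:
                table = out
            table.insert(0, "dataset", d)
            tables.append(table)
        if progress is not None:
            progress(d)
    results = pd.concat(tables, ignore_index=True)
    if collect_effect_draws:
        return results, all_draws
    return results


#: Desk-scale study profile: a deliberately small instantiation of the
#: simulation study that a single CPU can run in minutes. The generating
#: process is unchanged (published weights, traditional schedule); only the
#: sample sizes and chain lengths are reduced, so per-cell evidence is
#: attenuated and only sign patterns — not magnitudes — are meaningful.
DESK_SCALE = dict(n_participants=40, n_trials=100, n_datasets=2)
DESK_SAMPLER = dict(n_iterations=12_000, n_burnin=2_400, thin=3,
                    method="gibbs")


def run_desk_scenario(rho: float, base_seed: int,
                      progress=None) -> pd.DataFrame:
    """Run one scenario of the study at the desk-scale profile."""
    config = ScenarioConfig(rho=rho, base_seed=base_seed, **DESK_SCALE)
    return run_study(config, sampler_kwargs=dict(DESK_SAMPLER),
                     progress=progress)


def summarize(results: pd.DataFrame, include_nonconverged=False) -> pd.DataFrame:
    """Per-cell median and mean of log(BF10_RG) - log(BF10_MS).

    Cells whose fits did not pass the convergence gate are excluded (and
    counted) unless ``include_nonconverged`` is set. The linear-scale ratio
    exp(median difference) is reported alongside.
    """
    df = results.copy()
    wide = df.pivot_table(
        index=["dataset", "parameter", "covariate"],
        columns="analysis", values="logBF10",
    ).reset_index()
    conv = df.groupby("dataset")["converged"].all()
    wide["converged"] = wide["dataset"].map(conv)
    total = wide["dataset"].nunique()
    if not include_nonconverged:
        wide = wide[wide["converged"]]
    wide["log_bf_diff"] = wide["regression"] - wide["median_split"]
    out = (
        wide.groupby(["parameter", "covariate"])["log_bf_diff"]
        .agg(median_log_bf_diff="median", mean_log_bf_diff="mean",
             n_datasets="size")
        .reset_index()
    )
    out["ratio_at_median"] = np.exp(out["median_log_bf_diff"])
    out["ratio_at_mean"] = np.exp(out["mean_log_bf_diff"])
    out["n_datasets_total"] = total
    return out


def quantile_average_posteriors(draws_list, probs=None):
    """Average distributions across datasets on the quantile scale.

    For each probability level p, returns the across-dataset mean of the
    per-dataset p-quantiles. Draw sets are subsampled to the minimum length
    so each dataset enters with equal weight. The result is a monotone
    averaged quantile function.

    Returns ``(probs, averaged_quantiles)``.
    """
    if probs is None:
        probs = np.linspace(0.005, 0.995, 199)
    probs = np.asarray(probs, dtype=float)
    m = min(len(d) for d in draws_list)
    qs = np.stack([
        np.quantile(np.asarray(d, dtype=float)[:m], probs) for d in draws_list
    ])
    return probs, qs.mean(axis=0)
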