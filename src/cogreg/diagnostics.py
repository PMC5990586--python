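"""Convergence diagnostics for posterior samples."""

from __future__ import annotations

import numpy as np

from .sampling import InsufficientChainsError, PosteriorSamples

#: Fits are flagged unless every group-level R-hat is at or below this.
RHAT_THRESHOLD = 1.01


def gelman_rubin(chains) -> float:
    """Potential scale reduction (split R-hat) for one scalar quantity.

    ``chains`` is a (n_chains, n_draws) array. Requires >= 2 chains with
    >= 10 retained draws each.
    """
    import arviz as az

    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    if chains.shape[0] < 2:
        raise InsufficientChainsError(
            "R-hat requires at least two chains"
        )
    if chains.shape[1] < 10:
        raise ValueError("R-hat requires at least 10 draws per chain")
    return float(az.rhat(az.convert_to_dataset(chains[..., None]))["x"].values[0])


def rhat_table(samples: PosteriorSamples) -> dict:
    """Split R-hat for every group-level scalar quantity in a fit."""
    out = {}
    for name, arr in samples.draws.items():
        if name == "zp":
            continue
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        for k in range(flat.shape[2]):
            sub = np.unravel_index(k, arr.shape[2:]) if arr.ndim > 2 else ()
            label = name + "".join(f"[{i}]" for i in sub)
            out[label] = gelman_rubin(flat[:, :, k])
    return out


def max_rhat(samples: PosteriorSamples) -> float:
    return max(rhat_table(samples).values())


def converged(samples: PosteriorSamples, threshold: float = RHAT_THRESHOLD) -> bool:
    return max_rhat(samples) <= threshold
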