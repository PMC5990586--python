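"""Prospect Valence Learning model with delta rule (PVL-Delta).

The model describes risky choice on the Iowa Gambling Task as a three-step
process per trial: the net payoff X is evaluated through a prospect utility
function u(X) = X^A for gains and -w |X|^A for losses (outcome sensitivity
A in [0, 1], loss aversion w in [0, 5]); the chosen deck's expectancy is
updated by the delta rule Ev <- Ev + a (u - Ev) (updating rate a in [0, 1]);
and the next choice follows a softmax over expectancies with sensitivity
theta = 3^c - 1 (consistency c in [0, 5]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BOUNDS = {"A": (0.0, 1.0), "w": (0.0, 5.0), "a": (0.0, 1.0), "c": (0.0, 5.0)}
PARAM_NAMES = ("A", "w", "a", "c")
#: Upper bounds, in canonical (A, w, a, c) order.
UPPER_BOUNDS = np.array([1.0, 5.0, 1.0, 5.0])

LOG_QUARTER = float(np.log(0.25))


@dataclass(frozen=True)
class PVLParams:
    """The four PVL-Delta parameters on their natural (bounded) scale."""

    A: float
    w: float
    a: float
    c: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            lo, hi = BOUNDS[name]
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    @property
    def theta(self) -> float:
        return sensitivity(self.c)

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.w, self.a, self.c])


def utility(x, A, w):
    """Prospect utility of net outcome x.

    Gains: x^A; losses: -w |x|^A. x = 0 maps to 0 for every A (continuity
    from below, with the convention 0^A = 0 including A = 0).
    """
    A = np.asarray(A, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(A < 0) or np.any(A > 1):
        raise ValueError("A must lie in [0, 1]")
    if np.any(w < 0) or np.any(w > 5):
        raise ValueError("w must lie in [0, 5]")
    x = np.asarray(x, dtype=float)
    mag = np.power(np.abs(x), A, where=np.abs(x) > 0, out=np.zeros_like(np.abs(x) * A))
    return np.where(x >= 0, mag, -w * mag)


def update_expectancy(ev_prev, u, a):
    """Delta-rule update: Ev = Ev_prev + a (u - Ev_prev)."""
    a = np.asarray(a, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("a must lie in [0, 1]")
    return ev_prev + a * (u - ev_prev)


def sensitivity(c):
    """Softmax sensitivity theta = 3^c - 1."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0) or np.any(c > 5):
        raise ValueError("c must lie in [0, 5]")
    out = np.power(3.0, c) - 1.0
    return float(out) if out.ndim == 0 else out


def choice_probabilities(ev, theta):
    """Softmax choice probabilities over the four decks.

    Computed with a max-shift so large theta * Ev cannot overflow. ``ev``
    may be (..., 4); ``theta`` broadcasts over leading dimensions.
    """
    ev = np.asarray(ev, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("theta must be >= 0")
    z = theta[..., None] * ev if theta.ndim else theta * ev
    z = z - z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def simulate_agent(params: PVLParams, schedule, T: int, rng) -> "pd.DataFrame":
    """Simulate one agent for T trials against a payoff schedule.

    Trial 1 is uniform over decks (expectancies start at 0); each choice
    consumes the next scheduled position of its deck; expectancies update
    after every draw. Deterministic given the random generator state.

    Returns a DataFrame with columns trial, choice, win, loss.
    """
    import pandas as pd

    rng = np.random.default_rng(rng)
    if T > schedule.max_draws:
        raise ValueError(
            f"T={T} exceeds schedule max_draws={schedule.max_draws}"
        )
    theta = params.theta
    ev = np.zeros(4)
    positions = np.zeros(4, dtype=int)
    rows = []
    for t in range(1, T + 1):
        if t == 1:
            probs = np.full(4, 0.25)
        else:
            probs = choice_probabilities(ev, theta)
        deck = int(rng.choice(4, p=probs)) + 1
        positions[deck - 1] += 1
        win, loss = schedule.deal(deck, positions[deck - 1])
        x = win + loss
        u = utility(x, params.A, params.w)
        ev[deck - 1] = update_expectancy(ev[deck - 1], u, params.a)
        rows.append((t, deck, win, loss))
    return pd.DataFrame(rows, columns=["trial", "choice", "win", "loss"])


def log_likelihood(params: PVLParams, records) -> float:
    """Log-probability of one participant's choice sequence.

    ``records`` is a DataFrame with columns trial, choice, win, loss sorted
    by trial. Trial 1 contributes log(1/4); trials t >= 2 contribute the
    log softmax probability of the observed choice given the expectancy
    trajectory implied by the observed payoffs.
    """
    records = records.sort_values("trial")
    choices = records["choice"].to_numpy() - 1
    nets = (records["win"] + records["loss"]).to_numpy(dtype=float)
    ll = log_likelihood_matrix(
        np.array([params.A]), np.array([params.w]),
        np.array([params.a]), np.array([params.c]),
        choices[None, :], nets[None, :],
    )
    return float(ll[0])


from numba import njit


@njit(cache=False)
def _ll_kernel(A, w, a, theta, choices, nets):  # pragma: no cover - jitted
    n, t_max = choices.shape
    ll = np.full(n, LOG_QUARTER)
    for i in range(n):
        ev = np.zeros(4)
        for t in range(t_max):
            x = nets[i, t]
            if x == 0.0:
                u = 0.0
            elif x > 0.0:
                u = x ** A[i]
            else:
                u = -w[i] * (-x) ** A[i]
            k = choices[i, t]
            ev[k] += a[i] * (u - ev[k])
            if t + 1 < t_max:
                m = ev[0]
                for d in range(1, 4):
                    if ev[d] > m:
                        m = ev[d]
                s = 0.0
                for d in range(4):
                    s += np.exp(theta[i] * (ev[d] - m))
                kn = choices[i, t + 1]
                ll[i] += theta[i] * (ev[kn] - m) - np.log(s)
    return ll


@njit(cache=False)
def _ll_grad_kernel(A, w, a, theta, choices, nets):  # pragma: no cover - jitted
    """Log-likelihood and its gradient w.r.t. (A, w, a, theta).

    Forward sensitivity analysis through the delta-rule recursion: each
    deck's expectancy Ev carries derivatives w.r.t. A, w and a; the theta
    derivative accumulates directly from the softmax terms.
    """
    n, t_max = choices.shape
    ll = np.full(n, LOG_QUARTER)
    grad = np.zeros((n, 4))  # d ll / d (A, w, a, theta)
    for i in range(n):
        ev = np.zeros(4)
        dev = np.zeros((3, 4))  # sensitivities w.r.t. A, w, a
        for t in range(t_max):
            x = nets[i, t]
            if x == 0.0:
                u = 0.0
                du_dA = 0.0
                du_dw = 0.0
            elif x > 0.0:
                u = x ** A[i]
                du_dA = u * np.log(x)
                du_dw = 0.0
            else:
                m = (-x) ** A[i]
                u = -w[i] * m
                du_dA = u * np.log(-x)
                du_dw = -m
            k = choices[i, t]
            pe = u - ev[k]  # prediction error
            dev[0, k] += a[i] * (du_dA - dev[0, k])
            dev[1, k] += a[i] * (du_dw - dev[1, k])
            # d/da of Ev' = (1-a) Ev + a u  gives  (1-a) dEv/da + (u - Ev)
            dev[2, k] = (1.0 - a[i]) * dev[2, k] + pe
            ev[k] += a[i] * pe
            if t + 1 < t_max:
                m0 = ev[0]
                for d in range(1, 4):
                    if ev[d] > m0:
                        m0 = ev[d]
                s = 0.0
                pvec = np.empty(4)
                for d in range(4):
                    pvec[d] = np.exp(theta[i] * (ev[d] - m0))
                    s += pvec[d]
                kn = choices[i, t + 1]
                ll[i] += theta[i] * (ev[kn] - m0) - np.log(s)
                # softmax probabilities and expectation terms
                ev_bar = 0.0
                dev_bar = np.zeros(3)
                for d in range(4):
                    pvec[d] /= s
                    ev_bar += pvec[d] * ev[d]
                    for q in range(3):
                        dev_bar[q] += pvec[d] * dev[q, d]
                grad[i, 3] += ev[kn] - ev_bar
                for q in range(3):
                    grad[i, q] += theta[i] * (dev[q, kn] - dev_bar[q])
    return ll, grad


def log_likelihood_matrix(A, w, a, c, choices, nets):
    """PVL-Delta log-likelihood for N participants at once.

    Parameters are length-N vectors; ``choices`` (0-based deck indices) and
    ``nets`` are (N, T) arrays of each participant's observed sequence.
    Returns the length-N vector of per-participant log-likelihoods
    (including the uniform log(1/4) for trial 1). The expectancy recursion
    is compiled with numba; softmax terms use a max-shift for stability.
    """
    A = np.ascontiguousarray(A, dtype=np.float64)
    w = np.ascontiguousarray(w, dtype=np.float64)
    a = np.ascontiguousarray(a, dtype=np.float64)
    theta = np.ascontiguousarray(np.atleast_1d(sensitivity(c)),
                                 dtype=np.float64)
    choices = np.ascontiguousarray(choices, dtype=np.int64)
    nets = np.ascontiguousarray(nets, dtype=np.float64)
    return _ll_kernel(A, w, a, theta, choices, nets)


def log_likelihood_and_grad(A, w, a, c, choices, nets):
    """Per-participant log-likelihood and gradient w.r.t. (A, w, a, c).

    Same contract as :func:`log_likelihood_matrix`, additionally returning
    the (N, 4) gradient on the natural parameter scale. The consistency
    derivative follows from theta = 3^c - 1 by the chain rule.
    """
    A = np.ascontiguousarray(A, dtype=np.float64)
    w = np.ascontiguousarray(w, dtype=np.float64)
    a = np.ascontiguousarray(a, dtype=np.float64)
    c = np.ascontiguousarray(c, dtype=np.float64)
    theta = np.power(3.0, c) - 1.0
    choices = np.ascontiguousarray(choices, dtype=np.int64)
    nets = np.ascontiguousarray(nets, dtype=np.float64)
    ll, grad = _ll_grad_kernel(A, w, a, theta, choices, nets)
    grad = grad.copy()
    grad[:, 3] *= (theta + 1.0) * np.log(3.0)  # d theta / d c
    return ll, grad
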