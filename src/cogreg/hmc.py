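"""Hamiltonian Monte Carlo over all continuous latents.

The joint posterior of the hierarchical PVL-Delta variants is differentiable
in every latent once the variance-type quantities are log-transformed
(sigma^2, g) or logit-transformed (the basic hierarchy's uniform-bounded
sigma), so the whole state — participant probit-scale parameters, group
intercepts, regression weights / group differences, residual variances and
the g scalars — is updated jointly by leapfrog trajectories. Likelihood
gradients come from the forward-sensitivity recursion in
:mod:`cogreg.pvl`; the remaining terms are analytic.

Warmup adapts a diagonal mass matrix from windowed draw variances and tunes
the step size toward a target acceptance statistic; both are frozen after
burn-in so the post-warmup chain is a valid Markov chain.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, ndtr

from .pvl import UPPER_BOUNDS, log_likelihood_and_grad

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _norm_pdf(z):
    return np.exp(-0.5 * z * z) / _SQRT2PI


class _Potential:
    """Joint log-density and gradient for one model variant.

    The participant level is non-centered: the state carries standardized
    residuals eta_i = (z'_i - mean_i) / sigma with eta ~ N(0, 1), and
    z' = mean + sigma * eta is reconstructed inside the density. This
    removes the hierarchical funnel between the group level and the
    participant blocks, which is what makes joint gradient updates mix.

    State layout: [eta (N*4), mu (4), coef (4*P) if any,
    log sigma^2 (4) (regression/median-split) or logit-sigma (4) (basic),
    log g (4) (regression only)].
    """

    def __init__(self, spec, choices, nets, design=None, effect_codes=None):
        self.spec = spec
        self.kind = spec.kind
        self.choices = choices
        self.nets = nets
        self.has_data = choices is not None and choices.size > 0
        self.design = design
        self.codes = effect_codes
        if design is not None:
            self.X = design.X
            self.xtx_n = design.xtx_n
            self.p = design.p
        elif effect_codes is not None:
            self.p = effect_codes.shape[1]
        else:
            self.p = 0
        if self.has_data:
            self.n = choices.shape[0]
        elif design is not None:
            self.n = design.n
        elif effect_codes is not None:
            self.n = effect_codes.shape[0]
        else:
            raise ValueError("cannot infer participant count")
        self.dim = (self.n * 4 + 4
                    + (4 * self.p if self.kind != "basic" else 0)
                    + 4 + (4 if self.kind == "regression" else 0))

    # -- state packing ---------------------------------------------------
    def _sigma_of(self, u):
        if self.kind == "basic":
            e = expit(u)
            return self.spec.sigma_upper * e, e
        return np.exp(0.5 * u), None

    def _means(self, mu, coef, sigma):
        mean = np.tile(mu, (self.n, 1))
        dmean = None
        if self.kind == "regression":
            mean = mean + self.X @ coef.T
        elif self.kind == "median_split":
            dmean = self.codes @ coef.T  # (n, 4)
            mean = mean + dmean * sigma
        return mean, dmean

    def pack(self, lat):
        """Latents (natural scale, centered zp) -> state vector."""
        sigma = np.sqrt(lat.sigma2)
        mean, _ = self._means(lat.mu, lat.coef, sigma)
        eta = (lat.zp - mean) / sigma
        parts = [eta.ravel(), lat.mu]
        if self.kind in ("regression", "median_split"):
            parts.append(lat.coef.ravel())
        if self.kind == "basic":
            frac = np.clip(sigma / self.spec.sigma_upper, 1e-9, 1 - 1e-9)
            parts.append(np.log(frac / (1 - frac)))
        else:
            parts.append(np.log(lat.sigma2))
        if self.kind == "regression":
            parts.append(np.log(lat.g))
        return np.concatenate(parts)

    def _split(self, q):
        n, p = self.n, self.p
        eta = q[:n * 4].reshape(n, 4)
        i = n * 4
        mu = q[i:i + 4]
        i += 4
        coef = None
        if self.kind in ("regression", "median_split"):
            coef = q[i:i + 4 * p].reshape(4, p)
            i += 4 * p
        u = q[i:i + 4]
        i += 4
        v = q[i:i + 4] if self.kind == "regression" else None
        return eta, mu, coef, u, v

    def unpack(self, q):
        """State vector -> (zp, mu, coef, sigma2, g)."""
        eta, mu, coef, u, v = self._split(q)
        sigma, _ = self._sigma_of(u)
        mean, _ = self._means(mu, coef, sigma)
        zp = mean + sigma * eta
        g = np.exp(v) if v is not None else None
        return zp, mu, coef, sigma ** 2, g

    # -- log-density and gradient ---------------------------------------
    def __call__(self, q):
        n, p = self.n, self.p
        eta, mu, coef, u, v = self._split(q)
        sigma, e = self._sigma_of(u)
        s2 = sigma ** 2
        g = np.exp(v) if v is not None else None
        mean, dmean = self._means(mu, coef, sigma)
        zp = mean + sigma * eta

        grad = np.zeros_like(q)
        logp = 0.0

        # ---- likelihood (gradient G w.r.t. z', then chain rule) ----
        if self.has_data:
            pdf = _norm_pdf(zp)
            nat = ndtr(zp) * UPPER_BOUNDS
            ll, gnat = log_likelihood_and_grad(
                nat[:, 0], nat[:, 1], nat[:, 2], nat[:, 3],
                self.choices, self.nets)
            logp += float(ll.sum())
            G = gnat * UPPER_BOUNDS * pdf  # (n, 4), d loglik / d z'
        else:
            G = np.zeros((n, 4))

        # ---- standardized residuals: eta ~ N(0, 1) ----
        logp += float(-0.5 * (eta * eta).sum())
        grad[:n * 4] = (G * sigma - eta).ravel()

        gmu = G.sum(axis=0)
        if self.kind == "basic":
            dz_dsigma = eta
        elif self.kind == "regression":
            dz_dsigma = 0.5 * eta * sigma  # d z'/d u with dsigma/du = s/2
        else:  # median_split: mean also carries sigma
            dz_dsigma = 0.5 * (eta + dmean) * sigma

        # ---- priors ----
        logp += float(-0.5 * mu @ mu)
        gmu = gmu - mu
        grad[n * 4:n * 4 + 4] = gmu
        ic = n * 4 + 4

        if self.kind == "regression":
            gcoef = (self.X.T @ G).T  # (4, p)
            quad = np.einsum("jp,pq,jq->j", coef, self.xtx_n, coef)
            logp += float(
                (-0.5 * quad / (g * s2)
                 - 0.5 * p * (np.log(g) + np.log(s2))).sum())
            gcoef += -(coef @ self.xtx_n) / (g * s2)[:, None]
            gu = (G * dz_dsigma).sum(axis=0)
            gu += -0.5 * p + 0.5 * quad / (g * s2)
            # sigma^2 ~ IG(2, 1/2) on the log scale (Jacobian folded in)
            logp += float((-2.0 * u - 0.5 / s2).sum())
            gu += -2.0 + 0.5 / s2
            gv = -0.5 * p + 0.5 * quad / (g * s2)
            bg = self.spec.cauchy_scale ** 2 / 2.0
            logp += float((-0.5 * v - bg / g).sum())
            gv += -0.5 + bg / g
            grad[ic:ic + 4 * p] = gcoef.ravel()
            grad[ic + 4 * p:ic + 4 * p + 4] = gu
            grad[ic + 4 * p + 4:ic + 4 * p + 8] = gv
        elif self.kind == "median_split":
            # z' depends on delta through the mean shift sigma * (D delta)
            gcoef = (self.codes.T @ G * sigma).T  # (4, p)
            logp += float(-np.log1p(coef ** 2).sum() - 4 * p * np.log(np.pi))
            gcoef += -2.0 * coef / (1.0 + coef ** 2)
            gu = (G * dz_dsigma).sum(axis=0)
            logp += float((-2.0 * u - 0.5 / s2).sum())
            gu += -2.0 + 0.5 / s2
            grad[ic:ic + 4 * p] = gcoef.ravel()
            grad[ic + 4 * p:ic + 4 * p + 4] = gu
        else:  # basic: sigma ~ U(0, upper) via logit, Jacobian included
            logp += float((np.log(sigma) + np.log1p(-e)).sum())
            dsig_du = sigma * (1 - e)
            gu = (G * dz_dsigma).sum(axis=0) * dsig_du + (1 - 2 * e)
            grad[ic:ic + 4] = gu
        return logp, grad


def warm_start(pot, q0, n_steps=500, lr=0.05):
    """Adam ascent on the joint log-density to reach the typical set.

    Random initial states can land in extremely stiff regions (e.g. softmax
    sensitivity near its upper bound), where leapfrog steps are rejected
    until the chain crawls out. A couple hundred cheap gradient steps
    remove that transient before warmup proper.
    """
    q = q0.copy()
    m = np.zeros_like(q)
    s = np.zeros_like(q)
    best_q, best_lp = q.copy(), -np.inf
    for t in range(1, n_steps + 1):
        with np.errstate(over="ignore", invalid="ignore"):
            logp, grad = pot(q)
        if np.isfinite(logp) and logp > best_lp:
            best_q, best_lp = q.copy(), logp
        if not np.all(np.isfinite(grad)):
            q = best_q + 0.01 * np.random.default_rng(t).standard_normal(q.size)
            continue
        m = 0.9 * m + 0.1 * grad
        s = 0.999 * s + 0.001 * grad ** 2
        mh = m / (1 - 0.9 ** t)
        sh = s / (1 - 0.999 ** t)
        q = q + lr * mh / (np.sqrt(sh) + 1e-8)
    return best_q if best_lp > -np.inf else q0


def _leapfrog(pot, q, mom, step, n_steps, minv, logp, grad):
    mom = mom + 0.5 * step * grad
    for s in range(n_steps):
        q = q + step * minv * mom
        logp, grad = pot(q)
        if not np.isfinite(logp):
            return q, mom, logp, grad
        if s < n_steps - 1:
            mom = mom + step * grad
    mom = mom + 0.5 * step * grad
    return q, mom, logp, grad


class _Tree:
    """One NUTS trajectory (multinomial variant, recursive doubling)."""

    __slots__ = ("pot", "step", "minv", "rng", "h0", "n_eval", "divergent",
                 "sum_accept", "n_accept")

    MAX_DELTA_H = 1000.0

    def __init__(self, pot, step, minv, rng, h0):
        self.pot = pot
        self.step = step
        self.minv = minv
        self.rng = rng
        self.h0 = h0
        self.n_eval = 0
        self.divergent = False
        self.sum_accept = 0.0
        self.n_accept = 0

    def _leaf(self, q, p, grad, direction):
        step = direction * self.step
        p = p + 0.5 * step * grad
        q = q + step * self.minv * p
        with np.errstate(over="ignore", invalid="ignore"):
            logp, grad = self.pot(q)
        self.n_eval += 1
        if np.isfinite(logp):
            p = p + 0.5 * step * grad
            joint = logp - 0.5 * float((p * p * self.minv).sum())
        else:
            joint = -np.inf
        dh = joint - self.h0
        if not np.isfinite(dh) or dh < -self.MAX_DELTA_H:
            self.divergent = True
            dh = -np.inf
        self.sum_accept += min(1.0, np.exp(min(dh, 0.0)))
        self.n_accept += 1
        # (minus-state, plus-state, proposal, log weight, turning)
        state = (q, p, grad, logp)
        return state, state, state, dh, False

    def build(self, state, depth, direction):
        """Returns (minus, plus, proposal, log_weight, turning)."""
        if depth == 0:
            return self._leaf(state[0], state[1], state[2], direction)
        m1, p1, prop1, lw1, turn1 = self.build(state, depth - 1, direction)
        if turn1 or self.divergent:
            return m1, p1, prop1, lw1, True
        inner = p1 if direction > 0 else m1
        m2, p2, prop2, lw2, turn2 = self.build(inner, depth - 1, direction)
        minus, plus = (m1, p2) if direction > 0 else (m2, p1)
        if turn2 or self.divergent:
            return minus, plus, prop1, lw1, True
        lw = np.logaddexp(lw1, lw2)
        # multinomial sampling between subtrees
        if np.log(self.rng.random()) < lw2 - lw:
            prop = prop2
        else:
            prop = prop1
        turning = self._uturn(minus, plus)
        return minus, plus, prop, lw, turning

    def _uturn(self, minus, plus):
        dq = plus[0] - minus[0]
        return (float(dq @ (self.minv * minus[1])) < 0
                or float(dq @ (self.minv * plus[1])) < 0)


def nuts_step(pot, q, logp, grad, step, minv, rng, max_depth=9):
    """One NUTS transition; returns (q, logp, grad, accept_stat, n_eval,
    divergent, depth)."""
    p0 = rng.standard_normal(q.size) / np.sqrt(minv)
    h0 = logp - 0.5 * float((p0 * p0 * minv).sum())
    tree = _Tree(pot, step, minv, rng, h0)
    state = (q, p0, grad, logp)
    minus = plus = state
    prop = state
    log_w = 0.0  # weight of the initial point: exp(h0 - h0)
    depth = 0
    while depth < max_depth:
        direction = 1 if rng.random() < 0.5 else -1
        edge = plus if direction > 0 else minus
        m2, p2, prop2, lw2, turning = tree.build(edge, depth, direction)
        if tree.divergent or turning:
            break
        if direction > 0:
            plus = p2
        else:
            minus = m2
        # progressive (biased) multinomial update of the proposal
        if np.log(rng.random()) < lw2 - log_w:
            prop = prop2
        log_w = np.logaddexp(log_w, lw2)
        depth += 1
        if tree._uturn(minus, plus):
            break
    accept_stat = tree.sum_accept / max(tree.n_accept, 1)
    q_new, _, grad_new, logp_new = prop
    return q_new, logp_new, grad_new, accept_stat, tree.n_eval, \
        tree.divergent, depth


def _mass_windows(n_burnin, init_buffer=75, term_buffer=50, base=50):
    """Stan-style warmup schedule: [init_buffer | doubling windows |
    term_buffer]; returns iteration indices at which to refresh the mass."""
    if n_burnin < init_buffer + term_buffer + base:
        return []
    ends = []
    start = init_buffer
    width = base
    while True:
        end = start + width
        if end + term_buffer >= n_burnin:
            # merge the remainder into the previous window
            if ends:
                ends[-1] = n_burnin - term_buffer
            else:
                ends.append(n_burnin - term_buffer)
            break
        ends.append(end)
        start = end
        width *= 2
    return ends


class _DualAveraging:
    """Nesterov dual averaging of the step size toward a target
    acceptance statistic."""

    def __init__(self, step0, target=0.8, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * step0)
        self.target = target
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.log_step = np.log(step0)
        self.log_step_bar = np.log(step0)
        self.hbar = 0.0
        self.m = 0

    def update(self, accept_stat):
        self.m += 1
        frac = 1.0 / (self.m + self.t0)
        self.hbar = (1 - frac) * self.hbar + frac * (self.target - accept_stat)
        self.log_step = self.mu - np.sqrt(self.m) / self.gamma * self.hbar
        eta = self.m ** -self.kappa
        self.log_step_bar = eta * self.log_step + (1 - eta) * self.log_step_bar

    @property
    def step(self):
        return float(np.exp(self.log_step))

    @property
    def final_step(self):
        return float(np.exp(self.log_step_bar))


def _find_initial_step(pot, q, logp, grad, minv, rng):
    """Double/halve the step until one leapfrog crosses 50% acceptance."""
    step = 1.0
    p0 = rng.standard_normal(q.size) / np.sqrt(minv)
    h0 = logp - 0.5 * float((p0 * p0 * minv).sum())

    def accept_of(step):
        with np.errstate(over="ignore", invalid="ignore"):
            q1, p1, lp1, _ = _leapfrog(pot, q, p0, step, 1, minv, logp, grad)
        if not np.isfinite(lp1):
            return -np.inf
        return lp1 - 0.5 * float((p1 * p1 * minv).sum()) - h0

    direction = 1 if accept_of(step) > np.log(0.5) else -1
    for _ in range(50):
        step_next = step * (2.0 if direction == 1 else 0.5)
        crossed = accept_of(step_next) > np.log(0.5)
        if (direction == 1 and not crossed) or (direction == -1 and crossed):
            return step_next if direction == -1 else step
        step = step_next
    return step


def run_nuts_chain(pot, q0, config, rng, max_depth=9, target_accept=0.8):
    """One NUTS chain over the potential; returns (kept draws, stats).

    Warmup follows the usual three phases: an initial step-size-only
    buffer with unit mass, doubling windows each of which re-estimates the
    diagonal inverse mass from that window's draws alone (so early
    transients are forgotten), and a terminal step-size buffer. Step size
    is tuned by dual averaging toward the target acceptance statistic,
    restarted after every mass refresh, and frozen after burn-in.
    """
    q = warm_start(pot, q0)
    logp, grad = pot(q)
    if not np.isfinite(logp):
        raise RuntimeError(
            f"non-finite joint log-density at initialization (logp={logp})")
    d = q.size
    minv = np.ones(d)
    step0 = _find_initial_step(pot, q, logp, grad, minv, rng)
    da = _DualAveraging(step0, target=target_accept)
    windows = _mass_windows(config.n_burnin)
    mean = np.zeros(d)
    m2 = np.zeros(d)
    count = 0
    kept = []
    accept_sum = 0.0
    n_div = 0
    depth_sum = 0
    for it in range(config.n_iterations):
        in_burnin = it < config.n_burnin
        step = da.step if in_burnin else da.final_step
        q, logp, grad, astat, n_eval, div, depth = nuts_step(
            pot, q, logp, grad, step, minv, rng, max_depth=max_depth)
        accept_sum += astat
        n_div += div
        depth_sum += depth
        if in_burnin:
            da.update(astat)
            if windows and it >= 75:
                count += 1
                delta = q - mean
                mean += delta / count
                m2 += delta * (q - mean)
                if (it + 1) in windows and count > 10:
                    var = m2 / (count - 1)
                    # regularized toward a small constant, as in Stan
                    w = count / (count + 5.0)
                    minv = w * var + (1.0 - w) * 1e-3
                    mean[:] = 0.0
                    m2[:] = 0.0
                    count = 0
                    step0 = _find_initial_step(pot, q, logp, grad, minv, rng)
                    da = _DualAveraging(step0, target=target_accept)
        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
            kept.append(q.copy())
    stats = {
        "accept": accept_sum / config.n_iterations,
        "divergences": n_div,
        "mean_depth": depth_sum / config.n_iterations,
        "step": da.final_step,
    }
    return np.asarray(kept), stats


def run_hmc_chain(pot, q0, config, rng, **kw):
    """Alias retained for the gradient-based default sampler."""
    kept, stats = run_nuts_chain(pot, q0, config, rng, **kw)
    return kept, stats["accept"]
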