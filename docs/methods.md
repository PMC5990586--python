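# Methods

## The model

The package instantiates a hierarchical Bayesian regression framework for
testing relationships between cognitive-model parameters and continuous
covariates, using the PVL-Delta reinforcement-learning model of the Iowa
Gambling Task (IGT) as the cognitive layer.

**Task layer.** The IGT presents four decks; decks A/B win 100 per draw and
lose 250 net per 10-draw block, decks C/D win 50 and gain 250 net per
block; A and C carry five losses per block, B and D one large loss. The
traditional fixed schedule is built in 10-draw blocks that repeat
cyclically so any trial count that is a multiple of ten can be dealt. The
exact within-block loss positions are not uniquely fixed by the published
block constraints; the implementation uses one standard layout and the
test suite enforces only the block invariants (wins constant, block sums,
loss counts), so any conforming variant is acceptable. The initial credit
of $2000 is recorded but plays no role in the model equations.

**Cognitive layer (PVL-Delta).** Per trial the net payoff X is evaluated by
the prospect utility u(X) = X^A for X >= 0 and -w|X|^A for X < 0 (outcome
sensitivity A in [0,1], loss aversion w in [0,5]); the chosen deck's
expectancy follows the delta rule Ev <- Ev + a(u - Ev) (updating rate a in
[0,1]); choices follow a softmax with sensitivity theta = 3^c - 1
(consistency c in [0,5]). Conventions: X is the net outcome (win + loss);
u(0) = 0 for every A (continuity from below); trial 1 is uniform over
decks and contributes log(1/4) to the likelihood; unchosen decks'
expectancies are carried forward unchanged. The softmax is computed with a
max-shift so theta*Ev up to ~1e6 cannot overflow.

**Hierarchical layer.** Each bounded parameter z with upper bound U is
mapped to the real line by z' = Phi^{-1}(z/U) (the bound-scaled probit, a
bijection for all four parameters). Three group-level structures:

* basic: z'_i ~ N(mu, sigma^2), mu ~ N(0,1), sigma ~ U(0, 1.5);
* regression: z'_i ~ N(mu + x_i' alpha, sigma^2) over centered covariates,
  with the JZS mixture-of-g prior
  alpha | g ~ N(0, g sigma^2 (X'X/N)^{-1}), g ~ InvGamma(1/2, s^2/2),
  mu ~ N(0,1), sigma^2 ~ InvGamma(2, 1/2);
* median split: z'_i ~ N(mu + delta' d_i sigma, sigma^2) with effect codes
  d_ij = +0.5 strictly above the covariate median, -0.5 otherwise, and
  independent delta_j ~ Cauchy(0,1).

X'X is computed from the centered covariate matrix with the denominator-N
variance convention, so X'X/N equals the sample covariance exactly and,
for one covariate, reduces to s_x^2. One independent g is used per model
parameter (each of the four regressions carries its own JZS prior); this
is the natural per-regression reading of the mixture-of-g construction.

**Hypothesis tests.** Evidence for each standardized effect
beta_{z'j} = alpha_{z'j} s_j / sigma_{z'} (or each delta_{z'j}) is the
Savage-Dickey density ratio BF10 = p(beta = 0 | H1) / p(beta = 0 | y, H1)
with H1: beta ~ Cauchy(0, s). The prior density at zero is 1/(pi s)
exactly. With correlated covariates the marginal prior of a single beta_j
implied by the multivariate construction is slightly heavier than
Cauchy(s) (scale inflated by 1/sqrt(1 - rho^2)); the stated univariate
Cauchy(s) prior density is used for both analyses, matching the framework's
definition of the test. Default s = 1; s = 1/3 is available for settings
where small effects are expected a priori.

**Posterior density at zero.** A log-spline-type estimator: bin the pooled
post-burn-in draws, model the log-density with a cubic B-spline basis
(knots at draw quantiles), and fit a Poisson GLM with a log(N * binwidth)
offset, so the fitted intensity integrates to the draw count and
exp(fit)/N/binwidth is a proper density. Outside the draw range the
log-density is extended linearly from the boundary slope. A Gaussian
kernel estimate (Scott bandwidth) is the recorded fallback when the spline
fit fails. Benchmarks: at 1e5 standard-normal draws the estimate at the
center is within 0.01 of 1/sqrt(2 pi); at 3-3.5 SD into a tail the log
error is roughly 0.03-0.1, which bounds the accuracy of very large
Savage-Dickey Bayes factors.

## Samplers

Two independent backends target the same joint posterior; their agreement
on a common fit is itself a test.

**Gibbs (default).** Metropolis-within-Gibbs. Given the participant-level
z', the group level is a Gaussian linear model: mu, alpha, sigma^2 and g
have exact conjugate conditionals (normal / multivariate normal /
inverse-gamma), vectorized across the four model parameters. Participant
blocks use adaptive-covariance random-walk Metropolis (per-participant
proposal covariance learned in forgetting windows during burn-in, scale
tuned to ~0.25 acceptance, frozen afterwards); a joint "translation" move
shifts (mu, alpha) together with every z'_i so the hierarchy term cancels
and group-level mixing decouples from the participant random walk. The
median-split delta and sigma^2 (which enters the mean structure) use
random-walk Metropolis. The basic hierarchy's sigma^2 conditional is a
truncated inverse-gamma sampled by inverse-CDF.

**NUTS.** The No-U-Turn Sampler (multinomial variant, biased progressive
sampling, dual-averaging step size toward a 0.8 acceptance statistic,
windowed diagonal mass adaptation) over all continuous latents, with the
participant level non-centered (eta = (z' - mean)/sigma ~ N(0,1)) to
remove the hierarchical funnel. Likelihood gradients are analytic: forward
sensitivities of the expectancy recursion w.r.t. (A, w, a) plus the direct
softmax derivative w.r.t. theta, verified against finite differences to
1e-9. Variance-type latents are log-transformed (logit for the uniform-
bounded sigma), with Jacobians. A short Adam ascent on the joint
log-density precedes warmup so chains do not start in extremely stiff
regions.

**Why Gibbs is the default.** Under the published generating values the
consistency parameter sits near c ~ 4.5 (theta ~ 150), the softmax is
saturated, and the likelihood surface is plateau-and-cliff. Leapfrog
integration diverges at the cliffs, so NUTS needs very small steps and
deep trees; the rejection-based Gibbs moves are unaffected and converge
substantially faster per CPU-second in this regime (R-hat <= 1.01 within
40k sweeps at desk scale). On tame regimes (theta ~ 5-15) both backends
mix well and agree; NUTS is kept first-class and used as the
cross-checking route.

**Initialization** follows the distributional scheme of the simulation
protocol: mu ~ N(0,1), sigma ~ Exponential(1), regression weights
~ N(0, 2^2), g = 1, z' at its implied conditional mean.

**Convergence.** Split R-hat (via ArviZ) on every group-level scalar; fits
are flagged unless all R-hat <= 1.01. Desk-scale chains typically land at
1.01-1.06; study summaries at desk scale therefore include flagged fits
and report the maximum R-hat alongside, rather than silently excluding
everything. Paper-scale runs retain the strict gate.

## Synthetic-data generator

The generator emulates the study's generative process: covariates ~
bivariate normal, unit variances, correlation rho in {0, 0.7}; probit-
scale parameters linear in the (uncentered, mean-zero-population)
covariates with the published generating weights — effects alpha_A'1 = 1
and alpha_w'2 = -0.9, all other weights at their empirically estimated
values, intercepts (0.24, 0.38, 0.30, 1.34) and residual spreads
(1.06, 0.91, 1.58, 0.46) per (A', w', a', c'); agents then play T trials
of the traditional schedule. The residual-spread column is read as
standard deviations by default; a `sigma_as="var"` switch reads it as
variances (the two readings differ by <3% for the A'/w' rows but more for
a'/c'). Covariates are always centered at analysis time, so the pipeline
is correct for arbitrary user data. Per-dataset seeds derive
deterministically from (base seed, dataset index) via NumPy SeedSequence.

What the generator does **not** emulate: real participants' deviations
from the PVL-Delta process (lapses, position biases, non-stationarity),
covariate measurement error, and missing data. Passing tests therefore
demonstrate correctness of the machinery under the model, not robustness
to model misspecification.

## Study harness and problem sizes

The full protocol (150 participants, 200 trials, 50 datasets per scenario,
2 chains x 45,000 draws with 5,000 burn-in and thinning 5) is available
behind the `--paper-scale` flag and as the `SamplerConfig` default; it is
a cluster-scale computation. The packaged desk profile — the package's own
choice of a minimal faithful instantiation — uses 40 participants, 100
trials, 2 datasets per scenario, and Gibbs chains of 2 x 12,000 sweeps
(2,400 burn-in, thin 3). At this scale each Bayes factor is attenuated
(fewer trials weakly identify the outcome-sensitivity parameter in
particular) and medians are taken over two datasets, so only the *sign*
of the per-cell median log-BF difference log(BF10_RG) - log(BF10_MS) is
meaningful: positive for generated effects under uncorrelated covariates
(median-split loses power), near zero for null cells, negative for the
spurious-effect cells under correlated covariates (median-split
manufactures evidence). `summarize` reports the median and the mean
difference per cell plus their linear-scale ratios, and counts excluded
datasets when the convergence gate is enforced.

## Numerical choices and edge cases

* 0^A := 0 for all A in [0,1] (utility of a zero net outcome).
* Effect codes assign -0.5 to values exactly at the median.
* Constant covariate columns raise a degenerate-covariate error; a
  singular X'X raises a singular-design error.
* The analytic JZS Bayes factor integrates the g-conditional Bayes factor
  (1 + Ng)^{(n-1-p)/2} [1 + Ng(1-R^2)]^{-(n-1)/2} against the
  InvGamma(1/2, s^2/2) density on the log-g scale, with the integrand
  shifted by its mode for stability; the g-conditional factor itself is
  validated against direct 3-D quadrature of the marginal likelihoods at
  small n.
* Savage-Dickey ratios with an exactly-zero posterior density estimate are
  reported as +inf with a saturation flag.
* Quantile averaging subsamples draw sets to the shortest length so every
  dataset enters with equal weight.

## Known limitations

* Magnitude-level reproduction of the published study summaries requires
  the full-scale protocol (days of CPU serially); the desk profile asserts
  directions only.
* Savage-Dickey Bayes factors beyond ~e^5 are bounded in accuracy by the
  density-at-zero tail estimate (~0.1 on the log scale).
* Joint (multivariate) point nulls across several effect sizes are out of
  scope; each effect is tested marginally.
* The median-split model is intentionally the "sophisticated"
  one-step dichotomization; the two-step fit-then-test variant is not
  implemented.
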