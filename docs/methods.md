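# Methods

## Model

Let y_i be an outcome observed at continuous predictor value x_i, i = 1..n,
and let t_1 < ... < t_m be the unique ordered values of x, optionally merged
with user-requested augmentation points.  With x_i = t_j, horseshoe process
regression (HPR) models

    g(E[y_i]) = f_j = alpha + sum_{k<=j} h_k,            h_1 = 0
    h_k | tau, lambda_k ~ N(0, tau^2 lambda_k^2 (t_k - t_{k-1})),  k = 2..m
    tau ~ C+(0, c),    lambda_k ~ iid C+(0, 1),    alpha ~ N(a, b^2)

where C+(0, s) is the half-Cauchy distribution with scale s.  This places a
horseshoe prior on the first-order increments of the latent function f: the
global scale tau shrinks all increments toward zero (long flat stretches)
while the per-increment local scales lambda_k let individual increments
escape shrinkage entirely (abrupt jumps).  Increment variance scales with
the spacing t_k - t_{k-1}, so unevenly spaced and repeated predictor values
are handled naturally.  The outcome families are Gaussian (identity link,
residual sd sigma ~ C+(0, s)), Bernoulli (logit link) and Poisson (log
link).

Three extensions share this core:

- **Interpolation.**  Augmentation points are gridpoints without
  observations.  Because the joint density factorizes into the likelihood of
  the observed outcomes and the prior of the whole latent path, an
  augmentation point contributes prior terms only: it receives its own
  lambda_k and increment, the posterior at observed points is unchanged, and
  the posterior at the new point is a model-based interpolation (or
  extrapolation, if outside the observed range).  The scheme assumes the
  unobserved stretch behaves like the observed ones; jumps with no support
  in the observed data cannot be recovered.
- **Partial-linear covariates.**  g(E[y_i]) = f_j + beta' z_i with
  beta_l ~ N(0, d_l^2) for a p-vector of covariates z_i.
- **Monotonicity.**  f_j = alpha +/- sum_{k<=j} |h_k| constrains the fit to
  be nondecreasing/nonincreasing while leaving all priors unchanged.

## Non-centered parameterization

All sampled parameters have fixed priors; model-space parameters are
deterministic transforms (this removes the prior correlation between scales
and increments that defeats gradient-based samplers on funnel geometries):

    tau      = c * |tau1| * sqrt(tau2)      tau1 ~ N(0,1), tau2 ~ IG(1/2,1/2)
    lambda_k = |l1_k| * sqrt(l2_k)          same primitives, k = 2..m
    sigma    = s * |sigma1| * sqrt(sigma2)  same primitives (Gaussian only)
    h_k      = gamma_k * tau * lambda_k * sqrt(t_k - t_{k-1}),  gamma_k ~ N(0,1)
    alpha    = a + b * alpha_raw            alpha_raw ~ N(0,1)
    beta_l   = d_l * beta_raw_l             beta_raw_l ~ N(0,1)

Since |N(0,1)| * sqrt(IG(1/2,1/2)) is the ratio of a half-normal to the
square root of a chi-square(1), each scale is exactly half-Cauchy with the
stated scale, and Var(h_k | tau, lambda_k) = tau^2 lambda_k^2 (t_k -
t_{k-1}).  Both identities are enforced by property tests (two-sample
Kolmogorov-Smirnov at alpha = 0.01 on 10^5 draws against direct half-Cauchy
sampling, and a Monte-Carlo variance check).  The square roots are required
for these identities; writing the products without them would change the
implied laws.  Absolute values rather than half-normal constraints keep the
sampler space fully unconstrained; the positive primitives (tau2, lambda2,
sigma2) are sampled on the log scale with the exact inverse-gamma
log-Jacobian added.

## Default priors

| parameter | default | rationale |
|---|---|---|
| a (intercept mean) | mean(y) on the link scale | centers the process at the data; for discrete families the empirical mean is clamped to [0.01, 0.99] (Bernoulli) or >= 0.01 (Poisson) before the link |
| b (intercept scale) | 5 * sd(y); 5 for discrete outcomes or zero-variance y | weakly informative on the outcome's own scale |
| c (global-shrinkage scale) | 0.01 | strong prior pull toward a flat function; data overwhelm it wherever jumps are supported |
| s (residual-sd scale) | 5 | covers residual scales well beyond typical standardized outcomes |
| d (coefficient scales) | 5 (continuous outcome), 2.5 (discrete) | paired with covariate scaling below |

Continuous covariate columns are centered and rescaled to sd 1 (continuous
outcome) or sd 0.5 (discrete outcome); binary 0/1 dummies are centered only
so their coefficients remain per-level effects.  The scaling record inverts
fitted coefficients back to original units.  Constant covariate columns and
zero-variance outcomes degrade to declared fallbacks with warnings rather
than errors.

## Posterior computation

Inference is dynamic Hamiltonian Monte Carlo: the doubling/slice variant of
the No-U-Turn Sampler with dual-averaging step-size adaptation and a
windowed diagonal (inverse) mass-matrix estimate from warmup draws, written
against an analytic gradient of the unconstrained log posterior.  Two
implementations of the same algorithm exist deliberately: a pure-Python
recursive reference (`hpr.nuts`), kept readable and used as the test oracle,
and numba kernels (`hpr._kernels`) with an iterative tree construction used
by `fit_hpr`.  The kernel gradient is tested for exact (1e-9) agreement with
the reference gradient, which is itself tested against finite differences
and an independent scipy.stats term-by-term density oracle.

Defaults: 4 chains, 1000 warmup + 2000 retained iterations each (8000
retained draws), acceptance target 0.95, maximum tree depth 10, jittered
initialization near the origin of the raw scale with up to 4 seeded retries.
The high acceptance target is deliberate: horseshoe posteriors have
funnel-like geometry and sporadic divergences even after decentering.  The
diagnostics report flags a fit when divergences exceed 5% of retained
iterations or split-R-hat (computed via arviz, as is bulk ESS) exceeds 1.01;
both thresholds are configurable.  Treedepth-capped trajectories are counted
separately and are common under the 0.95 target; they cost efficiency, not
validity.

Point estimates default to the posterior mean at each gridpoint (median
available), with central credible intervals from empirical quantiles of the
retained draws.  Seeds split deterministically per chain and per replicate,
so identical data + configuration + seed reproduce identical draws.

## Simulation harness

Four truth functions on [0, 10], observed by default at n = 100 equally
spaced points (inclusive of the endpoints) with Gaussian noise:

- bigstep (sd 0.5): steps 0 / 6 / 1 / 3 / 10 with breaks at 2, 5, 6, 8
  (right-closed pieces);
- joinpoint (sd 0.5): continuous piecewise-linear with slope changes at
  2, 3, 6, 9 (left-closed pieces);
- impulse (sd 0.1): exponential decay exp(-x) restarted at x = 3, isolated
  unit spikes at x = 3 and x = 7, zero at x = 0 and beyond 7 — the printed
  boundary conventions are honored exactly, including the isolated points;
- bounce (sd 0.2): |sin x|, smooth — included as a stress case the model is
  not designed for.

The uneven-design study draws the n predictor values iid uniform on (0, 10)
(sorted, endpoints not forced in, so augmentation grids at every 0.5 or 0.1
can extrapolate).  Metrics per fit, averaged over a designated point set
(observed, augmented, or all): MAD = mean |f - f_hat|, Width = mean 95%
interval width, Coverage = share of points whose interval contains the
truth.  Replicate seeds are master_seed + replicate index (mod 2^31 - 1), so
studies are resumable; failed replicates are recorded with NaN metrics, not
fatal.  Aggregates are means with Monte-Carlo standard errors.

For Bernoulli/Poisson outcomes the generator maps each truth affinely onto
[-2, 2] on the linear-predictor scale (range computed on a dense grid of the
domain) and applies the inverse link.  This is a synthetic stand-in chosen
to give event probabilities in roughly [0.12, 0.88] and Poisson means in
[0.14, 7.4]; it is isolated behind the `linear_transform` hook of
`simulate_dataset` and is not calibrated against any external reference.

## Numerical choices and scaled-down defaults

- Grid merging uses exact floating-point equality; no tolerance-based
  absorption of near-duplicate augmentation points (silent merging would
  change m unpredictably).  An augmentation point below min(x) becomes the
  new leftmost gridpoint, so alpha then refers to it.
- Log-scale primitives beyond +/-600 are treated as zero-density (guards
  exp overflow during step-size search); a trajectory whose energy error
  exceeds 1000 nats is divergent.
- sign(0) = 0 in the gradient at the (measure-zero) kinks of the absolute
  values.
- Self-validation studies in the test suite and the reproduction script run
  scaled down — 8-10 replicates with 2 chains x (500 + 500) iterations
  rather than 100 replicates with 4 chains x (1000 + 2000) — which is why
  coverage assertions carry two Monte-Carlo standard errors of slack.

## Limitations

- The generator emulates iid measurement noise on a fixed design; real
  longitudinal series (the motivating basal-body-temperature setting) have
  missingness, day-to-day autocorrelation and recording artifacts none of
  which are modeled, so passing tests demonstrate calibration under the
  stated conditions only.
- The model assumes step-like structure; on smooth truths (bounce) it is
  consistently outperformed by smoothness-assuming methods, and its bands
  are wide there.
- No hyperprior on c, no regularized-horseshoe tail, single nonparametric
  term only; covariates enter linearly.
- Interpolation inherits the observed process's jump behavior; it cannot
  place jumps between observations that the data do not support.
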