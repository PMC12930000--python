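"""Horseshoe process regression model.

The latent function f on the grid t_1 < ... < t_m is the running sum of
horseshoe-distributed increments,

    f_j = alpha + sum_{k<=j} h_k,        h_1 = 0,
    h_k | tau, lambda_k ~ N(0, tau^2 lambda_k^2 (t_k - t_{k-1})),
    tau ~ C+(0, c),   lambda_k ~iid C+(0, 1),   alpha ~ N(a, b^2),

linked to the outcome through an identity (Gaussian), logit (Bernoulli) or
log (Poisson) link.  A monotone fit sums |h_k| (increasing) or -|h_k|
(decreasing); linear covariates enter additively with beta ~ N(0, d^2).

Sampling uses a non-centered parameterization throughout: every sampled
("raw") parameter has a fixed prior, and the model-space parameters are
deterministic transforms.  The half-Cauchy scales are realized as
|normal| * sqrt(inverse-gamma):

    tau    = c * |tau1| * sqrt(tau2),        tau1 ~ N(0,1), tau2 ~ IG(1/2, 1/2)
    lam_k  = |lambda1_k| * sqrt(lambda2_k),  same primitives
    sigma  = s * |sigma1| * sqrt(sigma2)
    h_k    = gamma_k * tau * lam_k * sqrt(t_k - t_{k-1}),  gamma_k ~ N(0,1)

which reproduces the stated half-Cauchy laws exactly (ratio of a half-normal
to the square root of a chi-square with one degree of freedom).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy.special import expit, gammaln

from .grid import Grid

__all__ = [
    "FamilySpec",
    "ObservedData",
    "PriorConfig",
    "RawParams",
    "TransformedParams",
    "CovariateScaler",
    "default_priors",
    "scale_covariates",
    "transform_raw",
    "latent_mean",
    "log_posterior",
]

Constraint = Literal["none", "increasing", "decreasing"]

_LINKS = {"gaussian": "identity", "bernoulli": "logit", "poisson": "log"}

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class FamilySpec:
    """Outcome family with its canonical link."""

    family: Literal["gaussian", "bernoulli", "poisson"] = "gaussian"

    def __post_init__(self) -> None:
        if self.family not in _LINKS:
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def link(self) -> str:
        return _LINKS[self.family]

    def link_fn(self, mu):
        """Apply the link g to a mean value."""
        mu = np.asarray(mu, dtype=float)
        if self.family == "gaussian":
            return mu
        if self.family == "bernoulli":
            return np.log(mu) - np.log1p(-mu)
        return np.log(mu)

    def inverse_link(self, eta):
        eta = np.asarray(eta, dtype=float)
        if self.family == "gaussian":
            return eta
        if self.family == "bernoulli":
            return expit(eta)
        return np.exp(eta)


@dataclass
class ObservedData:
    """Outcome / predictor / optional covariates, validated for a family."""

    y: np.ndarray
    x: np.ndarray
    family: FamilySpec = field(default_factory=FamilySpec)
    Z: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.x = np.asarray(self.x, dtype=float).ravel()
        if self.y.size == 0:
            raise ValueError("empty outcome vector")
        if self.y.size != self.x.size:
            raise ValueError("outcome and predictor lengths differ")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.x))):
            raise ValueError("non-finite outcome or predictor values")
        fam = self.family.family
        if fam == "bernoulli" and not np.all(np.isin(self.y, (0.0, 1.0))):
            bad = int(np.flatnonzero(~np.isin(self.y, (0.0, 1.0)))[0])
            raise ValueError(f"Bernoulli outcome must be 0/1; row {bad} is {self.y[bad]}")
        if fam == "poisson" and (np.any(self.y < 0) or np.any(self.y != np.round(self.y))):
            bad = int(np.flatnonzero((self.y < 0) | (self.y != np.round(self.y)))[0])
            raise ValueError(f"Poisson outcome must be nonnegative integer; row {bad} is {self.y[bad]}")
        if self.Z is not None:
            self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
            if self.Z.shape[0] != self.y.size:
                raise ValueError("covariate row count does not match observations")
            if not np.all(np.isfinite(self.Z)):
                raise ValueError("non-finite covariate values")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return 0 if self.Z is None else self.Z.shape[1]


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the fixed priors.

    a, b : intercept prior mean and scale (on the link scale).
    c    : scale of the half-Cauchy prior on the global shrinkage tau.
    s    : scale of the half-Cauchy prior on the residual sd (Gaussian only).
    d    : per-coefficient normal prior scales for linear covariates.
    """

    a: float = 0.0
    b: float = 5.0
    c: float = 0.01
    s: float = 5.0
    d: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float).ravel())
        if self.b <= 0 or self.c <= 0 or self.s <= 0 or np.any(self.d <= 0):
            raise ValueError("prior scales b, c, s, d must all be positive")


def default_priors(y, family: FamilySpec = FamilySpec(), p: int = 0) -> PriorConfig:
    """Recommended default priors derived from the outcome.

    The intercept prior is centered at the link-transformed sample mean with
    scale five times the sample standard deviation; the global-shrinkage
    scale is c = 0.01; the residual-sd scale is s = 5; coefficient prior
    scales are 5 for a continuous outcome and 2.5 for a discrete one.  For
    discrete families the empirical mean is clamped away from the boundary of
    the link's domain before transforming.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty outcome vector")
    ybar = float(np.mean(y))
    sdy = float(np.std(y, ddof=1)) if y.size > 1 else 0.0

    if family.family == "gaussian":
        a = ybar
        b = 5.0 * sdy
    elif family.family == "bernoulli":
        a = float(family.link_fn(np.clip(ybar, 0.01, 0.99)))
        b = 5.0
    else:  # poisson
        a = float(family.link_fn(max(ybar, 0.01)))
        b = 5.0
    if b <= 0:
        warnings.warn("outcome has zero variance; falling back to intercept prior scale b = 5")
        b = 5.0

    d_scale = 5.0 if family.family == "gaussian" else 2.5
    return PriorConfig(a=a, b=b, c=0.01, s=5.0, d=np.full(p, d_scale))


@dataclass(frozen=True)
class CovariateScaler:
    """Centering/scaling applied to covariate columns; inverts beta to original units."""

    center: np.ndarray
    scale: np.ndarray
    is_binary: np.ndarray

    def transform(self, Z: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(Z, dtype=float)) - self.center) / self.scale

    def beta_to_original(self, beta: np.ndarray) -> np.ndarray:
        """Map coefficients on the scaled covariates back to original units."""
        return np.asarray(beta) / self.scale


def scale_covariates(Z, family: FamilySpec = FamilySpec()):
    """Center and scale covariates for stable default priors.

    Continuous columns are centered and rescaled to sd 1 (continuous outcome)
    or sd 0.5 (discrete outcome).  Binary 0/1 dummy columns are centered only,
    so their coefficients remain interpretable per level.  Constant columns
    are centered but left unscaled with a warning.

    Returns the transformed matrix and a :class:`CovariateScaler` record.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite covariate values")
    target_sd = 1.0 if family.family == "gaussian" else 0.5
    p = Z.shape[1]
    center = Z.mean(axis=0)
    scale = np.ones(p)
    is_binary = np.array([np.all(np.isin(col, (0.0, 1.0))) for col in Z.T])
    for j in range(p):
        if is_binary[j]:
            continue
        sd = Z[:, j].std(ddof=1) if Z.shape[0] > 1 else 0.0
        if sd == 0.0:
            warnings.warn(f"covariate column {j} is constant; centered but not scaled")
            continue
        scale[j] = sd / target_sd
    scaler = CovariateScaler(center=center, scale=scale, is_binary=is_binary)
    return scaler.transform(Z), scaler


@dataclass
class RawParams:
    """Non-centered sampler-space parameters (fixed priors).

    Unconstrained scalars/vectors carry standard-normal priors; the positive
    components (tau2, lambda2, sigma2) carry inverse-gamma(1/2, 1/2) priors.
    lambda1/lambda2/gamma have one entry per increment (k = 2..m).
    """

    alpha_raw: float
    tau1: float
    tau2: float
    lambda1: np.ndarray
    lambda2: np.ndarray
    gamma: np.ndarray
    sigma1: float = 1.0
    sigma2: float = 1.0
    beta_raw: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.lambda1 = np.asarray(self.lambda1, dtype=float).ravel()
        self.lambda2 = np.asarray(self.lambda2, dtype=float).ravel()
        self.gamma = np.asarray(self.gamma, dtype=float).ravel()
        self.beta_raw = np.asarray(self.beta_raw, dtype=float).ravel()
        if self.tau2 <= 0 or self.sigma2 <= 0 or np.any(self.lambda2 <= 0):
            raise ValueError("tau2, sigma2 and lambda2 must be positive")
        if not (self.lambda1.size == self.lambda2.size == self.gamma.size):
            raise ValueError("lambda1, lambda2, gamma must have equal length")


@dataclass
class TransformedParams:
    """Model-space parameters implied by a RawParams draw.

    h has one entry per gridpoint with h[0] = 0; f_grid[0] equals alpha.
    lam has one entry per increment (gridpoints 2..m).
    """

    alpha: float
    tau: float
    lam: np.ndarray
    h: np.ndarray
    f_grid: np.ndarray
    sigma: Optional[float] = None
    beta: np.ndarray = field(default_factory=lambda: np.empty(0))


def transform_raw(
    raw: RawParams,
    prior: PriorConfig,
    grid: Grid,
    constraint: Constraint = "none",
) -> TransformedParams:
    """Map sampler-space parameters to model space."""
    tau = prior.c * abs(raw.tau1) * np.sqrt(raw.tau2)
    lam = np.abs(raw.lambda1) * np.sqrt(raw.lambda2)
    alpha = prior.a + prior.b * raw.alpha_raw
    sigma = prior.s * abs(raw.sigma1) * np.sqrt(raw.sigma2)

    h = np.zeros(grid.m)
    h[1:] = raw.gamma * tau * lam * np.sqrt(grid.delta)
    if constraint == "none":
        f_grid = alpha + np.cumsum(h)
    elif constraint == "increasing":
        f_grid = alpha + np.cumsum(np.abs(h))
    elif constraint == "decreasing":
        f_grid = alpha - np.cumsum(np.abs(h))
    else:
        raise ValueError(f"unknown constraint {constraint!r}")

    beta = prior.d * raw.beta_raw if raw.beta_raw.size else np.empty(0)
    return TransformedParams(
        alpha=alpha, tau=tau, lam=lam, h=h, f_grid=f_grid, sigma=sigma, beta=beta
    )


def latent_mean(tp: TransformedParams, grid: Grid, Z: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-observation linear predictor eta_i = f(x_i) + beta . z_i."""
    eta = tp.f_grid[grid.obs_index]
    if Z is not None and tp.beta.size:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[0] != grid.obs_index.size:
            raise ValueError("covariate row count does not match observations")
        if Z.shape[1] != tp.beta.size:
            raise ValueError("covariate column count does not match beta")
        eta = eta + Z @ tp.beta
    return eta


# ---------------------------------------------------------------------------
# Log densities


def _log_invgamma_half_half(z) -> np.ndarray:
    # IG(1/2, 1/2): log p(z) = -log Gamma(1/2) + (1/2) log(1/2) - (3/2) log z - 1/(2z)
    z = np.asarray(z, dtype=float)
    return -gammaln(0.5) - 0.5 * np.log(2.0) - 1.5 * np.log(z) - 0.5 / z


def _log_std_normal(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return -0.5 * v * v - _HALF_LOG_2PI


def family_loglik(family: FamilySpec, y: np.ndarray, eta: np.ndarray, sigma=None) -> float:
    """Sum of log-likelihood terms for the outcome given the linear predictor."""
    if family.family == "gaussian":
        r = y - eta
        return float(-0.5 * np.sum(r * r) / sigma**2 - y.size * (np.log(sigma) + _HALF_LOG_2PI))
    if family.family == "bernoulli":
        # y*eta - log(1 + e^eta), stably
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))


def log_posterior(
    raw: RawParams,
    data: ObservedData,
    grid: Grid,
    prior: PriorConfig,
    constraint: Constraint = "none",
) -> float:
    """Log posterior density of a raw-parameter draw (up to a constant).

    Equals the sum of the fixed raw-parameter log priors (standard normal on
    the unconstrained components, inverse-gamma(1/2, 1/2) on the positive
    ones) and the family log-likelihood of y given the linear predictor.
    Augmentation gridpoints contribute prior terms only: the likelihood
    involves f at observed gridpoints alone.
    """
    tp = transform_raw(raw, prior, grid, constraint)
    lp = float(_log_std_normal(raw.alpha_raw) + _log_std_normal(raw.tau1))
    lp += float(_log_invgamma_half_half(raw.tau2))
    lp += float(np.sum(_log_std_normal(raw.lambda1)))
    lp += float(np.sum(_log_invgamma_half_half(raw.lambda2)))
    lp += float(np.sum(_log_std_normal(raw.gamma)))
    if data.family.family == "gaussian":
        lp += float(_log_std_normal(raw.sigma1) + _log_invgamma_half_half(raw.sigma2))
    if raw.beta_raw.size:
        lp += float(np.sum(_log_std_normal(raw.beta_raw)))
    eta = latent_mean(tp, grid, data.Z)
    lp += family_loglik(data.family, data.y, eta, tp.sigma)
    return lp


# ---------------------------------------------------------------------------
# Flat unconstrained parameterization for HMC
#
# Positive raw components are sampled on the log scale; the density below is
# log_posterior plus the log-Jacobian of those transforms.  Layout of the
# flat vector (K = m - 1 increments):
#   [alpha_raw, tau1, log tau2, lambda1 (K), log lambda2 (K), gamma (K),
#    sigma1, log sigma2 (gaussian only), beta_raw (p)]


class HPRPosterior:
    """Unconstrained-space log density and gradient of the HPR posterior.

    Used as the target for NUTS.  All gradients are analytic.
    """

    def __init__(
        self,
        data: ObservedData,
        grid: Grid,
        prior: PriorConfig,
        constraint: Constraint = "none",
    ):
        self.data = data
        self.grid = grid
        self.prior = prior
        self.constraint = constraint
        self.K = grid.m - 1
        self.p = data.p
        self.gaussian = data.family.family == "gaussian"
        self.dim = 3 + 3 * self.K + (2 if self.gaussian else 0) + self.p
        self._sqrt_delta = np.sqrt(grid.delta)
        # number of observations per gridpoint, for accumulating df-gradients
        self._obs_counts = np.bincount(grid.obs_index, minlength=grid.m)

    # -- layout helpers

    def _split(self, v: np.ndarray):
        K = self.K
        i = 3
        alpha_raw, tau1, ltau2 = v[0], v[1], v[2]
        lambda1 = v[i : i + K]
        llambda2 = v[i + K : i + 2 * K]
        gamma = v[i + 2 * K : i + 3 * K]
        i += 3 * K
        if self.gaussian:
            sigma1, lsigma2 = v[i], v[i + 1]
            i += 2
        else:
            sigma1, lsigma2 = 1.0, 0.0
        beta_raw = v[i : i + self.p]
        return alpha_raw, tau1, ltau2, lambda1, llambda2, gamma, sigma1, lsigma2, beta_raw

    def to_raw(self, v: np.ndarray) -> RawParams:
        a, t1, lt2, l1, ll2, g, s1, ls2, br = self._split(np.asarray(v, dtype=float))
        return RawParams(
            alpha_raw=float(a),
            tau1=float(t1),
            tau2=float(np.exp(lt2)),
            lambda1=l1.copy(),
            lambda2=np.exp(ll2),
            gamma=g.copy(),
            sigma1=float(s1),
            sigma2=float(np.exp(ls2)),
            beta_raw=br.copy(),
        )

    def from_raw(self, raw: RawParams) -> np.ndarray:
        parts = [
            np.array([raw.alpha_raw, raw.tau1, np.log(raw.tau2)]),
            raw.lambda1,
            np.log(raw.lambda2),
            raw.gamma,
        ]
        if self.gaussian:
            parts.append(np.array([raw.sigma1, np.log(raw.sigma2)]))
        parts.append(raw.beta_raw)
        return np.concatenate(parts)

    def transform(self, v: np.ndarray) -> TransformedParams:
        return transform_raw(self.to_raw(v), self.prior, self.grid, self.constraint)

    def logp(self, v: np.ndarray) -> float:
        """log_posterior plus the log-Jacobian of the log-scale transforms."""
        _, _, lt2, _, ll2, _, _, ls2, _ = self._split(np.asarray(v, dtype=float))
        jac = lt2 + np.sum(ll2) + (ls2 if self.gaussian else 0.0)
        return log_posterior(
            self.to_raw(v), self.data, self.grid, self.prior, self.constraint
        ) + float(jac)

    def logp_and_grad(self, v: np.ndarray):
        """Return (log density, gradient) on the unconstrained space."""
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._logp_and_grad(v)

    def _logp_and_grad(self, v: np.ndarray):
        prior, grid, data = self.prior, self.grid, self.data
        a_r, t1, lt2, l1, ll2, g, s1, ls2, br = self._split(np.asarray(v, dtype=float))

        e_lt2h = np.exp(0.5 * lt2)  # sqrt(tau2)
        e_ll2h = np.exp(0.5 * ll2)  # sqrt(lambda2)
        tau = prior.c * abs(t1) * e_lt2h
        lam = np.abs(l1) * e_ll2h
        alpha = prior.a + prior.b * a_r
        h = g * tau * lam * self._sqrt_delta  # increments k = 2..m

        if self.constraint == "none":
            f = alpha + np.concatenate(([0.0], np.cumsum(h)))
        elif self.constraint == "increasing":
            f = alpha + np.concatenate(([0.0], np.cumsum(np.abs(h))))
        else:
            f = alpha - np.concatenate(([0.0], np.cumsum(np.abs(h))))

        eta = f[grid.obs_index]
        beta = prior.d * br if self.p else np.empty(0)
        if self.p:
            eta = eta + data.Z @ beta

        y = data.y
        # log prior (with constants) + Jacobian of the log transforms
        lp = float(
            np.sum(_log_std_normal(np.concatenate(([a_r, t1], l1, g))))
            - gammaln(0.5) - 0.5 * np.log(2.0) - 0.5 * lt2 - 0.5 * np.exp(-lt2)
            + np.sum(-gammaln(0.5) - 0.5 * np.log(2.0) - 0.5 * ll2 - 0.5 * np.exp(-ll2))
        )
        if self.p:
            lp += float(np.sum(_log_std_normal(br)))

        # likelihood and d logp / d eta
        if self.gaussian:
            sigma = prior.s * abs(s1) * np.exp(0.5 * ls2)
            r = y - eta
            inv_s2 = 1.0 / (sigma * sigma)
            lp += float(_log_std_normal(s1)) + (
                -gammaln(0.5) - 0.5 * np.log(2.0) - 0.5 * ls2 - 0.5 * np.exp(-ls2)
            )
            lp += float(-0.5 * np.sum(r * r) * inv_s2 - y.size * (np.log(sigma) + _HALF_LOG_2PI))
            dl_deta = r * inv_s2
            dl_dsigma = float(np.sum(r * r) * inv_s2 / sigma - y.size / sigma)
        elif data.family.family == "bernoulli":
            lp += float(np.sum(y * eta - np.logaddexp(0.0, eta)))
            dl_deta = y - expit(eta)
            sigma = None
        else:
            mu = np.exp(eta)
            lp += float(np.sum(y * eta - mu - gammaln(y + 1.0)))
            dl_deta = y - mu
            sigma = None

        # accumulate gradient wrt f at each gridpoint
        df = np.bincount(grid.obs_index, weights=dl_deta, minlength=grid.m)
        # wrt alpha (every f_j contains alpha)
        d_alpha = float(df.sum())
        # wrt h_k: f_j depends on h_k for j >= k -> reverse cumulative sum
        S = np.cumsum(df[::-1])[::-1][1:]  # length K, S_k = sum_{j>=k} df_j
        if self.constraint == "none":
            dh = S
        elif self.constraint == "increasing":
            dh = S * np.sign(h)
        else:
            dh = -S * np.sign(h)

        grad = np.empty_like(np.asarray(v, dtype=float))
        grad[0] = -a_r + prior.b * d_alpha
        # dh -> gamma, lam, tau
        d_gamma = dh * tau * lam * self._sqrt_delta
        d_lam = dh * g * tau * self._sqrt_delta
        d_tau = float(np.sum(dh * g * lam * self._sqrt_delta))
        grad[1] = -t1 + d_tau * prior.c * np.sign(t1) * e_lt2h
        grad[2] = -0.5 + 0.5 * np.exp(-lt2) + 0.5 * d_tau * tau
        K = self.K
        grad[3 : 3 + K] = -l1 + d_lam * np.sign(l1) * e_ll2h
        grad[3 + K : 3 + 2 * K] = -0.5 + 0.5 * np.exp(-ll2) + 0.5 * d_lam * lam
        grad[3 + 2 * K : 3 + 3 * K] = -g + d_gamma
        i = 3 + 3 * K
        if self.gaussian:
            grad[i] = -s1 + dl_dsigma * prior.s * np.sign(s1) * np.exp(0.5 * ls2)
            grad[i + 1] = -0.5 + 0.5 * np.exp(-ls2) + 0.5 * dl_dsigma * sigma
            i += 2
        if self.p:
            grad[i:] = -br + prior.d * (data.Z.T @ dl_deta)
        return lp, grad

    def initial_point(self, rng: np.random.Generator, jitter: float = 0.1) -> np.ndarray:
        """Jittered start near the origin of the raw scale (log-scales at 0)."""
        return rng.uniform(-jitter, jitter, size=self.dim)

    # -- compiled fast path (numba kernels; exact restatement of the above)

    def _kernel_args(self):
        fam = {"gaussian": 0, "bernoulli": 1, "poisson": 2}[self.data.family.family]
        cons = {"none": 0, "increasing": 1, "decreasing": 2}[self.constraint]
        Z = self.data.Z if self.p else np.empty((self.data.n, 0))
        return (
            self.data.y,
            self.grid.obs_index.astype(np.int64),
            np.ascontiguousarray(Z, dtype=float),
            self._sqrt_delta,
            float(self.prior.a),
            float(self.prior.b),
            float(self.prior.c),
            float(self.prior.s),
            self.prior.d.astype(float),
            fam,
            cons,
        )

    def fast_logp_and_grad(self, v: np.ndarray):
        """Compiled equivalent of :meth:`logp_and_grad`."""
        from ._kernels import logp_grad

        grad = np.empty(self.dim)
        lp = logp_grad(np.asarray(v, dtype=float), grad, *self._kernel_args())
        return lp, grad

    def fast_transition(self):
        """Compiled NUTS transition closed over this posterior's data.

        Uses the kernel module's own RNG stream (seed it per chain with
        :func:`hpr._kernels.seed_rng`).
        """
        from ._kernels import transition

        args = self._kernel_args()

        def step(q, lp, grad, eps, inv_mass, max_treedepth):
            return transition(q, lp, grad, eps, inv_mass, max_treedepth, *args)

        return step
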