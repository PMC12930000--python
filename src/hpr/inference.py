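"""Posterior sampling, summaries and convergence diagnostics for HPR fits."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .grid import Grid, build_grid
from .model import (
    Constraint,
    FamilySpec,
    HPRPosterior,
    ObservedData,
    PriorConfig,
    default_priors,
)
from .nuts import sample_chain

__all__ = [
    "SamplerConfig",
    "PosteriorFit",
    "DiagnosticsReport",
    "fit_hpr",
    "summarize_posterior",
    "diagnostics_report",
]


@dataclass(frozen=True)
class SamplerConfig:
    """NUTS run configuration.

    Defaults mirror common practice for this model family: four chains with a
    1000-iteration warmup and 2000 retained iterations each (8000 retained
    draws total), no thinning, and a high 0.95 acceptance target to tame the
    funnel geometry induced by the shrinkage priors.
    """

    chains: int = 4
    warmup: int = 1000
    sampling: int = 2000
    seed: int = 0
    adapt_target: float = 0.95
    max_treedepth: int = 10
    init_retries: int = 4

    def __post_init__(self) -> None:
        if self.chains < 1 or self.warmup < 0 or self.sampling < 1:
            raise ValueError("chains and sampling must be >= 1, warmup >= 0")
        if not 0.0 < self.adapt_target < 1.0:
            raise ValueError("adapt_target must lie in (0, 1)")


@dataclass
class PosteriorFit:
    """Retained posterior draws of every model-space parameter.

    Arrays are indexed (chain, iteration[, component]); ``f`` has one column
    per gridpoint, ``lam``/``h`` one per increment (gridpoints 2..m), so
    serialized outputs pad position 1 with a null marker.
    """

    grid: Grid
    constraint: Constraint
    family: FamilySpec
    alpha: np.ndarray
    tau: np.ndarray
    lam: np.ndarray
    h: np.ndarray
    f: np.ndarray
    sigma: Optional[np.ndarray]
    beta: np.ndarray
    divergent: np.ndarray
    treedepth_hit: np.ndarray
    accept_stat: np.ndarray
    prior: PriorConfig = field(default_factory=PriorConfig)

    @property
    def n_draws(self) -> int:
        """Total retained draws across chains."""
        return self.f.shape[0] * self.f.shape[1]


@dataclass(frozen=True)
class DiagnosticsReport:
    """Sampler health summary with the field's rules of thumb.

    Sporadic divergences below five percent of retained iterations are
    treated as tolerable; above that, or when split-R-hat exceeds its cutoff,
    the verdict flips to "warn".
    """

    divergence_fraction: float
    treedepth_fraction: float
    worst_rhat: Optional[float]
    min_ess: float
    verdict: str
    divergence_threshold: float = 0.05
    rhat_threshold: float = 1.01


def fit_hpr(
    data: ObservedData,
    x_aug=None,
    prior: Optional[PriorConfig] = None,
    constraint: Constraint = "none",
    sampler: SamplerConfig = SamplerConfig(),
) -> PosteriorFit:
    """Sample the HPR posterior with NUTS.

    Parameters
    ----------
    data : ObservedData
        Outcome, predictor, optional (already scaled) covariates, family.
    x_aug : array-like, optional
        Augmentation points: predictor values without observations at which
        the latent function is interpolated/extrapolated.  Each receives its
        own local shrinkage and increment parameters, so it contributes prior
        terms only and leaves the posterior at observed points untouched.
    prior : PriorConfig, optional
        Defaults to :func:`default_priors` computed from the outcome.
    constraint : {"none", "increasing", "decreasing"}
    sampler : SamplerConfig

    Returns
    -------
    PosteriorFit with ``chains * sampling`` retained draws.  Identical data,
    configuration and seed reproduce identical draws.
    """
    grid = build_grid(data.x, x_aug)
    if prior is None:
        prior = default_priors(data.y, data.family, data.p)
    if data.p and prior.d.size != data.p:
        raise ValueError("prior.d length does not match covariate count")

    post = HPRPosterior(data, grid, prior, constraint)
    seeds = np.random.SeedSequence(sampler.seed).spawn(sampler.chains)
    step = post.fast_transition()

    from ._kernels import seed_rng

    chains = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        seed_rng(int(ss.generate_state(1, np.uint32)[0]))
        result = None
        for attempt in range(sampler.init_retries):
            q0 = post.initial_point(rng)
            try:
                result = sample_chain(
                    post.fast_logp_and_grad,
                    q0,
                    num_warmup=sampler.warmup,
                    num_draws=sampler.sampling,
                    rng=rng,
                    adapt_target=sampler.adapt_target,
                    max_treedepth=sampler.max_treedepth,
                    transition=step,
                )
                break
            except RuntimeError:
                if attempt == sampler.init_retries - 1:
                    raise
        chains.append(result)

    C, S, m = sampler.chains, sampler.sampling, grid.m
    K, p = m - 1, data.p
    gaussian = data.family.family == "gaussian"
    alpha = np.empty((C, S))
    tau = np.empty((C, S))
    lam = np.empty((C, S, K))
    h = np.empty((C, S, m))
    f = np.empty((C, S, m))
    sigma = np.empty((C, S)) if gaussian else None
    beta = np.empty((C, S, p))
    for ci, res in enumerate(chains):
        for si in range(S):
            tp = post.transform(res.positions[si])
            alpha[ci, si] = tp.alpha
            tau[ci, si] = tp.tau
            lam[ci, si] = tp.lam
            h[ci, si] = tp.h
            f[ci, si] = tp.f_grid
            if gaussian:
                sigma[ci, si] = tp.sigma
            if p:
                beta[ci, si] = tp.beta

    return PosteriorFit(
        grid=grid,
        constraint=constraint,
        family=data.family,
        alpha=alpha,
        tau=tau,
        lam=lam,
        h=h,
        f=f,
        sigma=sigma,
        beta=beta,
        divergent=np.stack([r.divergent for r in chains]),
        treedepth_hit=np.stack([r.treedepth_hit for r in chains]),
        accept_stat=np.stack([r.accept_stat for r in chains]),
        prior=prior,
    )


def summarize_posterior(
    fit: PosteriorFit,
    probs=(0.025, 0.975),
    point: str = "mean",
) -> pd.DataFrame:
    """Per-gridpoint posterior summary of the latent function.

    Returns a DataFrame with columns ``gridpoint`` (1-based), ``t``,
    ``is_observed``, ``point``, ``lower``, ``upper``.  The point estimate is
    the posterior mean by default (``point="median"`` for the median); bounds
    are empirical quantiles of the retained draws.
    """
    lo, hi = probs
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("probs must be strictly increasing within (0, 1)")
    if fit.n_draws == 0:
        raise ValueError("empty posterior fit")
    draws = fit.f.reshape(-1, fit.grid.m)
    est = np.mean(draws, axis=0) if point == "mean" else np.median(draws, axis=0)
    lower = np.quantile(draws, lo, axis=0)
    upper = np.quantile(draws, hi, axis=0)
    return pd.DataFrame(
        {
            "gridpoint": np.arange(1, fit.grid.m + 1),
            "t": fit.grid.t,
            "is_observed": fit.grid.is_observed,
            "point": est,
            "lower": lower,
            "upper": upper,
        }
    )


def _core_draw_dict(fit: PosteriorFit) -> dict:
    out = {"alpha": fit.alpha, "tau": fit.tau, "f": fit.f}
    if fit.sigma is not None:
        out["sigma"] = fit.sigma
    if fit.beta.shape[-1]:
        out["beta"] = fit.beta
    return out


def diagnostics_report(
    fit: PosteriorFit,
    divergence_threshold: float = 0.05,
    rhat_threshold: float = 1.01,
) -> DiagnosticsReport:
    """Divergence/treedepth fractions, worst split-R-hat and minimum ESS.

    Fractions are over retained post-warmup iterations.  R-hat is reported as
    unavailable for a single chain; bulk ESS is still computed.
    """
    import arviz as az

    if fit.n_draws == 0:
        raise ValueError("empty posterior fit")
    div_frac = float(np.mean(fit.divergent))
    depth_frac = float(np.mean(fit.treedepth_hit))
    core = _core_draw_dict(fit)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=core)
        ess = az.ess(idata)
        min_ess = float(min(ess[v].values.min() for v in core))
        if fit.alpha.shape[0] > 1:
            rhat = az.rhat(idata)
            worst_rhat = float(max(rhat[v].values.max() for v in core))
        else:
            worst_rhat = None
    warn = div_frac >= divergence_threshold or (
        worst_rhat is not None and worst_rhat > rhat_threshold
    )
    return DiagnosticsReport(
        divergence_fraction=div_frac,
        treedepth_fraction=depth_frac,
        worst_rhat=worst_rhat,
        min_ess=min_ess,
        verdict="warn" if warn else "ok",
        divergence_threshold=divergence_threshold,
        rhat_threshold=rhat_threshold,
    )
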