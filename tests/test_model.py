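import numpy as np
import pytest
from scipy import stats

from hpr import (
    FamilySpec,
    ObservedData,
    PriorConfig,
    RawParams,
    build_grid,
    default_priors,
    latent_mean,
    log_posterior,
    scale_covariates,
    transform_raw,
)
from hpr.model import HPRPosterior, family_loglik


def random_raw(rng, m, p=0, gaussian=True):
    K = m - 1
    return RawParams(
        alpha_raw=rng.normal(),
        tau1=rng.normal(),
        tau2=1.0 / rng.gamma(0.5, 2.0),
        lambda1=rng.normal(size=K),
        lambda2=1.0 / rng.gamma(0.5, 2.0, size=K),
        gamma=rng.normal(size=K),
        sigma1=rng.normal() if gaussian else 1.0,
        sigma2=1.0 / rng.gamma(0.5, 2.0) if gaussian else 1.0,
        beta_raw=rng.normal(size=p),
    )


# ---------------------------------------------------------------------------
# default priors and covariate scaling


def test_default_priors_gaussian_follow_outcome_moments():
    y = np.array([1.0, 2.0, 3.0])  # mean 2, sd 1
    pr = default_priors(y, FamilySpec("gaussian"))
    assert pr.a == pytest.approx(2.0)
    assert pr.b == pytest.approx(5.0)
    assert pr.c == 0.01 and pr.s == 5.0


@pytest.mark.parametrize(
    "family,expected_d", [("gaussian", 5.0), ("poisson", 2.5), ("bernoulli", 2.5)]
)
def test_coefficient_prior_scale_by_outcome_type(family, expected_d):
    y = {"gaussian": [0.1, 2.3, 1.0], "poisson": [0, 3, 1], "bernoulli": [0, 1, 1]}[family]
    pr = default_priors(np.array(y, dtype=float), FamilySpec(family), p=2)
    assert np.allclose(pr.d, expected_d)


def test_discrete_intercept_prior_is_on_link_scale():
    y = np.array([0.0, 1.0, 1.0, 1.0])
    pr = default_priors(y, FamilySpec("bernoulli"))
    assert pr.a == pytest.approx(np.log(0.75 / 0.25))
    y = np.zeros(5)
    pr = default_priors(y, FamilySpec("bernoulli"))  # clamped at 0.01
    assert pr.a == pytest.approx(np.log(0.01 / 0.99))
    pr = default_priors(np.array([2.0, 4.0]), FamilySpec("poisson"))
    assert pr.a == pytest.approx(np.log(3.0))


def test_constant_outcome_falls_back_with_warning():
    with pytest.warns(UserWarning, match="zero variance"):
        pr = default_priors(np.full(4, 7.0), FamilySpec("gaussian"))
    assert pr.b == 5.0


def test_continuous_covariates_scaled_by_outcome_type(rng):
    Z = rng.normal(0.0, 4.0, size=(200, 1))
    Zs, rec = scale_covariates(Z, FamilySpec("gaussian"))
    assert Zs[:, 0].std(ddof=1) == pytest.approx(1.0)
    assert rec.scale[0] == pytest.approx(Z[:, 0].std(ddof=1))
    Zs, rec = scale_covariates(Z, FamilySpec("poisson"))
    assert Zs[:, 0].std(ddof=1) == pytest.approx(0.5)
    assert rec.scale[0] == pytest.approx(Z[:, 0].std(ddof=1) / 0.5)


def test_dummy_columns_centered_not_scaled(rng):
    Z = np.column_stack([rng.integers(0, 2, 100).astype(float), rng.normal(size=100)])
    Zs, rec = scale_covariates(Z)
    assert rec.is_binary[0] and not rec.is_binary[1]
    assert rec.scale[0] == 1.0
    assert Zs[:, 0].mean() == pytest.approx(0.0)


def test_constant_column_left_unscaled_with_warning():
    Z = np.column_stack([np.full(5, 3.0)])
    with pytest.warns(UserWarning, match="constant"):
        Zs, rec = scale_covariates(Z)
    assert rec.scale[0] == 1.0
    assert np.allclose(Zs, 0.0)


def test_beta_back_transform_roundtrip(rng):
    Z = rng.normal(2.0, 3.0, size=(50, 2))
    Zs, rec = scale_covariates(Z)
    beta_scaled = np.array([1.0, -2.0])
    beta_orig = rec.beta_to_original(beta_scaled)
    # identical linear predictor contribution up to centering
    assert np.allclose(Zs @ beta_scaled, (Z - rec.center) @ beta_orig)


# ---------------------------------------------------------------------------
# transforms


def test_zero_increments_give_constant_function(rng):
    grid = build_grid(rng.uniform(0, 10, 8))
    raw = random_raw(rng, grid.m)
    raw.gamma = np.zeros(grid.m - 1)
    tp = transform_raw(raw, PriorConfig(a=1.0, b=2.0), grid)
    assert np.allclose(tp.h, 0.0)
    assert np.allclose(tp.f_grid, tp.alpha)
    assert tp.f_grid[0] == pytest.approx(tp.alpha)


@pytest.mark.parametrize("constraint,comparator", [("increasing", np.greater_equal),
                                                   ("decreasing", np.less_equal)])
def test_monotone_constraint_forced_by_transform(rng, constraint, comparator):
    grid = build_grid(rng.uniform(0, 10, 10))
    for _ in range(20):
        raw = random_raw(rng, grid.m)
        tp = transform_raw(raw, PriorConfig(), grid, constraint)
        assert np.all(comparator(np.diff(tp.f_grid), 0.0))


def test_increment_variance_matches_shrinkage_scales(rng):
    # Var(h_k | tau, lambda_k) = tau^2 lambda_k^2 delta_k over gamma draws
    grid = build_grid([0.0, 1.0, 3.0, 7.0])
    prior = PriorConfig(c=0.5)
    raw = random_raw(rng, grid.m)
    draws = []
    for _ in range(20000):
        raw.gamma = rng.normal(size=grid.m - 1)
        draws.append(transform_raw(raw, prior, grid).h[1:])
    emp = np.var(np.asarray(draws), axis=0)
    tp = transform_raw(raw, prior, grid)
    expected = tp.tau**2 * tp.lam**2 * grid.delta
    assert np.allclose(emp, expected, rtol=0.05)


def test_decentered_tau_matches_half_cauchy_law(rng):
    # |N(0,1)| * sqrt(InvGamma(1/2,1/2)) scaled by c is half-Cauchy(0, c)
    n = 100_000
    c = 0.01
    tau1 = rng.normal(size=n)
    tau2 = stats.invgamma(a=0.5, scale=0.5).rvs(size=n, random_state=rng)
    tau = c * np.abs(tau1) * np.sqrt(tau2)
    direct = stats.halfcauchy(scale=c).rvs(size=n, random_state=rng)
    assert stats.ks_2samp(tau, direct).pvalue > 0.01


def test_global_shrinkage_limit_flattens_function(rng):
    grid = build_grid(rng.uniform(0, 10, 12))
    raw = random_raw(rng, grid.m)
    sups = []
    for c in [1.0, 1e-2, 1e-4, 1e-8]:
        tp = transform_raw(raw, PriorConfig(a=0.0, b=1.0, c=c), grid)
        sups.append(np.max(np.abs(tp.f_grid - tp.alpha)))
    assert all(a > b for a, b in zip(sups, sups[1:]))
    assert sups[-1] < 1e-6


def test_latent_mean_with_and_without_covariates(rng):
    grid = build_grid([0.0, 1.0, 2.0])
    raw = random_raw(rng, grid.m, p=1)
    prior = PriorConfig(d=[2.0])
    tp = transform_raw(raw, prior, grid)
    eta0 = latent_mean(tp, grid)
    assert np.allclose(eta0, tp.f_grid[grid.obs_index])
    # beta = 0 reduces to the no-covariate case
    tp.beta = np.zeros(1)
    assert np.allclose(latent_mean(tp, grid, np.ones((3, 1))), eta0)
    # unit covariate shifts everything by beta
    tp.beta = np.array([2.0])
    assert np.allclose(latent_mean(tp, grid, np.ones((3, 1))), eta0 + 2.0)
    with pytest.raises(ValueError):
        latent_mean(tp, grid, np.ones((5, 1)))


# ---------------------------------------------------------------------------
# log posterior


def oracle_log_posterior(raw, data, grid, prior, constraint="none"):
    """Independent term-by-term evaluation via scipy.stats distributions."""
    lp = stats.norm.logpdf(raw.alpha_raw) + stats.norm.logpdf(raw.tau1)
    lp += stats.invgamma.logpdf(raw.tau2, a=0.5, scale=0.5)
    lp += stats.norm.logpdf(raw.lambda1).sum()
    lp += stats.invgamma.logpdf(raw.lambda2, a=0.5, scale=0.5).sum()
    lp += stats.norm.logpdf(raw.gamma).sum()
    if data.family.family == "gaussian":
        lp += stats.norm.logpdf(raw.sigma1)
        lp += stats.invgamma.logpdf(raw.sigma2, a=0.5, scale=0.5)
    lp += stats.norm.logpdf(raw.beta_raw).sum()

    tau = prior.c * abs(raw.tau1) * np.sqrt(raw.tau2)
    lam = np.abs(raw.lambda1) * np.sqrt(raw.lambda2)
    sigma = prior.s * abs(raw.sigma1) * np.sqrt(raw.sigma2)
    alpha = prior.a + prior.b * raw.alpha_raw
    beta = prior.d * raw.beta_raw
    sign = {"none": 1.0, "increasing": 1.0, "decreasing": -1.0}[constraint]
    for i in range(data.n):
        j = grid.obs_index[i]
        f = alpha
        for k in range(1, j + 1):
            h_k = raw.gamma[k - 1] * tau * lam[k - 1] * np.sqrt(grid.delta[k - 1])
            f += h_k if constraint == "none" else sign * abs(h_k)
        if data.Z is not None:
            f += float(data.Z[i] @ beta)
        if data.family.family == "gaussian":
            lp += stats.norm.logpdf(data.y[i], f, sigma)
        elif data.family.family == "bernoulli":
            lp += stats.bernoulli.logpmf(data.y[i], 1.0 / (1.0 + np.exp(-f)))
        else:
            lp += stats.poisson.logpmf(data.y[i], np.exp(f))
    return float(lp)


@pytest.mark.parametrize("family", ["gaussian", "bernoulli", "poisson"])
@pytest.mark.parametrize("p", [0, 1])
@pytest.mark.parametrize("constraint", ["none", "increasing"])
def test_log_posterior_matches_term_by_term_oracle(rng, family, p, constraint):
    x = np.array([0.0, 1.5, 1.5, 4.0])  # m = 3 with a repeated value
    y = {"gaussian": np.array([0.2, -1.0, 0.5, 2.0]),
         "bernoulli": np.array([0.0, 1.0, 1.0, 0.0]),
         "poisson": np.array([1.0, 0.0, 2.0, 4.0])}[family]
    Z = rng.normal(size=(4, p)) if p else None
    data = ObservedData(y=y, x=x, family=FamilySpec(family), Z=Z)
    grid = build_grid(x)
    prior = PriorConfig(a=0.3, b=2.0, c=0.05, s=5.0, d=np.full(p, 2.5))
    for _ in range(5):
        raw = random_raw(rng, grid.m, p=p, gaussian=family == "gaussian")
        got = log_posterior(raw, data, grid, prior, constraint)
        want = oracle_log_posterior(raw, data, grid, prior, constraint)
        assert got == pytest.approx(want, rel=1e-10)


def test_single_observation_hand_computed_density():
    # one Gaussian observation y=0 at the sole gridpoint: the posterior is
    # normal prior terms + one normal likelihood term, assembled by hand
    data = ObservedData(y=[0.0], x=[2.0])
    grid = build_grid([2.0])
    prior = PriorConfig(a=1.0, b=2.0)
    raw = RawParams(alpha_raw=0.5, tau1=1.0, tau2=1.0, lambda1=[], lambda2=[],
                    gamma=[], sigma1=0.4, sigma2=1.0)
    sigma = 5.0 * 0.4  # s * |sigma1| * sqrt(sigma2)
    alpha = 1.0 + 2.0 * 0.5
    by_hand = (
        stats.norm.logpdf(0.5) + stats.norm.logpdf(1.0)
        + stats.invgamma.logpdf(1.0, a=0.5, scale=0.5) * 2
        + stats.norm.logpdf(0.4)
        + stats.norm.logpdf(0.0, alpha, sigma)
    )
    assert log_posterior(raw, data, grid, prior) == pytest.approx(by_hand, rel=1e-12)


def test_extrapolation_point_changes_prior_but_not_likelihood(rng):
    x = np.array([0.0, 2.0, 5.0])
    data = ObservedData(y=[1.0, 0.0, 2.0], x=x)
    grid = build_grid(x, x_aug=[8.0])
    prior = PriorConfig()
    raw = random_raw(rng, grid.m)
    raw2 = random_raw(rng, grid.m)
    # perturb only the trailing (augmentation) increment parameters
    for arr_name in ("lambda1", "lambda2", "gamma"):
        arr = getattr(raw2, arr_name).copy()
        arr[:-1] = getattr(raw, arr_name)[:-1]
        setattr(raw2, arr_name, arr)
    for scalar in ("alpha_raw", "tau1", "tau2", "sigma1", "sigma2"):
        setattr(raw2, scalar, getattr(raw, scalar))
    lik = lambda r: family_loglik(  # noqa: E731
        data.family, data.y,
        latent_mean(transform_raw(r, prior, grid), grid),
        transform_raw(r, prior, grid).sigma,
    )
    assert lik(raw) == pytest.approx(lik(raw2), rel=1e-12)
    assert log_posterior(raw, data, grid, prior) != pytest.approx(
        log_posterior(raw2, data, grid, prior), rel=1e-12
    )


def test_rescaled_spacings_compensated_by_gamma_leave_likelihood_unchanged(rng):
    # stretching t doubles every spacing; shrinking gamma by 1/sqrt(2)
    # reproduces the same increments, hence the same likelihood term
    x = np.array([0.0, 1.0, 3.0, 6.0])
    y = np.array([0.1, 1.2, -0.4, 0.9])
    grid1, grid2 = build_grid(x), build_grid(2.0 * x)
    prior = PriorConfig()
    raw = random_raw(rng, grid1.m)
    raw2 = RawParams(**{**raw.__dict__, "gamma": raw.gamma / np.sqrt(2.0)})
    tp1 = transform_raw(raw, prior, grid1)
    tp2 = transform_raw(raw2, prior, grid2)
    assert np.allclose(tp1.h, tp2.h, rtol=1e-12)
    fam = FamilySpec("gaussian")
    l1 = family_loglik(fam, y, latent_mean(tp1, grid1), tp1.sigma)
    l2 = family_loglik(fam, y, latent_mean(tp2, grid2), tp2.sigma)
    assert l1 == pytest.approx(l2, rel=1e-12)


@pytest.mark.parametrize("family,bad_y", [("bernoulli", [0.0, 2.0]), ("poisson", [1.0, -1.0]),
                                          ("poisson", [1.0, 2.5])])
def test_invalid_outcomes_for_family_rejected(family, bad_y):
    with pytest.raises(ValueError):
        ObservedData(y=bad_y, x=[0.0, 1.0], family=FamilySpec(family))


# ---------------------------------------------------------------------------
# unconstrained-space machinery


@pytest.mark.parametrize("family,constraint,p", [
    ("gaussian", "none", 0), ("gaussian", "increasing", 2),
    ("bernoulli", "none", 1), ("poisson", "decreasing", 0),
])
def test_unconstrained_gradient_matches_finite_differences(rng, family, constraint, p):
    n = 10
    x = rng.uniform(0, 10, n)
    y = {"gaussian": rng.normal(size=n),
         "bernoulli": rng.integers(0, 2, n).astype(float),
         "poisson": rng.poisson(2.0, n).astype(float)}[family]
    Z = rng.normal(size=(n, p)) if p else None
    data = ObservedData(y=y, x=x, family=FamilySpec(family), Z=Z)
    fam = FamilySpec(family)
    post = HPRPosterior(data, build_grid(x, [2.5]), default_priors(y, fam, p), constraint)
    v = rng.normal(size=post.dim) * 0.5
    lp, grad = post.logp_and_grad(v)
    assert lp == pytest.approx(post.logp(v), rel=1e-10)
    eps = 1e-6
    for i in range(post.dim):
        vp, vm = v.copy(), v.copy()
        vp[i] += eps
        vm[i] -= eps
        fd = (post.logp(vp) - post.logp(vm)) / (2 * eps)
        assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)


@pytest.mark.parametrize("family,constraint,p", [
    ("gaussian", "none", 0), ("gaussian", "decreasing", 1),
    ("bernoulli", "increasing", 0), ("poisson", "none", 2),
])
def test_compiled_kernel_agrees_with_reference(rng, family, constraint, p):
    n = 14
    x = rng.uniform(0, 10, n)
    y = {"gaussian": rng.normal(size=n),
         "bernoulli": rng.integers(0, 2, n).astype(float),
         "poisson": rng.poisson(2.0, n).astype(float)}[family]
    Z = rng.normal(size=(n, p)) if p else None
    data = ObservedData(y=y, x=x, family=FamilySpec(family), Z=Z)
    fam = FamilySpec(family)
    post = HPRPosterior(data, build_grid(x, [1.25, 11.0]), default_priors(y, fam, p), constraint)
    for _ in range(5):
        v = rng.normal(size=post.dim)
        lp_ref, g_ref = post.logp_and_grad(v)
        lp_fast, g_fast = post.fast_logp_and_grad(v)
        assert lp_fast == pytest.approx(lp_ref, rel=1e-10)
        assert np.allclose(g_fast, g_ref, rtol=1e-9, atol=1e-9)


def test_raw_roundtrip_through_flat_vector(rng):
    x = rng.uniform(0, 10, 6)
    data = ObservedData(y=rng.normal(size=6), x=x, Z=rng.normal(size=(6, 2)))
    post = HPRPosterior(data, build_grid(x), default_priors(data.y, p=2))
    raw = random_raw(rng, post.grid.m, p=2)
    back = post.to_raw(post.from_raw(raw))
    for name in ("alpha_raw", "tau1", "tau2", "sigma1", "sigma2"):
        assert getattr(back, name) == pytest.approx(getattr(raw, name), rel=1e-12)
    for name in ("lambda1", "lambda2", "gamma", "beta_raw"):
        assert np.allclose(getattr(back, name), getattr(raw, name), rtol=1e-12)
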