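"""Numba kernels: HPR log-posterior gradient and one NUTS transition.

The model gradient here is an exact, loop-based restatement of
``HPRPosterior.logp_and_grad`` (tested for equality against it); the
transition is an iterative formulation of the same doubling/slice NUTS as
``hpr.nuts``, with subtree U-turn checks done via power-of-two checkpoints
instead of recursion.  Everything runs in nopython mode so that the hot
leapfrog loop costs microseconds rather than Python-call overhead.

Family codes: 0 gaussian, 1 bernoulli, 2 poisson.
Constraint codes: 0 none, 1 increasing, 2 decreasing.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_HALF_LOG_2PI = 0.5 * math.log(2.0 * math.pi)
_LOG_GAMMA_HALF = math.lgamma(0.5)
_ENERGY_DIVERGENCE = 1000.0
_EXP_GUARD = 600.0


@njit(cache=False)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=False)
def logp_grad(v, grad, y, obs_idx, Z, sqrt_delta, a, b, c, s, d, fam, cons):
    """Log density and gradient on the unconstrained space; writes grad in place."""
    K = sqrt_delta.size
    m = K + 1
    n = y.size
    p = d.size
    gaussian = fam == 0

    a_r = v[0]
    t1 = v[1]
    lt2 = v[2]
    i0 = 3 + 3 * K
    if gaussian:
        s1 = v[i0]
        ls2 = v[i0 + 1]
        ib = i0 + 2
    else:
        s1 = 1.0
        ls2 = 0.0
        ib = i0

    # heavy-tailed log-scale parameters can transiently overflow exp during
    # step-size search; treat that region as zero density
    guard = abs(lt2) > _EXP_GUARD or (gaussian and abs(ls2) > _EXP_GUARD)
    for k in range(K):
        if abs(v[3 + K + k]) > _EXP_GUARD:
            guard = True
    if guard:
        for i in range(v.size):
            grad[i] = 0.0
        return -np.inf

    e_lt2h = math.exp(0.5 * lt2)
    tau = c * abs(t1) * e_lt2h
    alpha = a + b * a_r

    lam = np.empty(K)
    h = np.empty(K)
    lp = (
        -0.5 * a_r * a_r - 0.5 * t1 * t1 - 2.0 * _HALF_LOG_2PI
        - _LOG_GAMMA_HALF - 0.5 * math.log(2.0) - 0.5 * lt2 - 0.5 * math.exp(-lt2)
    )
    for k in range(K):
        l1k = v[3 + k]
        ll2k = v[3 + K + k]
        gk = v[3 + 2 * K + k]
        lam[k] = abs(l1k) * math.exp(0.5 * ll2k)
        h[k] = gk * tau * lam[k] * sqrt_delta[k]
        lp += (
            -0.5 * l1k * l1k - 0.5 * gk * gk - 2.0 * _HALF_LOG_2PI
            - _LOG_GAMMA_HALF - 0.5 * math.log(2.0) - 0.5 * ll2k - 0.5 * math.exp(-ll2k)
        )

    # latent function at gridpoints
    f = np.empty(m)
    f[0] = alpha
    if cons == 0:
        for k in range(K):
            f[k + 1] = f[k] + h[k]
    elif cons == 1:
        for k in range(K):
            f[k + 1] = f[k] + abs(h[k])
    else:
        for k in range(K):
            f[k + 1] = f[k] - abs(h[k])

    beta = np.empty(p)
    for j in range(p):
        br = v[ib + j]
        beta[j] = d[j] * br
        lp += -0.5 * br * br - _HALF_LOG_2PI

    eta = np.empty(n)
    for i in range(n):
        e = f[obs_idx[i]]
        for j in range(p):
            e += Z[i, j] * beta[j]
        eta[i] = e

    dl_deta = np.empty(n)
    dl_dsigma = 0.0
    sigma = 1.0
    if gaussian:
        sigma = s * abs(s1) * math.exp(0.5 * ls2)
        lp += (
            -0.5 * s1 * s1 - _HALF_LOG_2PI
            - _LOG_GAMMA_HALF - 0.5 * math.log(2.0) - 0.5 * ls2 - 0.5 * math.exp(-ls2)
        )
        inv_s2 = 1.0 / (sigma * sigma)
        ssq = 0.0
        for i in range(n):
            r = y[i] - eta[i]
            ssq += r * r
            dl_deta[i] = r * inv_s2
        lp += -0.5 * ssq * inv_s2 - n * (math.log(sigma) + _HALF_LOG_2PI)
        dl_dsigma = ssq * inv_s2 / sigma - n / sigma
    elif fam == 1:
        for i in range(n):
            e = eta[i]
            # log(1 + exp(e)) stably
            lse = e + math.log1p(math.exp(-e)) if e > 0 else math.log1p(math.exp(e))
            lp += y[i] * e - lse
            dl_deta[i] = y[i] - 1.0 / (1.0 + math.exp(-e))
    else:
        for i in range(n):
            e = eta[i]
            if e > _EXP_GUARD:
                for ii in range(v.size):
                    grad[ii] = 0.0
                return -np.inf
            mu = math.exp(e)
            lp += y[i] * e - mu - math.lgamma(y[i] + 1.0)
            dl_deta[i] = y[i] - mu

    if not np.isfinite(lp):
        for i in range(v.size):
            grad[i] = 0.0
        return -np.inf

    df = np.zeros(m)
    for i in range(n):
        df[obs_idx[i]] += dl_deta[i]

    # S_k = sum_{j >= k} df_j over increments k = 1..K (0-based k-1)
    S = np.empty(K)
    acc = 0.0
    for k in range(K - 1, -1, -1):
        acc += df[k + 1]
        S[k] = acc
    d_alpha = acc + df[0]

    d_tau = 0.0
    for k in range(K):
        if cons == 0:
            dh = S[k]
        elif cons == 1:
            dh = S[k] * (1.0 if h[k] > 0 else (-1.0 if h[k] < 0 else 0.0))
        else:
            dh = -S[k] * (1.0 if h[k] > 0 else (-1.0 if h[k] < 0 else 0.0))
        l1k = v[3 + k]
        gk = v[3 + 2 * K + k]
        ll2k = v[3 + K + k]
        d_gamma = dh * tau * lam[k] * sqrt_delta[k]
        d_lam = dh * gk * tau * sqrt_delta[k]
        d_tau += dh * gk * lam[k] * sqrt_delta[k]
        sgn_l1 = 1.0 if l1k > 0 else (-1.0 if l1k < 0 else 0.0)
        grad[3 + k] = -l1k + d_lam * sgn_l1 * math.exp(0.5 * ll2k)
        grad[3 + K + k] = -0.5 + 0.5 * math.exp(-ll2k) + 0.5 * d_lam * lam[k]
        grad[3 + 2 * K + k] = -gk + d_gamma

    grad[0] = -a_r + b * d_alpha
    sgn_t1 = 1.0 if t1 > 0 else (-1.0 if t1 < 0 else 0.0)
    grad[1] = -t1 + d_tau * c * sgn_t1 * e_lt2h
    grad[2] = -0.5 + 0.5 * math.exp(-lt2) + 0.5 * d_tau * tau
    if gaussian:
        sgn_s1 = 1.0 if s1 > 0 else (-1.0 if s1 < 0 else 0.0)
        grad[i0] = -s1 + dl_dsigma * s * sgn_s1 * math.exp(0.5 * ls2)
        grad[i0 + 1] = -0.5 + 0.5 * math.exp(-ls2) + 0.5 * dl_dsigma * sigma
    for j in range(p):
        acc_b = 0.0
        for i in range(n):
            acc_b += Z[i, j] * dl_deta[i]
        grad[ib + j] = -v[ib + j] + d[j] * acc_b
    return lp


@njit(cache=False)
def _kinetic(p, inv_mass):
    acc = 0.0
    for i in range(p.size):
        acc += p[i] * p[i] * inv_mass[i]
    return 0.5 * acc


@njit(cache=False)
def _uturn(dq, p_a, p_b, inv_mass, direction):
    da = 0.0
    db = 0.0
    for i in range(dq.size):
        da += dq[i] * inv_mass[i] * p_a[i]
        db += dq[i] * inv_mass[i] * p_b[i]
    return direction * da < 0.0 or direction * db < 0.0


@njit(cache=False)
def transition(
    q, lp, grad, eps, inv_mass, max_treedepth,
    y, obs_idx, Z, sqrt_delta, a, b, c, s, d, fam, cons,
):
    """One NUTS update.  Returns (q, lp, grad, divergent, hit_max, accept)."""
    dim = q.size
    p0 = np.random.standard_normal(dim)
    for i in range(dim):
        p0[i] /= math.sqrt(inv_mass[i])
    joint0 = lp - _kinetic(p0, inv_mass)
    log_u = joint0 - np.random.exponential()

    # tree endpoints (time-backward minus, time-forward plus)
    qm = q.copy(); pm = p0.copy(); gm = grad.copy()
    qp = q.copy(); pp = p0.copy(); gp = grad.copy()
    q_cur = q.copy(); lp_cur = lp; grad_cur = grad.copy()
    n_cur = 1
    divergent = False
    hit_max = False
    sum_accept = 0.0
    n_leapfrog = 0

    # checkpoints of subtree start leaves, by trailing-zero level
    ckpt_q = np.empty((max_treedepth + 1, dim))
    ckpt_p = np.empty((max_treedepth + 1, dim))

    depth = 0
    while depth < max_treedepth:
        direction = 1.0 if np.random.random() < 0.5 else -1.0
        if direction > 0:
            sq = qp; sp = pp; sg = gp
        else:
            sq = qm; sp = pm; sg = gm
        # build subtree of 2**depth leaves from (sq, sp, sg)
        n_sub = 0
        keep = True
        q_sub = q_cur  # placeholder; only used if n_sub > 0
        lp_sub = lp_cur
        g_sub = grad_cur
        n_leaves = 1 << depth
        wq = sq.copy(); wp = sp.copy(); wg = sg.copy()
        for leaf in range(n_leaves):
            # leapfrog one step in direction
            heps = direction * eps
            wp = wp + 0.5 * heps * wg
            wq = wq + heps * inv_mass * wp
            wg_new = np.empty(dim)
            lp_new = logp_grad(wq, wg_new, y, obs_idx, Z, sqrt_delta,
                               a, b, c, s, d, fam, cons)
            wg = wg_new
            wp = wp + 0.5 * heps * wg
            n_leapfrog += 1
            joint = lp_new - _kinetic(wp, inv_mass)
            if not np.isfinite(joint):
                joint = -np.inf
            if joint - joint0 > 0:
                sum_accept += 1.0
            else:
                sum_accept += math.exp(joint - joint0)
            if log_u >= joint + _ENERGY_DIVERGENCE:
                divergent = True
                keep = False
                break
            if log_u <= joint:
                n_sub += 1
                if np.random.random() < 1.0 / n_sub:
                    q_sub = wq.copy()
                    lp_sub = lp_new
                    g_sub = wg.copy()
            # checkpoint store / U-turn checks within the subtree
            if leaf % 2 == 0:
                z = depth
                if leaf > 0:
                    z = 0
                    while (leaf >> z) & 1 == 0:
                        z += 1
                ckpt_q[z] = wq
                ckpt_p[z] = wp
            else:
                span = 1
                i_leaf = leaf
                while i_leaf & 1:
                    start = leaf + 1 - 2 * span
                    z = depth
                    if start > 0:
                        z = 0
                        while (start >> z) & 1 == 0:
                            z += 1
                    if _uturn(wq - ckpt_q[z], ckpt_p[z], wp, inv_mass, direction):
                        keep = False
                        break
                    span <<= 1
                    i_leaf >>= 1
                if not keep:
                    break
        if keep or divergent:
            # subtree endpoints become the new tree endpoint on this side
            if direction > 0:
                qp = wq; pp = wp; gp = wg
            else:
                qm = wq; pm = wp; gm = wg
        if not keep:
            break
        if n_sub > 0 and np.random.random() < n_sub / n_cur:
            q_cur = q_sub
            lp_cur = lp_sub
            grad_cur = g_sub
        n_cur += n_sub
        depth += 1
        if _uturn(qp - qm, pm, pp, inv_mass, 1.0):
            break
        if depth == max_treedepth:
            hit_max = True

    accept = sum_accept / n_leapfrog if n_leapfrog > 0 else 0.0
    return q_cur, lp_cur, grad_cur, divergent, hit_max, accept
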