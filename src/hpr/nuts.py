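"""No-U-Turn sampler with dual-averaging step size and diagonal mass adaptation.

A self-contained implementation of dynamic Hamiltonian Monte Carlo for an
arbitrary differentiable log density: the doubling/slice variant of NUTS,
warmup step-size adaptation by dual averaging toward a target acceptance
statistic, and a windowed estimate of a diagonal inverse mass matrix from the
warmup draws.  Heavy-tailed funnel-like posteriors (the intended use is
shrinkage-prior regression) benefit from a high acceptance target; trees are
capped at ``max_treedepth`` doublings and a trajectory is flagged divergent
when its energy error exceeds 1000 nats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np

__all__ = ["sample_chain", "ChainResult"]

_ENERGY_DIVERGENCE = 1000.0


@dataclass
class ChainResult:
    """Draws and per-iteration sampler statistics for one chain."""

    positions: np.ndarray  # (num_draws, dim), post-warmup only
    divergent: np.ndarray  # (num_draws,) bool
    treedepth_hit: np.ndarray  # (num_draws,) bool
    accept_stat: np.ndarray  # (num_draws,)
    step_size: float
    inv_mass: np.ndarray


class _Welford:
    """Running mean/variance accumulator."""

    def __init__(self, dim: int):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def update(self, x: np.ndarray) -> None:
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    def variance(self) -> np.ndarray:
        return self.m2 / max(self.n - 1, 1)


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman-Gelman schedule)."""

    def __init__(self, eps0: float, target: float):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept: float) -> float:
        self.count += 1
        w = 1.0 / (self.count + self.t0)
        self.h_bar = (1.0 - w) * self.h_bar + w * (self.target - accept)
        self.log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        eta = self.count ** (-self.kappa)
        self.log_eps_bar = eta * self.log_eps + (1.0 - eta) * self.log_eps_bar
        return float(np.exp(self.log_eps))


def _leapfrog(logp_grad, q, p, grad, eps, inv_mass):
    p_half = p + 0.5 * eps * grad
    q_new = q + eps * inv_mass * p_half
    lp_new, grad_new = logp_grad(q_new)
    p_new = p_half + 0.5 * eps * grad_new
    return q_new, p_new, grad_new, lp_new


def _kinetic(p, inv_mass) -> float:
    return 0.5 * float(np.dot(p * p, inv_mass))


def _find_reasonable_step_size(logp_grad, q, grad, lp, inv_mass, rng) -> float:
    """Double/halve the step size to bracket a ~50% acceptance probability."""
    with np.errstate(over="ignore", invalid="ignore"):
        return _find_step_size_inner(logp_grad, q, grad, lp, inv_mass, rng)


def _find_step_size_inner(logp_grad, q, grad, lp, inv_mass, rng) -> float:
    eps = 1.0
    p = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    joint0 = lp - _kinetic(p, inv_mass)
    _, p1, _, lp1 = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
    joint1 = lp1 - _kinetic(p1, inv_mass)
    if not np.isfinite(joint1):
        joint1 = -np.inf
    direction = 1.0 if (joint1 - joint0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, _, lp1 = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
        joint1 = lp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(joint1):
            joint1 = -np.inf
        if direction * (joint1 - joint0) <= direction * np.log(0.5):
            break
    return max(eps, 1e-10)


class _Tree:
    """State threaded through recursive doubling of one NUTS trajectory."""

    __slots__ = (
        "logp_grad", "inv_mass", "eps", "log_u", "joint0",
        "divergent", "sum_accept", "n_leapfrog",
    )

    def __init__(self, logp_grad, inv_mass, eps, log_u, joint0):
        self.logp_grad = logp_grad
        self.inv_mass = inv_mass
        self.eps = eps
        self.log_u = log_u
        self.joint0 = joint0
        self.divergent = False
        self.sum_accept = 0.0
        self.n_leapfrog = 0

    def build(self, q, p, grad, direction, depth, rng):
        """Return (q-, p-, grad-, q+, p+, grad+, q_sample, n_valid, keep_going)."""
        if depth == 0:
            q1, p1, grad1, lp1 = _leapfrog(
                self.logp_grad, q, p, grad, direction * self.eps, self.inv_mass
            )
            joint = lp1 - _kinetic(p1, self.inv_mass)
            if not np.isfinite(joint):
                joint = -np.inf
            n_valid = int(self.log_u <= joint)
            keep = self.log_u < joint + _ENERGY_DIVERGENCE
            if not keep:
                self.divergent = True
            self.sum_accept += min(1.0, float(np.exp(joint - self.joint0)))
            self.n_leapfrog += 1
            return q1, p1, grad1, q1, p1, grad1, q1, n_valid, keep

        qm, pm, gm, qp, pp, gp, q_samp, n1, keep = self.build(
            q, p, grad, direction, depth - 1, rng
        )
        if not keep:
            return qm, pm, gm, qp, pp, gp, q_samp, n1, False
        if direction == -1:
            qm, pm, gm, _, _, _, q2, n2, keep2 = self.build(
                qm, pm, gm, direction, depth - 1, rng
            )
        else:
            _, _, _, qp, pp, gp, q2, n2, keep2 = self.build(
                qp, pp, gp, direction, depth - 1, rng
            )
        if n1 + n2 > 0 and rng.random() < n2 / (n1 + n2):
            q_samp = q2
        keep = keep2 and _no_u_turn(qm, pm, qp, pp, self.inv_mass)
        return qm, pm, gm, qp, pp, gp, q_samp, n1 + n2, keep


def _no_u_turn(q_minus, p_minus, q_plus, p_plus, inv_mass) -> bool:
    dq = q_plus - q_minus
    return (
        float(np.dot(dq, inv_mass * p_minus)) >= 0.0
        and float(np.dot(dq, inv_mass * p_plus)) >= 0.0
    )


def _transition(logp_grad, q, lp, grad, eps, inv_mass, max_treedepth, rng):
    """One NUTS update; returns new state and iteration statistics."""
    p0 = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    joint0 = lp - _kinetic(p0, inv_mass)
    log_u = joint0 - rng.exponential()
    tree = _Tree(logp_grad, inv_mass, eps, log_u, joint0)

    qm, pm, gm = q, p0, grad
    qp, pp, gp = q, p0, grad
    q_cur, n_cur = q, 1
    depth = 0
    hit_max = False
    while depth < max_treedepth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction == -1:
            qm, pm, gm, _, _, _, q_prop, n_prop, keep = tree.build(
                qm, pm, gm, -1, depth, rng
            )
        else:
            _, _, _, qp, pp, gp, q_prop, n_prop, keep = tree.build(
                qp, pp, gp, 1, depth, rng
            )
        if keep and n_prop > 0 and rng.random() < min(1.0, n_prop / n_cur):
            q_cur = q_prop
        n_cur += n_prop
        depth += 1
        if not keep or not _no_u_turn(qm, pm, qp, pp, inv_mass):
            break
    else:
        hit_max = True

    lp_cur, grad_cur = logp_grad(q_cur) if q_cur is not q else (lp, grad)
    accept = tree.sum_accept / max(tree.n_leapfrog, 1)
    return q_cur, lp_cur, grad_cur, tree.divergent, hit_max, accept


def _adaptation_windows(num_warmup: int):
    """Step-size-only buffers around doubling slow windows (metric updates).

    Returns (end of initial fast phase, list of slow-window end indices,
    start of terminal fast phase)."""
    if num_warmup < 20:
        return num_warmup, [], num_warmup
    init_buffer, term_buffer, base_window = 75, 50, 25
    if init_buffer + term_buffer + base_window > num_warmup:
        init_buffer = int(0.15 * num_warmup)
        term_buffer = int(0.10 * num_warmup)
        base_window = num_warmup - init_buffer - term_buffer
    ends = []
    start, size = init_buffer, base_window
    while start + size < num_warmup - term_buffer:
        if start + 3 * size >= num_warmup - term_buffer:
            size = num_warmup - term_buffer - start  # absorb the remainder
        ends.append(start + size)
        start += size
        size *= 2
    if not ends:
        ends = [num_warmup - term_buffer]
    return init_buffer, ends, ends[-1]


def sample_chain(
    logp_grad: Callable[[np.ndarray], Tuple[float, np.ndarray]],
    q0: np.ndarray,
    *,
    num_warmup: int,
    num_draws: int,
    rng: np.random.Generator,
    adapt_target: float = 0.95,
    max_treedepth: int = 10,
    transition=None,
) -> ChainResult:
    """Run one adaptive NUTS chain and return post-warmup draws.

    ``transition`` replaces the built-in pure-Python NUTS update with a
    drop-in kernel of signature ``(q, lp, grad, eps, inv_mass, max_treedepth)
    -> (q, lp, grad, divergent, hit_max, accept)``; step-size search and
    warmup adaptation are shared.
    """
    if transition is None:
        def transition(q, lp, grad, eps, inv_mass, max_depth):
            with np.errstate(over="ignore", invalid="ignore"):
                return _transition(logp_grad, q, lp, grad, eps, inv_mass, max_depth, rng)

    q = np.asarray(q0, dtype=float).copy()
    lp, grad = logp_grad(q)
    if not np.isfinite(lp):
        raise RuntimeError("log density is not finite at the initial point")
    dim = q.size
    inv_mass = np.ones(dim)

    eps = _find_reasonable_step_size(logp_grad, q, grad, lp, inv_mass, rng)
    da = _DualAveraging(eps, adapt_target)
    init_end, window_ends, _ = _adaptation_windows(num_warmup)
    welford = _Welford(dim)
    window_ends = list(window_ends)

    for it in range(num_warmup):
        q, lp, grad, _, _, accept = transition(q, lp, grad, eps, inv_mass, max_treedepth)
        eps = da.update(accept)
        if it >= init_end and (not window_ends or it < window_ends[-1]):
            welford.update(q)
        if window_ends and it + 1 == window_ends[0]:
            window_ends.pop(0)
            if welford.n > 2:
                n = welford.n
                var = welford.variance()
                inv_mass = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                welford = _Welford(dim)
                eps = _find_reasonable_step_size(logp_grad, q, grad, lp, inv_mass, rng)
                da = _DualAveraging(eps, adapt_target)

    eps = float(np.exp(da.log_eps_bar)) if num_warmup > 0 else eps

    positions = np.empty((num_draws, dim))
    divergent = np.zeros(num_draws, dtype=bool)
    treedepth_hit = np.zeros(num_draws, dtype=bool)
    accept_stat = np.empty(num_draws)
    for it in range(num_draws):
        q, lp, grad, div, hit, accept = transition(q, lp, grad, eps, inv_mass, max_treedepth)
        positions[it] = q
        divergent[it] = div
        treedepth_hit[it] = hit
        accept_stat[it] = accept

    return ChainResult(
        positions=positions,
        divergent=divergent,
        treedepth_hit=treedepth_hit,
        accept_stat=accept_stat,
        step_size=eps,
        inv_mass=inv_mass,
    )
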