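"""No-U-Turn sampler with dual-averaging step-size and diagonal mass adaptation.

A self-contained implementation of the slice-sampling NUTS variant
(doubling trajectories, stopped at a U-turn), written against a generic
``logp_and_grad`` callable so the regression module can supply analytic
gradients.  Warmup follows the usual three-phase schedule: an initial
buffer adapting only the step size, a sequence of doubling windows from
which the diagonal metric (posterior variances) is re-estimated, and a
terminal buffer re-tuning the step size against the final metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["nuts_sample", "NutsStats"]

_MAX_ENERGY_ERROR = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass
class NutsStats:
    step_size: float
    inv_mass: np.ndarray
    divergences: int
    mean_accept: float
    n_leapfrog: int


class _Hamiltonian:
    def __init__(self, logp_and_grad: Callable, inv_mass: np.ndarray):
        self.f = logp_and_grad
        self.inv_mass = inv_mass
        self.n_evals = 0

    def eval(self, q):
        self.n_evals += 1
        return self.f(q)

    def kinetic(self, p):
        return 0.5 * float(p @ (self.inv_mass * p))

    def sample_momentum(self, rng, dim):
        return rng.standard_normal(dim) / np.sqrt(self.inv_mass)

    def leapfrog(self, q, p, grad, eps):
        p = p + 0.5 * eps * grad
        q = q + eps * (self.inv_mass * p)
        logp, grad = self.eval(q)
        p = p + 0.5 * eps * grad
        return q, p, logp, grad


def _find_initial_step(ham, q, logp, grad, rng):
    eps = 1.0
    p = ham.sample_momentum(rng, q.size)
    h0 = logp - ham.kinetic(p)
    q1, p1, logp1, _ = ham.leapfrog(q, p, grad, eps)
    h1 = logp1 - ham.kinetic(p1)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if h1 - h0 > np.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0 ** direction
        q1, p1, logp1, _ = ham.leapfrog(q, p, grad, eps)
        h1 = logp1 - ham.kinetic(p1)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


class _Tree:
    """One doubling trajectory of the slice-variant NUTS."""

    def __init__(self, ham, rng, log_u, h0, eps):
        self.ham = ham
        self.rng = rng
        self.log_u = log_u
        self.h0 = h0
        self.eps = eps
        self.divergent = False
        self.sum_accept = 0.0
        self.n_accept = 0

    def build(self, q, p, grad, direction, depth):
        if depth == 0:
            q1, p1, logp1, grad1 = self.ham.leapfrog(q, p, grad, direction * self.eps)
            h1 = logp1 - self.ham.kinetic(p1)
            if not np.isfinite(h1):
                h1 = -np.inf
            n_valid = int(self.log_u <= h1)
            keep_going = self.log_u < h1 + _MAX_ENERGY_ERROR
            if not keep_going:
                self.divergent = True
            self.sum_accept += np.exp(min(0.0, h1 - self.h0))
            self.n_accept += 1
            return q1, p1, grad1, q1, p1, grad1, q1, grad1, logp1, n_valid, keep_going
        # recursively build left and right subtrees
        out = self.build(q, p, grad, direction, depth - 1)
        qm, pm, gm, qp, pp, gp, q1, g1, logp1, n1, ok = out
        if ok:
            if direction == -1:
                out2 = self.build(qm, pm, gm, direction, depth - 1)
                qm, pm, gm, _, _, _, q2, g2, logp2, n2, ok2 = out2
            else:
                out2 = self.build(qp, pp, gp, direction, depth - 1)
                _, _, _, qp, pp, gp, q2, g2, logp2, n2, ok2 = out2
            if n2 > 0 and self.rng.random() < n2 / max(n1 + n2, 1):
                q1, g1, logp1 = q2, g2, logp2
            n1 += n2
            ok = ok2 and self._no_u_turn(qm, pm, qp, pp)
        return qm, pm, gm, qp, pp, gp, q1, g1, logp1, n1, ok

    def _no_u_turn(self, qm, pm, qp, pp):
        dq = qp - qm
        return (dq @ (self.ham.inv_mass * pm) >= 0) and (
            dq @ (self.ham.inv_mass * pp) >= 0
        )


def _nuts_iteration(ham, q, logp, grad, eps, rng, max_depth):
    p = ham.sample_momentum(rng, q.size)
    h0 = logp - ham.kinetic(p)
    log_u = h0 + np.log(rng.random())
    tree = _Tree(ham, rng, log_u, h0, eps)
    qm = qp = q
    pm = pp = p
    gm = gp = grad
    q_new, g_new, logp_new = q, grad, logp
    n_valid, keep_going, depth = 1, True, 0
    while keep_going and depth < max_depth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction == -1:
            out = tree.build(qm, pm, gm, -1, depth)
            qm, pm, gm = out[0], out[1], out[2]
        else:
            out = tree.build(qp, pp, gp, 1, depth)
            qp, pp, gp = out[3], out[4], out[5]
        q2, g2, logp2, n2, ok = out[6], out[7], out[8], out[9], out[10]
        if ok and n2 > 0 and rng.random() < min(1.0, n2 / n_valid):
            q_new, g_new, logp_new = q2, g2, logp2
        n_valid += n2
        keep_going = ok and tree._no_u_turn(qm, pm, qp, pp)
        depth += 1
    accept_stat = tree.sum_accept / max(tree.n_accept, 1)
    return q_new, logp_new, g_new, accept_stat, tree.divergent


def _warmup_windows(n_warmup: int):
    """(start, end) of metric-estimation windows plus step-size-only buffers."""
    init_buf = max(int(0.15 * n_warmup), 10)
    term_buf = max(int(0.10 * n_warmup), 10)
    windows = []
    start = init_buf
    size = max(int(0.10 * n_warmup), 25)
    while start + size < n_warmup - term_buf:
        end = start + size
        if end + 2 * size >= n_warmup - term_buf:
            end = n_warmup - term_buf
        windows.append((start, end))
        start = end
        size *= 2
    if not windows and n_warmup - term_buf > init_buf:
        windows.append((init_buf, n_warmup - term_buf))
    return windows


def nuts_sample(
    logp_and_grad: Callable,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_depth: int = 10,
) -> tuple[np.ndarray, NutsStats]:
    """Draw ``n_draws`` samples after ``n_warmup`` adaptation iterations.

    ``logp_and_grad(q) -> (logp, grad)`` must return the log target density
    (up to a constant) and its gradient.  Returns the post-warmup draws
    (n_draws × dim) and sampler statistics.
    """
    q = np.asarray(x0, dtype=float).copy()
    dim = q.size
    inv_mass = np.ones(dim)
    ham = _Hamiltonian(logp_and_grad, inv_mass)
    logp, grad = ham.eval(q)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_initial_step(ham, q, logp, grad, rng)
    # dual averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    windows = _warmup_windows(n_warmup)
    win_idx = 0
    da_iter = 0  # dual-averaging iterations since the last metric update
    acc_count, acc_mean, acc_m2 = 0, np.zeros(dim), np.zeros(dim)

    draws = np.empty((n_draws, dim))
    divergences = 0
    accept_sum = 0.0

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        q, logp, grad, accept_stat, divergent = _nuts_iteration(
            ham, q, logp, grad, eps, rng, max_depth
        )
        if warming:
            da_iter += 1
            eta = 1.0 / (da_iter + t0)
            h_bar = (1 - eta) * h_bar + eta * (target_accept - accept_stat)
            log_eps = mu - np.sqrt(da_iter) / gamma * h_bar
            w = da_iter ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if win_idx < len(windows):
                start, end = windows[win_idx]
                if start <= it < end:
                    acc_count += 1
                    delta = q - acc_mean
                    acc_mean += delta / acc_count
                    acc_m2 += delta * (q - acc_mean)
                if it == end - 1:
                    if acc_count > 4:
                        var = acc_m2 / (acc_count - 1)
                        # regularise towards unit scale as Stan does
                        n = acc_count
                        ham.inv_mass = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-3
                        ham.inv_mass = np.maximum(ham.inv_mass, 1e-10)
                    acc_count, acc_mean, acc_m2 = 0, np.zeros(dim), np.zeros(dim)
                    win_idx += 1
                    # restart step-size adaptation against the new metric
                    eps = _find_initial_step(ham, q, logp, grad, rng)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, da_iter = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = q
            divergences += int(divergent)
            accept_sum += accept_stat

    stats = NutsStats(
        step_size=eps,
        inv_mass=ham.inv_mass.copy(),
        divergences=divergences,
        mean_accept=accept_sum / max(n_draws, 1),
        n_leapfrog=ham.n_evals,
    )
    return draws, stats
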