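"""No-U-Turn sampler with dual-averaging step-size and diagonal-metric warmup.

Generic over a ``logp_grad(x) -> (logp, grad)`` target on an unconstrained
space.  The tree doubling follows the original slice-variable formulation;
warmup interleaves step-size adaptation (dual averaging, target acceptance
0.8) with expanding variance-estimation windows for a diagonal metric, in the
style of mainstream HMC implementations.

Only this module knows about Hamiltonian dynamics; callers provide the target
density and transform constrained parameters themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["sample_nuts", "NutsDiagnostics"]

_DELTA_MAX = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass
class NutsDiagnostics:
    step_sizes: np.ndarray      # per chain
    divergences: np.ndarray     # per chain, post-warmup count
    tree_depths: np.ndarray     # per chain mean post-warmup depth


def _kinetic(p, inv_metric):
    return 0.5 * float(np.dot(p, inv_metric * p))


def _leapfrog(x, p, grad, eps, inv_metric, logp_grad):
    p_half = p + 0.5 * eps * grad
    x_new = x + eps * inv_metric * p_half
    logp_new, grad_new = logp_grad(x_new)
    p_new = p_half + 0.5 * eps * grad_new
    return x_new, p_new, grad_new, logp_new


def _find_reasonable_epsilon(logp_grad, x, grad, logp, inv_metric, rng):
    eps = 1.0
    p = rng.standard_normal(len(x)) / np.sqrt(inv_metric)
    h0 = logp - _kinetic(p, inv_metric)
    x1, p1, _, logp1 = _leapfrog(x, p, grad, eps, inv_metric, logp_grad)
    h1 = logp1 - _kinetic(p1, inv_metric) if np.isfinite(logp1) else -np.inf
    ratio = h1 - h0
    direction = 1.0 if ratio > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        x1, p1, _, logp1 = _leapfrog(x, p, grad, eps, inv_metric, logp_grad)
        h1 = logp1 - _kinetic(p1, inv_metric) if np.isfinite(logp1) else -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


class _Tree:
    __slots__ = ("x_minus", "p_minus", "g_minus", "x_plus", "p_plus", "g_plus",
                 "x_prop", "logp_prop", "g_prop", "n", "s", "alpha", "n_alpha",
                 "diverged")


def _build_tree(x, p, grad, logu, v, j, eps, inv_metric, h0, logp_grad, rng):
    t = _Tree()
    if j == 0:
        x1, p1, g1, logp1 = _leapfrog(x, p, grad, v * eps, inv_metric, logp_grad)
        h1 = logp1 - _kinetic(p1, inv_metric) if np.isfinite(logp1) else -np.inf
        t.n = int(logu <= h1)
        t.diverged = logu - _DELTA_MAX >= h1
        t.s = not t.diverged
        t.x_minus = t.x_plus = t.x_prop = x1
        t.p_minus = t.p_plus = p1
        t.g_minus = t.g_plus = t.g_prop = g1
        t.logp_prop = logp1
        t.alpha = min(1.0, float(np.exp(min(0.0, h1 - h0))))
        t.n_alpha = 1
        return t
    left = _build_tree(x, p, grad, logu, v, j - 1, eps, inv_metric, h0,
                       logp_grad, rng)
    t = left
    if left.s:
        if v == -1:
            right = _build_tree(left.x_minus, left.p_minus, left.g_minus, logu,
                                v, j - 1, eps, inv_metric, h0, logp_grad, rng)
            t.x_minus, t.p_minus, t.g_minus = (right.x_minus, right.p_minus,
                                               right.g_minus)
        else:
            right = _build_tree(left.x_plus, left.p_plus, left.g_plus, logu,
                                v, j - 1, eps, inv_metric, h0, logp_grad, rng)
            t.x_plus, t.p_plus, t.g_plus = (right.x_plus, right.p_plus,
                                            right.g_plus)
        total = left.n + right.n
        if total > 0 and rng.random() < right.n / total:
            t.x_prop, t.logp_prop, t.g_prop = (right.x_prop, right.logp_prop,
                                               right.g_prop)
        dx = t.x_plus - t.x_minus
        no_uturn = (np.dot(dx, inv_metric * t.p_minus) >= 0
                    and np.dot(dx, inv_metric * t.p_plus) >= 0)
        t.s = left.s and right.s and no_uturn
        t.n = total
        t.alpha = left.alpha + right.alpha
        t.n_alpha = left.n_alpha + right.n_alpha
        t.diverged = left.diverged or right.diverged
    return t


def _warmup_windows(n_warmup):
    """(init buffer, metric windows, terminal buffer) iteration spans."""
    if n_warmup < 150:
        return n_warmup, [], 0
    init, term = 75, 50
    body = n_warmup - init - term
    windows, w = [], 25
    while body > 0:
        if body < 2 * w:  # absorb the remainder into the final window
            windows.append(body)
            body = 0
        else:
            windows.append(w)
            body -= w
            w *= 2
    return init, windows, term


def _sample_chain(logp_grad, x0, n_warmup, n_draws, rng, target_accept,
                  max_treedepth):
    x = np.asarray(x0, dtype=float).copy()
    d = len(x)
    logp, grad = logp_grad(x)
    if not np.isfinite(logp):
        raise ValueError("non-finite log-posterior at the initial point")
    inv_metric = np.ones(d)

    eps = _find_reasonable_epsilon(logp_grad, x, grad, logp, inv_metric, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar, m_adapt = 0.0, 0.0, 0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    init, windows, term = _warmup_windows(n_warmup)
    window_ends = set()
    pos = init
    for w in windows:
        pos += w
        window_ends.add(pos)
    window_buf = []

    draws = np.empty((n_draws, d))
    n_div = 0
    depth_sum = 0

    total = n_warmup + n_draws
    for it in range(total):
        warm = it < n_warmup
        p0 = rng.standard_normal(d) / np.sqrt(inv_metric)
        h0 = logp - _kinetic(p0, inv_metric)
        logu = h0 + np.log(rng.random())

        x_minus = x_plus = x
        p_minus = p_plus = p0
        g_minus = g_plus = grad
        j, n, s = 0, 1, True
        alpha, n_alpha = 1.0, 1
        diverged = False
        while s and j < max_treedepth:
            v = 1 if rng.random() < 0.5 else -1
            if v == -1:
                t = _build_tree(x_minus, p_minus, g_minus, logu, v, j, eps,
                                inv_metric, h0, logp_grad, rng)
                x_minus, p_minus, g_minus = t.x_minus, t.p_minus, t.g_minus
            else:
                t = _build_tree(x_plus, p_plus, g_plus, logu, v, j, eps,
                                inv_metric, h0, logp_grad, rng)
                x_plus, p_plus, g_plus = t.x_plus, t.p_plus, t.g_plus
            if t.s and rng.random() < min(1.0, t.n / n):
                x, logp, grad = t.x_prop, t.logp_prop, t.g_prop
            n += t.n
            dx = x_plus - x_minus
            s = (t.s and np.dot(dx, inv_metric * p_minus) >= 0
                 and np.dot(dx, inv_metric * p_plus) >= 0)
            alpha, n_alpha = t.alpha, t.n_alpha
            diverged = diverged or t.diverged
            j += 1

        if warm:
            m_adapt += 1
            h_bar = ((1 - 1 / (m_adapt + t0)) * h_bar
                     + (target_accept - alpha / n_alpha) / (m_adapt + t0))
            log_eps = mu - np.sqrt(m_adapt) / gamma * h_bar
            eta = m_adapt ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))

            if it >= init and window_ends:
                window_buf.append(x.copy())
            if (it + 1) in window_ends:
                buf = np.asarray(window_buf)
                nb = len(buf)
                if nb > 2:
                    var = buf.var(axis=0, ddof=1)
                    inv_metric = (nb / (nb + 5.0)) * var + 1e-3 * (5.0 / (nb + 5.0))
                window_buf = []
                # re-initialise step-size adaptation under the new metric
                eps = _find_reasonable_epsilon(logp_grad, x, grad, logp,
                                               inv_metric, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, m_adapt = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = x
            n_div += int(diverged)
            depth_sum += j

    return draws, eps, n_div, depth_sum / max(n_draws, 1)


def sample_nuts(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    init: np.ndarray,
    *,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_draws: int = 2500,
    seed: int = 0,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> tuple[np.ndarray, NutsDiagnostics]:
    """Run independent NUTS chains; returns draws (chains, draws, dim).

    ``init`` may be a single point (jittered per chain) or one point per
    chain with shape (n_chains, dim).
    """
    if n_chains < 1:
        raise ValueError("need at least one chain")
    init = np.atleast_2d(np.asarray(init, dtype=float))
    dim = init.shape[1]
    if init.shape[0] == 1:
        init = np.repeat(init, n_chains, axis=0)
    if init.shape[0] != n_chains:
        raise ValueError("init must be one point or one point per chain")

    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    all_draws = np.empty((n_chains, n_draws, dim))
    step_sizes = np.empty(n_chains)
    divergences = np.empty(n_chains, dtype=int)
    depths = np.empty(n_chains)
    for c in range(n_chains):
        rng = np.random.default_rng(seeds[c])
        x0 = init[c] + 0.01 * rng.standard_normal(dim)
        draws, eps, ndiv, depth = _sample_chain(
            logp_grad, x0, n_warmup, n_draws, rng, target_accept, max_treedepth
        )
        all_draws[c] = draws
        step_sizes[c] = eps
        divergences[c] = ndiv
        depths[c] = depth
    return all_draws, NutsDiagnostics(step_sizes, divergences, depths)
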