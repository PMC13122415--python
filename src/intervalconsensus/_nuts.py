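"""Dynamic-trajectory Hamiltonian Monte Carlo (NUTS-style) in pure numpy.

A self-contained gradient-based sampler used to fit the ICM posterior:
multinomial sampling over a doubling trajectory with a generalised U-turn
criterion, dual-averaging step-size adaptation toward a target acceptance
statistic, and windowed diagonal mass-matrix adaptation during warmup.
Trajectories with an energy error above 1000 count as divergent and stop the
doubling.  The implementation follows the standard algorithm; it is exercised
against exact Gaussian targets in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["sample_nuts", "NutsStats"]

_MAX_ENERGY_ERROR = 1000.0


@dataclass
class NutsStats:
    """Per-chain sampler statistics."""

    divergences: int
    step_size: float
    mean_accept: float
    max_treedepth_hits: int


class _Tree:
    __slots__ = ("q_m", "p_m", "g_m", "q_p", "p_p", "g_p", "q_prop", "logp_prop",
                 "g_prop", "log_w", "turning", "diverged", "sum_accept", "n_leaf")

    def __init__(self):
        self.turning = False
        self.diverged = False
        self.sum_accept = 0.0
        self.n_leaf = 0


def _leapfrog(logp_grad, q, p, grad, eps, inv_mass):
    # extreme trajectories overflow to inf/nan and surface as divergences
    with np.errstate(over="ignore", invalid="ignore"):
        p = p + 0.5 * eps * grad
        q = q + eps * inv_mass * p
        logp, grad = logp_grad(q)
        p = p + 0.5 * eps * grad
    return q, p, logp, grad


def _is_turning(q_m, p_m, q_p, p_p, inv_mass) -> bool:
    dq = q_p - q_m
    return (dq @ (inv_mass * p_m)) < 0 or (dq @ (inv_mass * p_p)) < 0


def _build_tree(logp_grad, q, p, grad, direction, depth, eps, inv_mass, h0, rng):
    tree = _Tree()
    if depth == 0:
        q1, p1, logp1, grad1 = _leapfrog(logp_grad, q, p, grad, direction * eps, inv_mass)
        with np.errstate(over="ignore", invalid="ignore"):
            h = -logp1 + 0.5 * (p1 @ (inv_mass * p1))
        energy_error = h - h0
        tree.n_leaf = 1
        if not np.isfinite(h) or energy_error > _MAX_ENERGY_ERROR:
            tree.diverged = True
            tree.log_w = -np.inf
            tree.sum_accept = 0.0
            tree.q_m = tree.q_p = q1
            tree.p_m = tree.p_p = p1
            tree.g_m = tree.g_p = grad1
            tree.q_prop, tree.logp_prop, tree.g_prop = q1, logp1, grad1
            return tree
        tree.log_w = -energy_error
        tree.sum_accept = np.exp(-max(energy_error, 0.0))
        tree.q_m = tree.q_p = q1
        tree.p_m = tree.p_p = p1
        tree.g_m = tree.g_p = grad1
        tree.q_prop, tree.logp_prop, tree.g_prop = q1, logp1, grad1
        return tree

    first = _build_tree(logp_grad, q, p, grad, direction, depth - 1, eps, inv_mass, h0, rng)
    if first.diverged or first.turning:
        return first
    if direction > 0:
        seed_q, seed_p, seed_g = first.q_p, first.p_p, first.g_p
    else:
        seed_q, seed_p, seed_g = first.q_m, first.p_m, first.g_m
    second = _build_tree(logp_grad, seed_q, seed_p, seed_g, direction, depth - 1,
                         eps, inv_mass, h0, rng)
    tree = _Tree()
    tree.n_leaf = first.n_leaf + second.n_leaf
    tree.sum_accept = first.sum_accept + second.sum_accept
    tree.diverged = second.diverged
    if direction > 0:
        tree.q_m, tree.p_m, tree.g_m = first.q_m, first.p_m, first.g_m
        tree.q_p, tree.p_p, tree.g_p = second.q_p, second.p_p, second.g_p
    else:
        tree.q_m, tree.p_m, tree.g_m = second.q_m, second.p_m, second.g_m
        tree.q_p, tree.p_p, tree.g_p = first.q_p, first.p_p, first.g_p
    tree.log_w = np.logaddexp(first.log_w, second.log_w)
    # multinomial sampling between the two halves
    if second.diverged:
        src = first
    elif np.log(rng.uniform()) < second.log_w - tree.log_w:
        src = second
    else:
        src = first
    tree.q_prop, tree.logp_prop, tree.g_prop = src.q_prop, src.logp_prop, src.g_prop
    tree.turning = second.turning or _is_turning(
        tree.q_m, tree.p_m, tree.q_p, tree.p_p, inv_mass
    )
    return tree


def _nuts_step(logp_grad, q, logp, grad, eps, inv_mass, max_depth, rng):
    dim = q.shape[0]
    p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
    h0 = -logp + 0.5 * (p0 @ (inv_mass * p0))
    q_m = q_p = q
    p_m = p_p = p0
    g_m = g_p = grad
    q_cur, logp_cur, grad_cur = q, logp, grad
    log_w = 0.0  # weight of the initial point relative to exp(-h0)
    sum_accept = 0.0
    n_leaf = 0
    diverged = False
    hit_max = False
    for depth in range(max_depth):
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction > 0:
            sub = _build_tree(logp_grad, q_p, p_p, g_p, 1, depth, eps, inv_mass, h0, rng)
            if not (sub.diverged and sub.n_leaf == 1):
                q_p, p_p, g_p = sub.q_p, sub.p_p, sub.g_p
        else:
            sub = _build_tree(logp_grad, q_m, p_m, g_m, -1, depth, eps, inv_mass, h0, rng)
            if not (sub.diverged and sub.n_leaf == 1):
                q_m, p_m, g_m = sub.q_m, sub.p_m, sub.g_m
        sum_accept += sub.sum_accept
        n_leaf += sub.n_leaf
        if sub.diverged:
            diverged = True
            break
        if sub.turning:
            break
        # progressive multinomial sampling between old trajectory and new subtree
        if np.log(rng.uniform()) < sub.log_w - log_w:
            q_cur, logp_cur, grad_cur = sub.q_prop, sub.logp_prop, sub.g_prop
        log_w = np.logaddexp(log_w, sub.log_w)
        if _is_turning(q_m, p_m, q_p, p_p, inv_mass):
            break
    else:
        hit_max = True
    accept_stat = sum_accept / max(n_leaf, 1)
    return q_cur, logp_cur, grad_cur, accept_stat, diverged, hit_max


def _find_reasonable_step_size(logp_grad, q, logp, grad, inv_mass, rng) -> float:
    """Double / halve the step size until one leapfrog has accept prob ~0.5."""
    eps = 0.1
    dim = q.shape[0]
    p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
    with np.errstate(over="ignore", invalid="ignore"):
        h0 = -logp + 0.5 * (p0 @ (inv_mass * p0))
        _, p1, logp1, _ = _leapfrog(logp_grad, q, p0, grad, eps, inv_mass)
        h1 = -logp1 + 0.5 * (p1 @ (inv_mass * p1))
        delta = h0 - h1 if np.isfinite(h1) else -np.inf
        direction = 1.0 if delta > np.log(0.5) else -1.0
        for _ in range(50):
            eps_try = eps * (2.0**direction)
            _, p1, logp1, _ = _leapfrog(logp_grad, q, p0, grad, eps_try, inv_mass)
            h1 = -logp1 + 0.5 * (p1 @ (inv_mass * p1))
            delta = h0 - h1 if np.isfinite(h1) else -np.inf
            if (direction > 0 and delta <= np.log(0.5)) or (
                direction < 0 and delta >= np.log(0.5)
            ):
                break
            eps = eps_try
    return eps


def sample_nuts(
    logp_grad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_treedepth: int = 10,
    init_step_size: float | None = None,
    post_step=None,
    init_inv_mass: np.ndarray | None = None,
    adapt_mass: bool = True,
):
    """Run one chain; returns (draws, logps, stats, state).

    ``logp_grad(q) -> (logp, grad)``.  Warmup adapts a dual-averaged step size
    throughout and, when ``adapt_mass``, a diagonal mass matrix on expanding
    windows; warmup draws are discarded.  ``post_step(q, rng) -> q``
    optionally applies an extra posterior-invariant kernel (e.g. interweaving
    updates) after every trajectory.  ``state`` carries the final position,
    adapted inverse mass and step size, so adaptation can be staged across
    runs (e.g. pooled between chains).
    """
    q = np.asarray(x0, dtype=float).copy()
    logp, grad = logp_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log-density")
    dim = q.shape[0]
    inv_mass = np.ones(dim) if init_inv_mass is None else np.asarray(init_inv_mass, dtype=float).copy()

    # dual averaging state
    eps = init_step_size or _find_reasonable_step_size(
        logp_grad, q, logp, grad, inv_mass, rng
    )
    mu = np.log(10.0 * eps)
    log_eps_bar = 0.0
    h_bar = 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # mass-matrix windows (Stan-like schedule, shrunk for small warmups)
    init_buffer = min(75, max(10, int(0.15 * n_warmup)))
    term_buffer = min(50, max(10, int(0.1 * n_warmup)))
    window_starts = []
    if adapt_mass:
        wstart = init_buffer
        wsize = 25
        while wstart + wsize < n_warmup - term_buffer:
            window_starts.append((wstart, wstart + wsize))
            wstart += wsize
            wsize *= 2
        if window_starts:
            window_starts[-1] = (window_starts[-1][0], n_warmup - term_buffer)
        elif n_warmup > init_buffer + term_buffer + 10:
            window_starts = [(init_buffer, n_warmup - term_buffer)]

    window_samples: list[np.ndarray] = []
    win_idx = 0
    divergences = 0
    hit_max_total = 0
    accepts = []

    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        # mild step-size jitter decorrelates trajectory lengths
        eps_it = eps * rng.uniform(0.9, 1.1)
        q, logp, grad, accept_stat, diverged, hit_max = _nuts_step(
            logp_grad, q, logp, grad, eps_it, inv_mass, max_treedepth, rng
        )
        if post_step is not None:
            q = post_step(q, rng)
            logp, grad = logp_grad(q)
        if warming:
            # dual averaging
            m = it + 1
            h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - accept_stat) / (m + t0)
            log_eps = mu - np.sqrt(m) / gamma * h_bar
            eta = m ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = np.exp(log_eps)
            # mass-matrix window bookkeeping
            if win_idx < len(window_starts):
                ws, we = window_starts[win_idx]
                if ws <= it < we:
                    window_samples.append(q.copy())
                if it == we - 1 and len(window_samples) > 5:
                    arr = np.asarray(window_samples)
                    var = arr.var(axis=0, ddof=1)
                    n_s = arr.shape[0]
                    # regularise toward unit variance as Stan does
                    var = (n_s / (n_s + 5.0)) * var + 1e-3 * (5.0 / (n_s + 5.0))
                    inv_mass = np.maximum(var, 1e-10)
                    window_samples = []
                    win_idx += 1
                    # restart step-size adaptation around the current eps
                    mu = np.log(10.0 * eps)
                    h_bar = 0.0
            if it == n_warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            if diverged:
                divergences += 1
            if hit_max:
                hit_max_total += 1
            accepts.append(accept_stat)
            draws[it - n_warmup] = q
            logps[it - n_warmup] = logp

    stats = NutsStats(
        divergences=divergences,
        step_size=float(eps),
        mean_accept=float(np.mean(accepts)) if accepts else float("nan"),
        max_treedepth_hits=hit_max_total,
    )
    state = {"q": q.copy(), "inv_mass": inv_mass.copy(), "step_size": float(eps)}
    return draws, logps, stats, state
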