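"""Hamiltonian Monte Carlo with dual-averaging step-size and diagonal mass
adaptation.

A small, self-contained NUTS-free sampler: jittered-length leapfrog
trajectories with a Metropolis accept/reject step, which is exact for any
step size.  Warmup interleaves step-size adaptation (Nesterov dual
averaging toward a target acceptance rate) with windowed estimation of a
diagonal mass matrix from the warmup draws, after which both are frozen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class HMCOptions:
    target_accept: float = 0.9
    init_step: float = 0.1
    int_time: float = 1.2          # nominal trajectory length after mass scaling
    max_leapfrog: int = 96
    adapt_gamma: float = 0.05
    adapt_t0: float = 10.0
    adapt_kappa: float = 0.75
    divergence_threshold: float = 1000.0


def _leapfrog(logp_grad, x, p, step, n_steps, inv_mass):
    lp, grad = logp_grad(x)
    for _ in range(n_steps):
        p = p + 0.5 * step * grad
        x = x + step * inv_mass * p
        lp, grad = logp_grad(x)
        if not np.isfinite(lp):
            return x, p, lp, grad
        p = p + 0.5 * step * grad
    return x, p, lp, grad


def _find_initial_step(logp_grad, x, step, inv_mass, rng):
    """Crude doubling/halving search for a step size with accept prob near 0.5."""
    lp0, _ = logp_grad(x)
    p = rng.standard_normal(x.size) / np.sqrt(inv_mass)
    h0 = lp0 - 0.5 * np.sum(inv_mass * p * p)
    x1, p1, lp1, _ = _leapfrog(logp_grad, x, p, step, 1, inv_mass)
    h1 = lp1 - 0.5 * np.sum(inv_mass * p1 * p1) if np.isfinite(lp1) else -np.inf
    delta = h1 - h0
    direction = 1 if delta > np.log(0.5) else -1
    for _ in range(60):
        step = step * (2.0 ** direction)
        x1, p1, lp1, _ = _leapfrog(logp_grad, x, p, step, 1, inv_mass)
        h1 = lp1 - 0.5 * np.sum(inv_mass * p1 * p1) if np.isfinite(lp1) else -np.inf
        delta = h1 - h0
        if (direction == 1 and delta <= np.log(0.5)) or (
            direction == -1 and delta >= np.log(0.5)
        ):
            break
    return step


def _mass_windows(n_warmup: int) -> list[tuple[int, int]]:
    """Doubling adaptation windows inside [0.15, 0.9] of warmup (Stan-style)."""
    lo, hi = int(0.15 * n_warmup), int(0.9 * n_warmup)
    windows, start, width = [], lo, max(25, n_warmup // 20)
    while start < hi:
        end = min(start + width, hi)
        if hi - end < width:  # absorb the remainder into the final window
            end = hi
        windows.append((start, end))
        start, width = end, width * 2
    return windows


def run_hmc(
    logp_grad,
    x0: np.ndarray,
    n_warmup: int,
    n_keep: int,
    rng: np.random.Generator,
    options: HMCOptions | None = None,
):
    """Sample ``n_keep`` post-warmup draws starting from ``x0``.

    Returns ``(draws, stats)`` where draws has shape (n_keep, dim) and stats
    records the tuned step size, acceptance rates and divergence count.
    """
    opt = options or HMCOptions()
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    inv_mass = np.ones(dim)

    lp, _ = logp_grad(x)
    if not np.isfinite(lp):
        raise FloatingPointError("non-finite log density at the initial point")

    step = _find_initial_step(logp_grad, x, opt.init_step, inv_mass, rng)
    mu = np.log(10.0 * step)
    log_step_bar, h_bar = np.log(step), 0.0
    m_adapt = 0  # dual-averaging iteration count, restarted at window resets
    windows = _mass_windows(n_warmup)
    window_buf: list[np.ndarray] = []
    window_i = 0

    draws = np.empty((n_keep, dim))
    accept_sum, n_accept_steps, divergences = 0.0, 0, 0

    total = n_warmup + n_keep
    for it in range(total):
        warming = it < n_warmup
        cur_step = step if warming else np.exp(log_step_bar)

        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        lp0, _ = logp_grad(x)
        h0 = lp0 - 0.5 * np.sum(inv_mass * p0 * p0)
        n_base = max(1, min(opt.max_leapfrog, int(round(opt.int_time / cur_step))))
        n_steps = max(1, int(np.ceil(n_base * rng.uniform(0.5, 1.0))))
        x1, p1, lp1, _ = _leapfrog(logp_grad, x, p0, cur_step, n_steps, inv_mass)
        if np.isfinite(lp1):
            with np.errstate(over="ignore", invalid="ignore"):
                h1 = lp1 - 0.5 * np.sum(inv_mass * p1 * p1)
            delta = h1 - h0 if np.isfinite(h1) else -np.inf
        else:
            delta = -np.inf
        diverged = (not np.isfinite(delta)) or (-delta > opt.divergence_threshold)
        accept_prob = 0.0 if diverged else min(1.0, float(np.exp(min(delta, 0.0))))
        if rng.uniform() < accept_prob:
            x = x1

        if warming:
            # dual averaging toward the target acceptance rate
            m_adapt += 1
            m = m_adapt
            eta = 1.0 / (m + opt.adapt_t0)
            h_bar = (1 - eta) * h_bar + eta * (opt.target_accept - accept_prob)
            log_step = mu - np.sqrt(m) / opt.adapt_gamma * h_bar
            w = m ** (-opt.adapt_kappa)
            log_step_bar = w * log_step + (1 - w) * log_step_bar
            step = float(np.exp(log_step))
            if window_i < len(windows):
                w_lo, w_hi = windows[window_i]
                if w_lo <= it < w_hi:
                    window_buf.append(x.copy())
                if it == w_hi - 1 and len(window_buf) >= 10:
                    arr = np.asarray(window_buf)
                    var = np.var(arr, axis=0, ddof=1)
                    n = arr.shape[0]
                    # regularized toward unit scale as in Stan's windowed adapt
                    inv_mass = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                    inv_mass = np.maximum(inv_mass, 1e-10)
                    window_buf = []
                    window_i += 1
                    step = _find_initial_step(logp_grad, x, step, inv_mass, rng)
                    mu = np.log(10.0 * step)
                    log_step_bar, h_bar = np.log(step), 0.0
                    m_adapt = 0
        else:
            draws[it - n_warmup] = x
            accept_sum += accept_prob
            n_accept_steps += 1
            if diverged:
                divergences += 1

    stats = {
        "step_size": float(np.exp(log_step_bar)),
        "mean_accept": accept_sum / max(1, n_accept_steps),
        "divergences": divergences,
        "inv_mass": inv_mass,
    }
    return draws, stats
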