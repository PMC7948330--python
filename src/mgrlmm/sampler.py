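"""No-U-Turn sampler with dual-averaging step size and diagonal mass matrix.

A self-contained gradient-based MCMC kernel in the Hamiltonian Monte Carlo
family: doubling trajectories with the slice-sampling acceptance rule, a
U-turn termination criterion evaluated in the metric, dual averaging of the
step size towards a target acceptance statistic, and windowed estimation of a
diagonal mass matrix from warmup draws.  Everything is driven by a single
``numpy.random.Generator`` so runs are reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["nuts_chain", "NutsResult"]

_MAX_DELTA_H = 1000.0  # divergence threshold on energy error


@dataclass
class NutsResult:
    draws: np.ndarray  # (n_draws, dim), post-warmup
    accept_stat: np.ndarray  # (n_draws,)
    n_divergent: int
    step_size: float
    inv_mass: np.ndarray
    treedepths: np.ndarray


class _State:
    __slots__ = ("z", "p", "grad", "logp")

    def __init__(self, z, p, logp, grad):
        self.z, self.p, self.logp, self.grad = z, p, logp, grad


def _leapfrog(logp_grad, state: _State, eps: float, inv_mass: np.ndarray) -> _State:
    p = state.p + 0.5 * eps * state.grad
    z = state.z + eps * inv_mass * p
    logp, grad = logp_grad(z)
    p = p + 0.5 * eps * grad
    return _State(z, p, logp, grad)


def _energy(state: _State, inv_mass: np.ndarray) -> float:
    return -state.logp + 0.5 * np.dot(state.p, inv_mass * state.p)


def _uturn(z_minus, z_plus, p_minus, p_plus, inv_mass) -> bool:
    dz = z_plus - z_minus
    return (np.dot(dz, inv_mass * p_minus) < 0.0) or (np.dot(dz, inv_mass * p_plus) < 0.0)


def _build_tree(logp_grad, state, logu, direction, depth, eps, inv_mass, H0, rng):
    """Recursively double the trajectory; Hoffman–Gelman slice variant."""
    if depth == 0:
        new = _leapfrog(logp_grad, state, direction * eps, inv_mass)
        H = _energy(new, inv_mass)
        if not np.isfinite(H):
            H = np.inf
        n_valid = int(logu <= -H)
        divergent = (-H) < logu - _MAX_DELTA_H
        alpha = min(1.0, np.exp(min(H0 - H, 0.0))) if np.isfinite(H) else 0.0
        return new, new, new, n_valid, not divergent, alpha, 1, divergent
    (minus, plus, prop, n_valid, cont, alpha, n_alpha, div) = _build_tree(
        logp_grad, state, logu, direction, depth - 1, eps, inv_mass, H0, rng
    )
    if cont:
        if direction == -1:
            (minus, _, prop2, n2, cont2, a2, na2, div2) = _build_tree(
                logp_grad, minus, logu, direction, depth - 1, eps, inv_mass, H0, rng
            )
        else:
            (_, plus, prop2, n2, cont2, a2, na2, div2) = _build_tree(
                logp_grad, plus, logu, direction, depth - 1, eps, inv_mass, H0, rng
            )
        if n2 > 0 and rng.uniform() < n2 / max(n_valid + n2, 1):
            prop = prop2
        n_valid += n2
        alpha += a2
        n_alpha += na2
        div = div or div2
        cont = cont2 and not _uturn(minus.z, plus.z, minus.p, plus.p, inv_mass)
    return minus, plus, prop, n_valid, cont, alpha, n_alpha, div


def _nuts_step(logp_grad, state, eps, inv_mass, max_treedepth, rng):
    p0 = rng.standard_normal(state.z.shape) / np.sqrt(inv_mass)
    start = _State(state.z, p0, state.logp, state.grad)
    H0 = _energy(start, inv_mass)
    logu = -H0 - rng.exponential()
    minus = plus = sample = start
    n_valid, depth, divergent = 1, 0, False
    alpha_sum, n_alpha = 0.0, 0
    while depth < max_treedepth:
        direction = 1 if rng.uniform() < 0.5 else -1
        edge = minus if direction == -1 else plus
        (m2, p2, prop, n2, cont, a2, na2, div2) = _build_tree(
            logp_grad, edge, logu, direction, depth, eps, inv_mass, H0, rng
        )
        if direction == -1:
            minus = m2
        else:
            plus = p2
        alpha_sum += a2
        n_alpha += na2
        divergent = divergent or div2
        if not cont:
            break
        if n2 > 0 and rng.uniform() < min(1.0, n2 / n_valid):
            sample = prop
        n_valid += n2
        depth += 1
        if _uturn(minus.z, plus.z, minus.p, plus.p, inv_mass):
            break
    accept_stat = alpha_sum / max(n_alpha, 1)
    return sample, accept_stat, divergent, depth


def _find_initial_step(logp_grad, state, inv_mass, rng) -> float:
    eps = 1.0
    p0 = rng.standard_normal(state.z.shape) / np.sqrt(inv_mass)
    s0 = _State(state.z, p0, state.logp, state.grad)
    H0 = _energy(s0, inv_mass)
    new = _leapfrog(logp_grad, s0, eps, inv_mass)
    H = _energy(new, inv_mass)
    dH = H0 - H if np.isfinite(H) else -np.inf
    direction = 1 if dH > np.log(0.8) else -1
    for _ in range(50):
        eps *= 2.0**direction
        new = _leapfrog(logp_grad, s0, eps, inv_mass)
        H = _energy(new, inv_mass)
        dH = H0 - H if np.isfinite(H) else -np.inf
        if (direction == 1 and dH <= np.log(0.8)) or (
            direction == -1 and dH >= np.log(0.8)
        ):
            break
    return eps


class _DualAverage:
    """Nesterov dual averaging of log step size (Stan defaults)."""

    def __init__(self, eps0: float, target: float):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_stat: float) -> float:
        self.count += 1
        eta = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        w = self.count**-self.kappa
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return np.exp(self.log_eps)

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def _metric_windows(n_warmup: int) -> list[tuple[int, int]]:
    """(start, end) iteration spans whose draws feed a mass-matrix update."""
    if n_warmup < 40:
        return []
    init = min(75, n_warmup // 3)
    term = min(50, n_warmup // 5)
    windows = []
    start, size = init, max(25, (n_warmup - init - term) // 8)
    while start + size <= n_warmup - term:
        end = start + size
        if n_warmup - term - end < size:  # absorb the remainder
            end = n_warmup - term
        windows.append((start, end))
        start, size = end, size * 2
    return windows


def nuts_chain(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    z0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_treedepth: int = 10,
) -> NutsResult:
    """Run one adaptive NUTS chain and return post-warmup draws."""
    dim = z0.shape[0]
    inv_mass = np.ones(dim)
    logp, grad = logp_grad(z0)
    if not np.isfinite(logp):
        raise ValueError("log posterior not finite at the initial point")
    state = _State(z0.copy(), np.zeros(dim), logp, grad)

    eps = _find_initial_step(logp_grad, state, inv_mass, rng)
    da = _DualAverage(eps, target_accept)
    windows = _metric_windows(n_warmup)
    window_iter = 0 if windows else None
    buffer: list[np.ndarray] = []

    n_div = 0
    for it in range(n_warmup):
        state, astat, div, _ = _nuts_step(logp_grad, state, eps, inv_mass, max_treedepth, rng)
        eps = da.update(astat)
        if window_iter is not None and window_iter < len(windows):
            w0, w1 = windows[window_iter]
            if w0 <= it < w1:
                buffer.append(state.z.copy())
            if it == w1 - 1:
                sample = np.asarray(buffer)
                n = sample.shape[0]
                var = sample.var(axis=0, ddof=1) if n > 1 else np.ones(dim)
                inv_mass = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-3
                buffer = []
                window_iter += 1
                # re-adapt the step size under the new metric
                eps = _find_initial_step(logp_grad, state, inv_mass, rng)
                da = _DualAverage(eps, target_accept)
    eps = da.adapted if da.count > 0 else eps

    draws = np.empty((n_draws, dim))
    accept = np.empty(n_draws)
    depths = np.empty(n_draws, dtype=int)
    for it in range(n_draws):
        state, astat, div, depth = _nuts_step(
            logp_grad, state, eps, inv_mass, max_treedepth, rng
        )
        n_div += int(div)
        draws[it] = state.z
        accept[it] = astat
        depths[it] = depth
    return NutsResult(
        draws=draws,
        accept_stat=accept,
        n_divergent=n_div,
        step_size=float(eps),
        inv_mass=inv_mass,
        treedepths=depths,
    )
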