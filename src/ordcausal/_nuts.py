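"""A compact No-U-Turn sampler with Stan-style warmup adaptation.

Implements multinomial NUTS over a user-supplied log-density-and-gradient
callable, with dual-averaging step-size adaptation and windowed diagonal
mass-matrix estimation.  Written for posteriors of a few hundred
dimensions where the gradient is cheap; no attempt at parallelism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np

LogpGrad = Callable[[np.ndarray], Tuple[float, np.ndarray]]

_MAX_DELTA_H = 1000.0  # divergence threshold on the Hamiltonian error


class SamplingError(RuntimeError):
    pass


@dataclass
class NutsConfig:
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.9
    max_treedepth: int = 10
    init_buffer: int = 75
    term_buffer: int = 50
    base_window: int = 25


@dataclass
class ChainResult:
    draws: np.ndarray          # (n_draws, dim) post-warmup positions
    divergent: np.ndarray      # (n_draws,) bool
    accept_stat: np.ndarray    # (n_draws,) mean acceptance statistic
    tree_depth: np.ndarray     # (n_draws,) int
    step_size: float
    inv_mass: np.ndarray


class _Tree:
    """State carried while recursively doubling a NUTS trajectory."""

    __slots__ = (
        "theta_minus", "p_minus", "grad_minus",
        "theta_plus", "p_plus", "grad_plus",
        "theta_prop", "log_sum_weight",
        "sum_accept", "n_leapfrog", "valid", "divergent",
    )


def _leapfrog(logp_grad, theta, p, grad, eps, inv_mass):
    with np.errstate(over="ignore", invalid="ignore"):
        p_half = p + 0.5 * eps * grad
        theta_new = theta + eps * inv_mass * p_half
        lp, grad_new = logp_grad(theta_new)
        p_new = p_half + 0.5 * eps * grad_new
    return theta_new, p_new, lp, grad_new


def _kinetic(p, inv_mass):
    # momenta can overflow transiently on divergent trajectories
    with np.errstate(over="ignore", invalid="ignore"):
        return 0.5 * float(np.dot(p, inv_mass * p))


def _uturn(theta_plus, theta_minus, p_plus, p_minus, inv_mass):
    dtheta = theta_plus - theta_minus
    return (
        np.dot(dtheta, inv_mass * p_minus) < 0
        or np.dot(dtheta, inv_mass * p_plus) < 0
    )


def _build_tree(logp_grad, theta, p, grad, direction, depth, eps, inv_mass,
                h0, rng) -> _Tree:
    """Recursively build one subtree of 2**depth leapfrog steps."""
    if depth == 0:
        theta1, p1, lp1, grad1 = _leapfrog(
            logp_grad, theta, p, grad, direction * eps, inv_mass
        )
        if math.isfinite(lp1):
            delta = (-lp1 + _kinetic(p1, inv_mass)) - h0
        else:
            delta = float("inf")
        tree = _Tree()
        tree.theta_minus = tree.theta_plus = tree.theta_prop = theta1
        tree.p_minus = tree.p_plus = p1
        tree.grad_minus = tree.grad_plus = grad1
        tree.log_sum_weight = -delta
        tree.sum_accept = min(1.0, math.exp(-delta)) if delta > 0 else 1.0
        tree.n_leapfrog = 1
        tree.divergent = delta > _MAX_DELTA_H
        tree.valid = not tree.divergent
        return tree

    first = _build_tree(
        logp_grad, theta, p, grad, direction, depth - 1, eps, inv_mass, h0, rng
    )
    if not first.valid:
        return first
    if direction == 1:
        second = _build_tree(
            logp_grad, first.theta_plus, first.p_plus, first.grad_plus,
            direction, depth - 1, eps, inv_mass, h0, rng,
        )
        first.theta_plus = second.theta_plus
        first.p_plus = second.p_plus
        first.grad_plus = second.grad_plus
    else:
        second = _build_tree(
            logp_grad, first.theta_minus, first.p_minus, first.grad_minus,
            direction, depth - 1, eps, inv_mass, h0, rng,
        )
        first.theta_minus = second.theta_minus
        first.p_minus = second.p_minus
        first.grad_minus = second.grad_minus

    first.sum_accept += second.sum_accept
    first.n_leapfrog += second.n_leapfrog
    if not second.valid:
        first.valid = False
        first.divergent = first.divergent or second.divergent
        return first

    total = np.logaddexp(first.log_sum_weight, second.log_sum_weight)
    if math.log(rng.uniform()) < second.log_sum_weight - total:
        first.theta_prop = second.theta_prop
    first.log_sum_weight = total
    first.valid = not _uturn(
        first.theta_plus, first.theta_minus, first.p_plus, first.p_minus,
        inv_mass,
    )
    return first


def _nuts_step(logp_grad, theta, lp, grad, eps, inv_mass, max_depth, rng):
    mass = 1.0 / inv_mass
    p0 = rng.normal(size=theta.shape) * np.sqrt(mass)
    h0 = -lp + _kinetic(p0, inv_mass)

    theta_minus = theta_plus = theta
    p_minus = p_plus = p0
    grad_minus = grad_plus = grad
    theta_prop = theta
    log_sum_weight = 0.0
    sum_accept = 0.0
    n_leapfrog = 0
    divergent = False
    depth = 0

    while depth < max_depth:
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(
                logp_grad, theta_plus, p_plus, grad_plus, 1, depth, eps,
                inv_mass, h0, rng,
            )
            edge_new = (sub.theta_plus, sub.p_plus, sub.grad_plus)
        else:
            sub = _build_tree(
                logp_grad, theta_minus, p_minus, grad_minus, -1, depth, eps,
                inv_mass, h0, rng,
            )
            edge_new = (sub.theta_minus, sub.p_minus, sub.grad_minus)
        sum_accept += sub.sum_accept
        n_leapfrog += sub.n_leapfrog
        if not sub.valid:
            divergent = sub.divergent
            break
        if direction == 1:
            theta_plus, p_plus, grad_plus = edge_new
        else:
            theta_minus, p_minus, grad_minus = edge_new
        # Biased progressive sampling: favour the fresh subtree.
        log_ratio = sub.log_sum_weight - log_sum_weight
        if log_ratio > 0 or math.log(rng.uniform()) < log_ratio:
            theta_prop = sub.theta_prop
        log_sum_weight = np.logaddexp(log_sum_weight, sub.log_sum_weight)
        depth += 1
        if _uturn(theta_plus, theta_minus, p_plus, p_minus, inv_mass):
            break

    accept_stat = sum_accept / max(n_leapfrog, 1)
    return theta_prop, accept_stat, divergent, depth


def _find_initial_step(logp_grad, theta, lp, grad, inv_mass, rng):
    """Heuristic doubling/halving search for a workable step size."""
    eps = 1.0
    mass = 1.0 / inv_mass
    p0 = rng.normal(size=theta.shape) * np.sqrt(mass)
    h0 = -lp + _kinetic(p0, inv_mass)

    def log_ratio(eps_try):
        _, p1, lp1, _ = _leapfrog(logp_grad, theta, p0, grad, eps_try, inv_mass)
        if not math.isfinite(lp1):
            return float("-inf")
        return h0 - (-lp1 + _kinetic(p1, inv_mass))

    target = math.log(0.8)
    direction = 1 if log_ratio(eps) > target else -1
    for _ in range(100):
        eps_next = eps * 2.0 ** direction
        r = log_ratio(eps_next)
        if direction == 1 and r < target:
            break
        if direction == -1 and r > target:
            eps = eps_next
            break
        eps = eps_next
        if eps < 1e-10 or eps > 1e7:
            break
    return max(eps, 1e-10)


class _DualAveraging:
    def __init__(self, eps0, target):
        self.target = target
        self.gamma = 0.05
        self.t0 = 10.0
        self.kappa = 0.75
        self.restart(eps0)

    def restart(self, eps):
        self.mu = math.log(10.0 * eps)
        self.h_bar = 0.0
        self.log_eps_bar = 0.0
        self.count = 0

    def update(self, accept_stat):
        self.count += 1
        frac = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_stat)
        log_eps = self.mu - math.sqrt(self.count) / self.gamma * self.h_bar
        weight = self.count ** -self.kappa
        self.log_eps_bar = weight * log_eps + (1 - weight) * self.log_eps_bar
        return math.exp(log_eps)

    def adapted(self):
        return math.exp(self.log_eps_bar)


def _adaptation_windows(cfg: NutsConfig):
    """Warmup iteration counts at which a mass-matrix window closes."""
    ends = []
    start = cfg.init_buffer
    size = cfg.base_window
    last = cfg.warmup - cfg.term_buffer
    while start + size < last:
        nxt = start + size
        if nxt + 2 * size >= last:
            nxt = last
        ends.append(nxt)
        start = nxt
        size *= 2
    if not ends and last > cfg.init_buffer:
        ends.append(last)
    return ends


def sample_chain(
    logp_grad: LogpGrad,
    theta0: np.ndarray,
    rng: np.random.Generator,
    cfg: NutsConfig,
) -> ChainResult:
    """Run warmup + sampling for one chain from the given start position."""
    theta = np.asarray(theta0, dtype=float).copy()
    lp, grad = logp_grad(theta)
    if not math.isfinite(lp):
        raise SamplingError("non-finite log density at the initial position")

    dim = theta.size
    inv_mass = np.ones(dim)
    eps = _find_initial_step(logp_grad, theta, lp, grad, inv_mass, rng)
    da = _DualAveraging(eps, cfg.target_accept)

    window_ends = _adaptation_windows(cfg)
    w_count = 0
    w_mean = np.zeros(dim)
    w_m2 = np.zeros(dim)

    for it in range(cfg.warmup):
        theta, accept_stat, _, _ = _nuts_step(
            logp_grad, theta, lp, grad, eps, inv_mass, cfg.max_treedepth, rng,
        )
        lp, grad = logp_grad(theta)
        eps = da.update(accept_stat)
        if it >= cfg.init_buffer:
            w_count += 1
            delta = theta - w_mean
            w_mean += delta / w_count
            w_m2 += delta * (theta - w_mean)
        if window_ends and it + 1 == window_ends[0]:
            window_ends.pop(0)
            if w_count > 1:
                var = w_m2 / (w_count - 1)
                inv_mass = (
                    w_count / (w_count + 5.0) * var
                    + 1e-3 * (5.0 / (w_count + 5.0))
                )
            w_count = 0
            w_mean[:] = 0.0
            w_m2[:] = 0.0
            eps = _find_initial_step(logp_grad, theta, lp, grad, inv_mass, rng)
            da.restart(eps)
    if cfg.warmup > 0:
        eps = da.adapted()

    draws = np.empty((cfg.draws, dim))
    divergent = np.zeros(cfg.draws, dtype=bool)
    accept = np.empty(cfg.draws)
    depth_arr = np.empty(cfg.draws, dtype=np.int64)
    for it in range(cfg.draws):
        theta, accept_stat, div, depth = _nuts_step(
            logp_grad, theta, lp, grad, eps, inv_mass, cfg.max_treedepth, rng,
        )
        lp, grad = logp_grad(theta)
        draws[it] = theta
        divergent[it] = div
        accept[it] = accept_stat
        depth_arr[it] = depth
    return ChainResult(draws, divergent, accept, depth_arr, eps, inv_mass)
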