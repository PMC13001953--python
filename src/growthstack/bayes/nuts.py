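"""No-U-Turn sampler with dual-averaging step size and adaptive mass matrix.

This is a standard adaptive Hamiltonian Monte Carlo implementation: leapfrog
dynamics on the unconstrained parameter space, multinomial sampling over the
trajectory, the generalized no-u-turn termination criterion, dual averaging of
the step size toward a target acceptance statistic, and windowed estimation of
the inverse mass matrix from warmup draws.  It needs only a function returning
the log density and its gradient.

The mass matrix can be diagonal or dense; dense adaptation (the default here)
matters for posteriors with correlated soft-identified directions, e.g. an
intercept alongside a full one-hot indicator block held together only by its
prior.  Warmup follows the usual three-phase layout: a fast initial buffer
(step size only), doubling slow windows (mass matrix), and a fast terminal
buffer (step size again).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular

__all__ = ["sample_chain", "ChainResult"]

MAX_ENERGY_ERROR = 1000.0  # divergence threshold on energy drift


class _Metric:
    """Euclidean metric: inverse mass = estimated posterior (co)variance."""

    def __init__(self, inv_mass: np.ndarray):
        self.inv_mass = inv_mass
        self.diag = inv_mass.ndim == 1
        if self.diag:
            self._mom_sd = 1.0 / np.sqrt(inv_mass)
        else:
            # inv_mass = Sigma = L L^T; momentum ~ N(0, Sigma^{-1}) = L^{-T} xi
            self._chol = cholesky(inv_mass, lower=True)

    def velocity(self, p: np.ndarray) -> np.ndarray:
        return self.inv_mass * p if self.diag else self.inv_mass @ p

    def kinetic(self, p: np.ndarray) -> float:
        with np.errstate(over="ignore", invalid="ignore"):
            return 0.5 * float(p @ self.velocity(p))

    def sample_momentum(self, rng: np.random.Generator, dim: int) -> np.ndarray:
        xi = rng.normal(size=dim)
        if self.diag:
            return xi * self._mom_sd
        return solve_triangular(self._chol.T, xi, lower=False)


@dataclass
class ChainResult:
    draws: np.ndarray              # (n_draws, dim) post-warmup positions
    divergences: int               # count during sampling phase
    step_size: float
    inv_mass: np.ndarray           # final inverse mass (vector or matrix)
    mean_accept: float
    mean_treedepth: float
    warmup_divergences: int = 0


class _Tree:
    """State bundle for one trajectory subtree."""

    __slots__ = (
        "z_minus", "p_minus", "grad_minus",
        "z_plus", "p_plus", "grad_plus",
        "z_prop", "logp_prop", "grad_prop",
        "log_sum_w", "rho", "stop", "n_div", "sum_accept", "n_accept",
    )


def _leapfrog(logp_grad, z, p, grad, eps, metric):
    p_half = p + 0.5 * eps * grad
    z_new = z + eps * metric.velocity(p_half)
    logp_new, grad_new = logp_grad(z_new)
    p_new = p_half + 0.5 * eps * grad_new
    return z_new, p_new, logp_new, grad_new


def _uturn(rho, p_minus, p_plus, metric):
    return (
        float(rho @ metric.velocity(p_minus)) < 0.0
        or float(rho @ metric.velocity(p_plus)) < 0.0
    )


def _build_tree(logp_grad, z, p, grad, direction, depth, eps, H0, metric, rng):
    if depth == 0:
        z1, p1, logp1, grad1 = _leapfrog(logp_grad, z, p, grad, direction * eps, metric)
        tree = _Tree()
        H = (logp1 - metric.kinetic(p1)) if np.isfinite(logp1) else -np.inf
        energy_error = H - H0
        tree.z_minus = tree.z_plus = tree.z_prop = z1
        tree.p_minus = tree.p_plus = p1
        tree.grad_minus = tree.grad_plus = tree.grad_prop = grad1
        tree.logp_prop = logp1
        tree.rho = p1.copy()
        divergent = (not np.isfinite(energy_error)) or (energy_error < -MAX_ENERGY_ERROR)
        tree.n_div = int(divergent)
        tree.stop = divergent
        tree.log_sum_w = -np.inf if divergent else energy_error
        tree.sum_accept = min(1.0, math.exp(min(energy_error, 0.0))) if np.isfinite(energy_error) else 0.0
        tree.n_accept = 1
        return tree

    inner = _build_tree(logp_grad, z, p, grad, direction, depth - 1, eps, H0, metric, rng)
    if inner.stop:
        return inner
    if direction == 1:
        outer = _build_tree(
            logp_grad, inner.z_plus, inner.p_plus, inner.grad_plus,
            direction, depth - 1, eps, H0, metric, rng,
        )
        inner.z_plus, inner.p_plus, inner.grad_plus = outer.z_plus, outer.p_plus, outer.grad_plus
    else:
        outer = _build_tree(
            logp_grad, inner.z_minus, inner.p_minus, inner.grad_minus,
            direction, depth - 1, eps, H0, metric, rng,
        )
        inner.z_minus, inner.p_minus, inner.grad_minus = outer.z_minus, outer.p_minus, outer.grad_minus

    total = np.logaddexp(inner.log_sum_w, outer.log_sum_w)
    if np.isfinite(outer.log_sum_w) and math.log(rng.uniform()) < outer.log_sum_w - total:
        inner.z_prop, inner.logp_prop, inner.grad_prop = outer.z_prop, outer.logp_prop, outer.grad_prop
    inner.log_sum_w = total
    inner.rho = inner.rho + outer.rho
    inner.n_div += outer.n_div
    inner.sum_accept += outer.sum_accept
    inner.n_accept += outer.n_accept
    inner.stop = outer.stop or _uturn(inner.rho, inner.p_minus, inner.p_plus, metric)
    return inner


def _nuts_step(logp_grad, z, logp, grad, eps, metric, rng, max_treedepth):
    p0 = metric.sample_momentum(rng, z.size)
    H0 = logp - metric.kinetic(p0)

    tree = _Tree()
    tree.z_minus = tree.z_plus = tree.z_prop = z
    tree.p_minus = tree.p_plus = p0
    tree.grad_minus = tree.grad_plus = tree.grad_prop = grad
    tree.logp_prop = logp
    tree.rho = p0.copy()
    tree.log_sum_w = 0.0
    tree.n_div = 0
    sum_accept, n_accept = 0.0, 0

    depth = 0
    while depth < max_treedepth:
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(logp_grad, tree.z_plus, tree.p_plus, tree.grad_plus,
                              1, depth, eps, H0, metric, rng)
            tree.z_plus, tree.p_plus, tree.grad_plus = sub.z_plus, sub.p_plus, sub.grad_plus
        else:
            sub = _build_tree(logp_grad, tree.z_minus, tree.p_minus, tree.grad_minus,
                              -1, depth, eps, H0, metric, rng)
            tree.z_minus, tree.p_minus, tree.grad_minus = sub.z_minus, sub.p_minus, sub.grad_minus

        tree.n_div += sub.n_div
        sum_accept += sub.sum_accept
        n_accept += sub.n_accept
        if sub.stop:
            break
        # biased progressive sampling: favour the new subtree
        if np.isfinite(sub.log_sum_w) and math.log(rng.uniform()) < sub.log_sum_w - tree.log_sum_w:
            tree.z_prop, tree.logp_prop, tree.grad_prop = sub.z_prop, sub.logp_prop, sub.grad_prop
        tree.log_sum_w = np.logaddexp(tree.log_sum_w, sub.log_sum_w)
        depth += 1
        if _uturn(tree.rho + sub.rho, tree.p_minus, tree.p_plus, metric):
            tree.rho = tree.rho + sub.rho
            break
        tree.rho = tree.rho + sub.rho

    accept_stat = sum_accept / max(n_accept, 1)
    return tree.z_prop, tree.logp_prop, tree.grad_prop, tree.n_div, accept_stat, depth


def _find_reasonable_epsilon(logp_grad, z, logp, grad, metric, rng):
    eps = 1.0
    p = metric.sample_momentum(rng, z.size)
    H0 = logp - metric.kinetic(p)
    _, p1, logp1, _ = _leapfrog(logp_grad, z, p, grad, eps, metric)
    H1 = (logp1 - metric.kinetic(p1)) if np.isfinite(logp1) else -np.inf
    direction = 1.0 if (H1 - H0) > math.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        _, p1, logp1, _ = _leapfrog(logp_grad, z, p, grad, eps, metric)
        H1 = (logp1 - metric.kinetic(p1)) if np.isfinite(logp1) else -np.inf
        ratio = H1 - H0
        if direction == 1.0 and ratio <= math.log(0.5):
            break
        if direction == -1.0 and ratio >= math.log(0.5):
            break
    return max(eps, 1e-10)


@dataclass
class _DualAveraging:
    mu: float
    target: float
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    count: int = field(default=0)
    h_bar: float = field(default=0.0)
    log_eps_bar: float = field(default=0.0)

    def update(self, accept_stat: float) -> float:
        self.count += 1
        frac = 1.0 / (self.count + self.t0)
        self.h_bar = (1.0 - frac) * self.h_bar + frac * (self.target - accept_stat)
        log_eps = self.mu - math.sqrt(self.count) / self.gamma * self.h_bar
        w = self.count ** (-self.kappa)
        self.log_eps_bar = w * log_eps + (1.0 - w) * self.log_eps_bar
        return math.exp(log_eps)


def _warmup_windows(n_tune: int):
    """(start, end, is_slow) phases: fast buffer, doubling slow windows, fast buffer."""
    if n_tune < 40:
        return [(0, n_tune, False)]
    init_buf = min(50, int(0.15 * n_tune))
    term_buf = min(50, int(0.1 * n_tune))
    slow_total = n_tune - init_buf - term_buf
    windows = [(0, init_buf, False)]
    pos, size = init_buf, 25
    while pos < init_buf + slow_total:
        end = min(pos + size, init_buf + slow_total)
        # fold the remainder into the last window so the final (co)variance
        # estimate uses the largest possible sample
        if init_buf + slow_total - end < size * 2:
            end = init_buf + slow_total
        windows.append((pos, end, True))
        pos, size = end, size * 2
    windows.append((init_buf + slow_total, n_tune, False))
    return windows


def _estimate_inv_mass(samples: np.ndarray, dense: bool) -> np.ndarray:
    """Regularized (co)variance estimate from a warmup window, Stan-style."""
    n, dim = samples.shape
    shrink = n / (n + 5.0)
    if dense and n > dim:
        cov = np.cov(samples, rowvar=False)
        reg = shrink * cov + 1e-3 * (5.0 / (n + 5.0)) * np.eye(dim)
        # guard against numerically non-PD estimates
        try:
            cholesky(reg, lower=True)
            return reg
        except np.linalg.LinAlgError:
            pass
    var = samples.var(axis=0, ddof=1)
    return shrink * np.maximum(var, 1e-10) + 1e-3 * (5.0 / (n + 5.0))


def sample_chain(
    logp_grad,
    z0: np.ndarray,
    n_tune: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.95,
    max_treedepth: int = 10,
    dense_mass: bool = True,
    init_inv_mass: np.ndarray | None = None,
    warmup_max_treedepth: int = 8,
) -> ChainResult:
    """Run one adaptive NUTS chain and return post-warmup draws.

    ``init_inv_mass`` seeds the metric with rough posterior variances before
    the first adaptation window; trajectories during warmup are capped at
    ``warmup_max_treedepth`` doublings since early trees under a poorly
    scaled metric can otherwise grow very long.
    """
    z = np.asarray(z0, dtype=float).copy()
    logp, grad = logp_grad(z)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")
    dim = z.size
    metric = _Metric(np.ones(dim) if init_inv_mass is None else np.asarray(init_inv_mass, dtype=float))

    eps = _find_reasonable_epsilon(logp_grad, z, logp, grad, metric, rng)
    da = _DualAveraging(mu=math.log(10.0 * eps), target=target_accept)

    warmup_div = 0
    for (start, end, is_slow) in _warmup_windows(n_tune):
        window = np.empty((end - start, dim)) if is_slow else None
        for i in range(end - start):
            z, logp, grad, ndiv, accept, _ = _nuts_step(
                logp_grad, z, logp, grad, eps, metric, rng,
                min(max_treedepth, warmup_max_treedepth),
            )
            warmup_div += ndiv
            eps = da.update(accept)
            if is_slow:
                window[i] = z
        if is_slow and len(window) > 1:
            metric = _Metric(_estimate_inv_mass(window, dense_mass))
            eps = _find_reasonable_epsilon(logp_grad, z, logp, grad, metric, rng)
            da = _DualAveraging(mu=math.log(10.0 * eps), target=target_accept)

    eps = math.exp(da.log_eps_bar) if da.count else eps

    draws = np.empty((n_draws, dim))
    divergences = 0
    accept_sum = 0.0
    depth_sum = 0
    for i in range(n_draws):
        z, logp, grad, ndiv, accept, depth = _nuts_step(
            logp_grad, z, logp, grad, eps, metric, rng, max_treedepth
        )
        draws[i] = z
        divergences += ndiv
        accept_sum += accept
        depth_sum += depth

    return ChainResult(
        draws=draws,
        divergences=divergences,
        step_size=eps,
        inv_mass=metric.inv_mass,
        mean_accept=accept_sum / max(n_draws, 1),
        mean_treedepth=depth_sum / max(n_draws, 1),
        warmup_divergences=warmup_div,
    )
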