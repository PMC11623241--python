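"""A self-contained No-U-Turn sampler over a differentiable log density.

Implements the dynamic-trajectory NUTS of Hoffman & Gelman with slice
sampling across the doubling tree, dual-averaging step-size adaptation
toward a target acceptance statistic, and a diagonal mass matrix estimated
during warmup.  The sampler is deliberately generic: it sees only a
callable ``logp_and_grad(x) -> (float, ndarray)`` on an unconstrained
parameter vector, so every model variant in this package shares one kernel.

Determinism: all randomness flows through the ``numpy.random.Generator``
passed in, so a fixed seed yields bit-identical chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["NutsResult", "nuts_sample"]

_DIVERGENCE_THRESHOLD = 1000.0  # energy error above which a leapfrog diverged


@dataclass
class NutsResult:
    """Draws and per-draw diagnostics from one chain."""

    draws: np.ndarray               # (n_samples, dim)
    logp: np.ndarray                # (n_samples,)
    divergent: np.ndarray           # (n_samples,) bool, post-warmup only
    tree_depth: np.ndarray          # (n_samples,)
    accept_stat: np.ndarray         # (n_samples,) mean Metropolis statistic
    step_size: float
    inv_mass: np.ndarray            # diagonal of the inverse mass matrix
    n_divergent_warmup: int = 0


def _joint(logp, p, inv_mass):
    return logp - 0.5 * np.dot(p, inv_mass * p)


def _make_leapfrog(logp_and_grad):
    """Python leapfrog returning (x1, p1, logp1, grad1, joint1)."""

    def lf(x, p, grad, eps, inv_mass):
        p1 = p + 0.5 * eps * grad
        x1 = x + eps * inv_mass * p1
        logp, grad1 = logp_and_grad(x1)
        p1 = p1 + 0.5 * eps * grad1
        joint = _joint(logp, p1, inv_mass) if np.isfinite(logp) else -np.inf
        return x1, p1, logp, grad1, joint

    return lf


def _initial_step_size(lf, logp_and_grad, x0, rng, inv_mass):
    """Heuristic: double/halve eps until the one-step accept prob crosses 1/2."""
    logp0, grad0 = logp_and_grad(x0)
    if not np.isfinite(logp0):
        raise FloatingPointError("non-finite log density at initialization")
    eps = 1.0
    p0 = rng.standard_normal(len(x0)) / np.sqrt(inv_mass)
    joint0 = _joint(logp0, p0, inv_mass)
    delta = lf(x0, p0, grad0, eps, inv_mass)[4] - joint0
    while not np.isfinite(delta):
        eps *= 0.5
        if eps < 1e-10:
            raise FloatingPointError("could not find a finite initial step size")
        delta = lf(x0, p0, grad0, eps, inv_mass)[4] - joint0
    direction = 1.0 if delta > np.log(0.5) else -1.0
    while direction * delta > -direction * np.log(2.0):
        eps *= 2.0 ** direction
        if eps > 1e7 or eps < 1e-10:
            break
        delta = lf(x0, p0, grad0, eps, inv_mass)[4] - joint0
        if not np.isfinite(delta):
            delta = -np.inf
    return eps


class _Tree:
    """State bundle for recursive tree doubling."""

    __slots__ = (
        "x_minus", "p_minus", "grad_minus",
        "x_plus", "p_plus", "grad_plus",
        "x_prop", "logp_prop", "n", "keep_going",
        "sum_accept", "n_accept", "divergent",
    )


def _build_tree(lf, x, p, grad, logp, log_u, direction, depth,
                eps, joint0, inv_mass, rng):
    if depth == 0:
        x1, p1, logp1, grad1, joint = lf(x, p, grad, direction * eps, inv_mass)
        t = _Tree()
        t.x_minus = t.x_plus = t.x_prop = x1
        t.p_minus = t.p_plus = p1
        t.grad_minus = t.grad_plus = grad1
        t.logp_prop = logp1
        t.n = 1 if log_u <= joint else 0
        t.divergent = log_u > joint + _DIVERGENCE_THRESHOLD
        t.keep_going = not t.divergent
        t.sum_accept = (
            min(1.0, np.exp(min(joint - joint0, 0.0))) if np.isfinite(joint) else 0.0
        )
        t.n_accept = 1
        return t

    t = _build_tree(lf, x, p, grad, logp, log_u, direction,
                    depth - 1, eps, joint0, inv_mass, rng)
    if t.keep_going:
        if direction == -1:
            t2 = _build_tree(lf, t.x_minus, t.p_minus, t.grad_minus,
                             logp, log_u, direction, depth - 1, eps, joint0,
                             inv_mass, rng)
            t.x_minus, t.p_minus, t.grad_minus = t2.x_minus, t2.p_minus, t2.grad_minus
        else:
            t2 = _build_tree(lf, t.x_plus, t.p_plus, t.grad_plus,
                             logp, log_u, direction, depth - 1, eps, joint0,
                             inv_mass, rng)
            t.x_plus, t.p_plus, t.grad_plus = t2.x_plus, t2.p_plus, t2.grad_plus
        if t2.n > 0 and rng.uniform() < t2.n / max(t.n + t2.n, 1):
            t.x_prop, t.logp_prop = t2.x_prop, t2.logp_prop
        t.n += t2.n
        t.sum_accept += t2.sum_accept
        t.n_accept += t2.n_accept
        t.divergent = t.divergent or t2.divergent
        span = t.x_plus - t.x_minus
        no_uturn = (
            np.dot(span, inv_mass * t.p_minus) >= 0
            and np.dot(span, inv_mass * t.p_plus) >= 0
        )
        t.keep_going = t2.keep_going and no_uturn
    return t


def _nuts_step(lf, x, logp, grad, eps, inv_mass, rng, max_depth):
    p0 = rng.standard_normal(len(x)) / np.sqrt(inv_mass)
    joint0 = _joint(logp, p0, inv_mass)
    log_u = joint0 + np.log(rng.uniform())
    x_minus = x_plus = x
    p_minus = p_plus = p0
    grad_minus = grad_plus = grad
    x_new, logp_new = x, logp
    n, depth = 1, 0
    divergent = False
    sum_accept, n_accept = 0.0, 0
    keep_going = True
    while keep_going and depth < max_depth:
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == -1:
            t = _build_tree(lf, x_minus, p_minus, grad_minus, logp,
                            log_u, direction, depth, eps, joint0, inv_mass, rng)
            x_minus, p_minus, grad_minus = t.x_minus, t.p_minus, t.grad_minus
        else:
            t = _build_tree(lf, x_plus, p_plus, grad_plus, logp,
                            log_u, direction, depth, eps, joint0, inv_mass, rng)
            x_plus, p_plus, grad_plus = t.x_plus, t.p_plus, t.grad_plus
        if t.keep_going and t.n > 0 and rng.uniform() < min(1.0, t.n / n):
            x_new, logp_new = t.x_prop, t.logp_prop
        n += t.n
        sum_accept += t.sum_accept
        n_accept += t.n_accept
        divergent = divergent or t.divergent
        span = x_plus - x_minus
        keep_going = (
            t.keep_going
            and np.dot(span, inv_mass * p_minus) >= 0
            and np.dot(span, inv_mass * p_plus) >= 0
        )
        depth += 1
    accept_stat = sum_accept / max(n_accept, 1)
    return x_new, logp_new, depth, divergent, accept_stat


@dataclass
class _DualAveraging:
    """Nesterov dual averaging of log step size toward a target accept rate."""

    mu: float
    target: float = 0.8
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    _count: int = 0
    _h_bar: float = 0.0
    _log_eps_bar: float = 0.0

    def update(self, accept_stat: float) -> float:
        self._count += 1
        frac = 1.0 / (self._count + self.t0)
        self._h_bar = (1 - frac) * self._h_bar + frac * (self.target - accept_stat)
        log_eps = self.mu - np.sqrt(self._count) / self.gamma * self._h_bar
        weight = self._count ** (-self.kappa)
        self._log_eps_bar = weight * log_eps + (1 - weight) * self._log_eps_bar
        return float(np.exp(log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self._log_eps_bar))


def nuts_sample(
    logp_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    n_warmup: int,
    n_samples: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    leapfrog: Callable | None = None,
) -> NutsResult:
    """Run one NUTS chain: warmup (adaptation) then ``n_samples`` draws.

    Warmup follows the familiar three-stage schedule: an initial fast
    interval adapting only the step size, a sequence of doubling
    "slow" windows each ending in a diagonal mass-matrix re-estimate
    (with a dual-averaging restart), and a terminal fast interval
    polishing the step size under the final metric.  With fewer than 100
    warmup iterations, mass estimation is skipped.
    """
    x = np.array(x0, dtype=float)
    dim = len(x)
    inv_mass = np.ones(dim)
    lf = leapfrog if leapfrog is not None else _make_leapfrog(logp_and_grad)
    logp, grad = logp_and_grad(x)
    if not np.isfinite(logp):
        raise FloatingPointError("non-finite log density at the initial point")

    n_div_warmup = 0

    def run_phase(n_iter, eps, inv_mass, collect=False):
        nonlocal x, logp, grad, n_div_warmup
        da = _DualAveraging(mu=np.log(10.0 * eps), target=target_accept)
        window = np.empty((n_iter, dim)) if collect else None
        for it in range(n_iter):
            x, logp, depth, div, astat = _nuts_step(
                lf, x, logp, grad, eps, inv_mass, rng, max_treedepth
            )
            logp, grad = logp_and_grad(x)  # refresh gradient at accepted point
            eps = da.update(astat)
            if div:
                n_div_warmup += 1
            if collect:
                window[it] = x
        return da.adapted, window

    def estimate_mass(window):
        n_w = len(window)
        var = np.var(window, axis=0, ddof=1)
        # shrink toward a small unit-ish floor, Stan-style regularization
        var = (n_w / (n_w + 5.0)) * var + (5.0 / (n_w + 5.0)) * 1e-3
        return np.maximum(var, 1e-10)

    if n_warmup >= 100:
        n_init = max(20, int(0.15 * n_warmup))
        n_term = max(20, int(0.10 * n_warmup))
        n_slow = n_warmup - n_init - n_term
        windows = []
        w = max(25, n_slow // 15)
        remaining = n_slow
        while remaining > 0:
            w_eff = w if remaining >= 3 * w else remaining
            windows.append(min(w_eff, remaining))
            remaining -= windows[-1]
            w *= 2
        eps = _initial_step_size(lf, logp_and_grad, x, rng, inv_mass)
        eps, _ = run_phase(n_init, eps, inv_mass)
        for w_len in windows:
            eps, window = run_phase(w_len, eps, inv_mass, collect=True)
            if w_len >= 10:
                inv_mass = estimate_mass(window)
        eps, _ = run_phase(n_term, eps, inv_mass)
    else:
        eps = _initial_step_size(lf, logp_and_grad, x, rng, inv_mass)
        eps, _ = run_phase(n_warmup, eps, inv_mass)

    draws = np.empty((n_samples, dim))
    logps = np.empty(n_samples)
    divergent = np.zeros(n_samples, dtype=bool)
    depths = np.zeros(n_samples, dtype=np.int8)
    astats = np.zeros(n_samples)
    for it in range(n_samples):
        x, logp, depth, div, astat = _nuts_step(
            lf, x, logp, grad, eps, inv_mass, rng, max_treedepth
        )
        logp, grad = logp_and_grad(x)
        draws[it] = x
        logps[it] = logp
        divergent[it] = div
        depths[it] = depth
        astats[it] = astat
    return NutsResult(
        draws=draws,
        logp=logps,
        divergent=divergent,
        tree_depth=depths,
        accept_stat=astats,
        step_size=float(eps),
        inv_mass=inv_mass,
        n_divergent_warmup=n_div_warmup,
    )
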