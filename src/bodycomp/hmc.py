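"""A compact Hamiltonian Monte Carlo sampler with warmup adaptation.

Gradient-based MCMC for smooth, unconstrained log-densities.  Warmup adapts
the leapfrog step size by dual averaging towards a target acceptance
probability and estimates a dense mass matrix (posterior covariance) from an
intermediate adaptation window; sampling then runs with both frozen.
Preconditioning is implemented as a Cholesky change of variables
``x = L @ xi`` with ``L L' = Cov(x)``, so the chain integrates a roughly
isotropic density with unit mass.  Trajectory lengths are jittered around a
fixed path length to avoid resonance.

This is deliberately a minimal fixed-path-length HMC, not NUTS: the
posteriors it targets here (a hierarchical linear model with a non-centered
random effect) are close to Gaussian after the covariance preconditioning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class HMCTrace:
    """Post-warmup draws of one chain plus sampler diagnostics."""

    draws: np.ndarray  # (n_draws, dim)
    accept_rate: float
    step_size: float
    n_divergent: int


class _DualAveraging:
    """Nesterov dual averaging of log step size (Stan's scheme and constants)."""

    def __init__(self, eps0: float, target: float):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_prob: float) -> float:
        self.count += 1
        w = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - w) * self.h_bar + w * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        eta = self.count**-self.kappa
        self.log_eps_bar = eta * self.log_eps + (1 - eta) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


class _Preconditioned:
    """The target density in whitened coordinates ``xi`` with ``x = L @ xi``."""

    def __init__(self, logp_grad: LogpGrad, L: np.ndarray):
        self.logp_grad = logp_grad
        self.L = L

    def to_x(self, xi: np.ndarray) -> np.ndarray:
        return self.L @ xi

    def to_xi(self, x: np.ndarray) -> np.ndarray:
        return np.linalg.solve(self.L, x)

    def __call__(self, xi: np.ndarray) -> tuple[float, np.ndarray]:
        lp, g = self.logp_grad(self.L @ xi)
        return lp, self.L.T @ g


def _leapfrog(
    target: _Preconditioned, xi: np.ndarray, p: np.ndarray, eps: float, n_steps: int
) -> tuple[np.ndarray, np.ndarray, float]:
    lp, grad = target(xi)
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        xi = xi + eps * p
        lp, grad = target(xi)
        if not np.all(np.isfinite(grad)) or not np.isfinite(lp):
            return xi, p, -np.inf
        p = p + (eps if step < n_steps - 1 else 0.5 * eps) * grad
    return xi, p, lp


def _find_initial_step(target: _Preconditioned, xi: np.ndarray, rng) -> float:
    """Heuristic initial step: double/halve until acceptance crosses 0.5."""
    eps = 0.1
    lp0, _ = target(xi)
    p = rng.standard_normal(xi.size)
    h0 = lp0 - 0.5 * p @ p

    def h_after(eps: float) -> float:
        _, p1, lp1 = _leapfrog(target, xi, p, eps, 1)
        return (lp1 - 0.5 * p1 @ p1) if np.isfinite(lp1) else -np.inf

    direction = 1.0 if (h_after(eps) - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        if direction * (h_after(eps) - h0) <= direction * np.log(0.5):
            break
    return float(eps)


def sample_chain(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_draws: int,
    n_warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    path_length: float = 2.5,
    max_leapfrog: int = 256,
) -> HMCTrace:
    """Run one HMC chain: *n_warmup* adaptation iterations, then *n_draws*.

    ``path_length`` is the nominal integration time in whitened coordinates
    (posterior SDs ~ 1 after adaptation); leapfrog steps per iteration are
    ``round(path_length / eps)``, jittered by a uniform factor in [0.7, 1.3]
    and capped at *max_leapfrog*.
    """
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    target = _Preconditioned(logp_grad, np.eye(dim))
    xi = x.copy()

    # warmup window layout (fractions of n_warmup): step-size burn-in,
    # covariance-estimation window, final step-size polish
    w1 = max(1, int(0.15 * n_warmup))
    w3 = max(1, int(0.10 * n_warmup))
    w2 = max(1, n_warmup - w1 - w3)

    n_divergent = 0

    def one_iter(eps: float) -> float:
        nonlocal xi, n_divergent
        n_steps = max(1, int(round(path_length / eps * rng.uniform(0.7, 1.3))))
        n_steps = min(n_steps, max_leapfrog)
        p = rng.standard_normal(dim)
        lp0, _ = target(xi)
        h0 = lp0 - 0.5 * p @ p
        xi1, p1, lp1 = _leapfrog(target, xi, p, eps, n_steps)
        h1 = lp1 - 0.5 * p1 @ p1 if np.isfinite(lp1) else -np.inf
        log_alpha = min(0.0, h1 - h0)
        if not np.isfinite(log_alpha):
            log_alpha = -np.inf
            n_divergent += 1
        if np.log(rng.uniform()) < log_alpha:
            xi = xi1
        return float(np.exp(log_alpha))

    eps = _find_initial_step(target, xi, rng)
    da = _DualAveraging(eps, target_accept)
    for _ in range(w1):
        eps = da.update(one_iter(eps))

    window = np.empty((w2, dim))
    for i in range(w2):
        eps = da.update(one_iter(eps))
        window[i] = target.to_x(xi)
    cov = np.cov(window, rowvar=False, ddof=1).reshape(dim, dim)
    # Stan-style shrinkage towards a small diagonal keeps the estimate PD
    shrink = w2 / (w2 + 5.0)
    cov = shrink * cov + (1 - shrink) * 1e-3 * np.eye(dim)
    cov += 1e-10 * np.eye(dim)
    x_cur = target.to_x(xi)
    target = _Preconditioned(logp_grad, np.linalg.cholesky(cov))
    xi = target.to_xi(x_cur)

    eps = _find_initial_step(target, xi, rng)
    da = _DualAveraging(eps, target_accept)
    for _ in range(w3):
        eps = da.update(one_iter(eps))

    eps = da.adapted
    draws = np.empty((n_draws, dim))
    n_accept = 0.0
    for i in range(n_draws):
        n_accept += one_iter(eps)
        draws[i] = target.to_x(xi)

    return HMCTrace(
        draws=draws,
        accept_rate=n_accept / max(n_draws, 1),
        step_size=eps,
        n_divergent=n_divergent,
    )
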