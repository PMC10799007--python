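"""A compact Hamiltonian Monte Carlo sampler with warmup adaptation.

Static-trajectory HMC with:

- dual-averaging step-size adaptation toward a target acceptance rate
  (Nesterov-style averaging, the scheme popularized by NUTS);
- diagonal mass-matrix estimation from the first half of warmup;
- per-iteration jitter of the leapfrog path length to avoid resonances.

Chains are run sequentially and are fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["HMCResult", "sample_hmc"]

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class HMCResult:
    draws: np.ndarray  # (chains, draws, dim)
    accept_rate: np.ndarray  # (chains,)
    step_size: np.ndarray  # (chains,)
    divergences: np.ndarray  # (chains,)


class _DualAveraging:
    """Step-size adaptation (gamma=0.05, t0=10, kappa=0.75)."""

    def __init__(self, eps0: float, target: float):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_prob: float) -> float:
        self.count += 1
        m = self.count
        w = 1.0 / (m + 10.0)
        self.h_bar = (1.0 - w) * self.h_bar + w * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(m) / 0.05 * self.h_bar
        eta = m ** -0.75
        self.log_eps_bar = eta * self.log_eps + (1.0 - eta) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def _leapfrog(
    logp_grad: LogpGrad,
    theta: np.ndarray,
    r: np.ndarray,
    grad: np.ndarray,
    eps: float,
    n_steps: int,
    inv_mass: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    r = r + 0.5 * eps * grad
    for i in range(n_steps):
        theta = theta + eps * inv_mass * r
        lp, grad = logp_grad(theta)
        if not np.isfinite(lp):
            return theta, r, -np.inf, grad
        if i < n_steps - 1:
            r = r + eps * grad
    r = r + 0.5 * eps * grad
    return theta, r, lp, grad


def _run_chain(
    logp_grad: LogpGrad,
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float,
    max_leapfrog: int,
) -> tuple[np.ndarray, float, float, int]:
    dim = theta0.size
    inv_mass = np.ones(dim)
    theta = theta0.copy()
    lp, grad = logp_grad(theta)
    if not np.isfinite(lp):
        raise ValueError("non-finite log density at the initial point")

    eps = 0.1
    da = _DualAveraging(eps, target_accept)
    draws = np.empty((n_draws, dim))
    n_accept = 0
    n_div = 0
    mass_window: list[np.ndarray] = []
    half = max(n_warmup // 2, 1)
    lo = max(max_leapfrog // 2, 1)

    total = n_warmup + n_draws
    for it in range(total):
        warm = it < n_warmup
        n_steps = int(rng.integers(lo, max_leapfrog + 1))
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * float(np.sum(inv_mass * r0 * r0))
        theta_new, r_new, lp_new, grad_new = _leapfrog(
            logp_grad, theta, r0, grad, eps, n_steps, inv_mass
        )
        if np.isfinite(lp_new):
            h1 = lp_new - 0.5 * float(np.sum(inv_mass * r_new * r_new))
            log_ratio = h1 - h0
        else:
            log_ratio = -np.inf
        if log_ratio < -1000.0:
            n_div += 1
        accept_prob = min(1.0, np.exp(min(log_ratio, 0.0)))
        if np.log(rng.random()) < log_ratio:
            theta, lp, grad = theta_new, lp_new, grad_new
            if not warm:
                n_accept += 1

        if warm:
            eps = da.update(accept_prob)
            if it < half:
                if it >= half // 4:
                    mass_window.append(theta.copy())
                if it == half - 1 and len(mass_window) >= 10:
                    var = np.var(np.asarray(mass_window), axis=0, ddof=1)
                    inv_mass = np.clip(var, 1e-6, 1e6)
                    # restart step-size search under the new metric
                    eps = da.adapted if da.adapted > 0 else eps
                    da = _DualAveraging(eps, target_accept)
            if it == n_warmup - 1:
                eps = da.adapted
        else:
            draws[it - n_warmup] = theta

    return draws, n_accept / max(n_draws, 1), eps, n_div


def sample_hmc(
    logp_grad: LogpGrad,
    init: Callable[[np.random.Generator], np.ndarray] | np.ndarray,
    n_chains: int = 4,
    n_warmup: int = 500,
    n_draws: int = 500,
    seed: int = 0,
    target_accept: float = 0.8,
    max_leapfrog: int = 32,
) -> HMCResult:
    """Run ``n_chains`` independent HMC chains; deterministic given ``seed``."""
    if n_chains < 2:
        raise ValueError("at least 2 chains are required for split-Rhat")
    seqs = np.random.SeedSequence(seed).spawn(n_chains)
    all_draws = []
    rates = np.empty(n_chains)
    steps = np.empty(n_chains)
    divs = np.empty(n_chains, dtype=int)
    for c in range(n_chains):
        rng = np.random.default_rng(seqs[c])
        theta0 = init(rng) if callable(init) else np.asarray(init, dtype=float)
        d, rate, eps, ndiv = _run_chain(
            logp_grad, theta0, n_warmup, n_draws, rng, target_accept, max_leapfrog
        )
        all_draws.append(d)
        rates[c] = rate
        steps[c] = eps
        divs[c] = ndiv
    return HMCResult(
        draws=np.asarray(all_draws), accept_rate=rates, step_size=steps, divergences=divs
    )
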