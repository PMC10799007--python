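"""MCMC convergence and model-comparison diagnostics.

``split_rhat`` is the classic potential-scale-reduction factor computed on
half-chains.  ``psis_loo`` wraps arviz's Pareto-smoothed importance-sampling
leave-one-out estimator (Vehtari, Gelman & Gabry) and reports LOOIC on the
deviance scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["split_rhat", "psis_loo", "LooResult"]


def split_rhat(draws: np.ndarray) -> float:
    """Split-R̂ for one scalar parameter.

    Parameters
    ----------
    draws : array (chains, iterations)

    Each chain is split in half; R̂ = sqrt(var_plus / W) where
    W is the mean within-half-chain variance and
    var_plus = (n-1)/n * W + B/n with B the between-half-chain variance.
    Returns NaN (a flagged sentinel) when the draws are constant, where R̂ is
    undefined.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("draws must be 2-D (chains, iterations)")
    m_chains, n_iter = draws.shape
    if m_chains < 2:
        raise ValueError("split-Rhat requires at least 2 chains")
    if n_iter < 4:
        raise ValueError("split-Rhat requires at least 4 draws per chain")
    half = n_iter // 2
    halves = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    n = half
    within = halves.var(axis=1, ddof=1)
    W = within.mean()
    if W == 0.0:
        return float("nan")
    B = n * halves.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


@dataclass
class LooResult:
    elpd_loo: float
    looic: float
    pareto_k: np.ndarray
    se: float
    warning: str | None = None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        flag = f" [{self.warning}]" if self.warning else ""
        return f"LooResult(elpd_loo={self.elpd_loo:.2f}, looic={self.looic:.2f}{flag})"


def psis_loo(log_lik: np.ndarray) -> LooResult:
    """PSIS-LOO from a pointwise log-likelihood array.

    Parameters
    ----------
    log_lik : array (chains, draws, n_points) or (draws, n_points)
        Pointwise log-likelihood; here one point is one subject (summed over
        that subject's trials).

    Returns elpd_loo, LOOIC = -2 * elpd_loo, and the per-point Pareto k
    shape diagnostics.  A warning string is attached when more than half the
    points have k > 0.7.
    """
    import arviz as az

    ll = np.asarray(log_lik, dtype=float)
    if ll.ndim == 2:
        ll = ll[None, :, :]
    if ll.ndim != 3:
        raise ValueError("log_lik must be (chains, draws, points)")
    if not np.isfinite(ll).all():
        raise ValueError("log_lik contains non-finite values")
    n_draws_total = ll.shape[0] * ll.shape[1]
    if n_draws_total < 100:
        raise ValueError(f"need >= 100 posterior draws for PSIS-LOO, got {n_draws_total}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # az.loo requires a posterior group; supply a placeholder variable
        idata = az.from_dict(
            posterior={"_placeholder": np.zeros(ll.shape[:2])},
            log_likelihood={"obs": ll},
        )
        res = az.loo(idata, pointwise=True)
    k = np.asarray(res.pareto_k)
    warn = None
    if (k > 0.7).mean() > 0.5:
        warn = "more than 50% of Pareto k exceed 0.7; PSIS-LOO unreliable"
    elpd = float(res.elpd_loo)
    return LooResult(
        elpd_loo=elpd,
        looic=-2.0 * elpd,
        pareto_k=k,
        se=float(res.se),
        warning=warn,
    )
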