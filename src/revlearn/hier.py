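"""Hierarchical log-posterior (with analytic gradient) for one study cell.

One cell is one treatment-group × context combination.  For each model
parameter k the group level has a location ``mu_k`` (standard-normal prior)
and a scale ``sigma_k`` (half-normal prior, scale 0.2, sampled as
``eta_k = log sigma_k`` with the Jacobian folded into the density).  Subjects
get non-centered standard-normal deviates ``z_sk`` and native parameters

    native_sk = ub_k * Phi(mu_k + sigma_k * z_sk)

where Phi is the standard-normal CDF and ub_k the native upper bound (1 for
probabilities/learning rates, ``beta_max`` for the inverse temperature).

The unconstrained parameter vector is laid out as
``[mu (K), eta (K), z (S*K row-major)]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from . import _kernels

__all__ = ["PriorSpec", "CellPosterior", "MODEL_PARAMS"]

_SQRT2PI = np.sqrt(2.0 * np.pi)

#: native parameter names and upper bounds per model (lower bound 0 for all)
MODEL_PARAMS: dict[str, tuple[tuple[str, float], ...]] = {
    "RP": (("alpha_pos", 1.0), ("alpha_neg", 1.0), ("beta", None)),
    "RW": (("alpha", 1.0), ("beta", None)),
    "EWA": (("phi", 1.0), ("rho", 1.0), ("beta", None)),
}


@dataclass(frozen=True)
class PriorSpec:
    """Hyperpriors: mu ~ N(mu_loc, mu_scale); sigma ~ half-N(0, sigma_scale)."""

    mu_loc: float = 0.0
    mu_scale: float = 1.0
    sigma_scale: float = 0.2

    def __post_init__(self) -> None:
        if self.mu_scale <= 0 or self.sigma_scale <= 0:
            raise ValueError("prior scales must be positive")


def _phi_pdf(u: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * u * u) / _SQRT2PI


@dataclass
class CellPosterior:
    """Log posterior and gradient for one cell's trial data under one model."""

    choices: np.ndarray  # int8 (S, T), 0 = A
    outcomes: np.ndarray  # int8 (S, T)
    model: str = "RP"
    priors: PriorSpec = field(default_factory=PriorSpec)
    beta_max: float = 10.0
    v0: float = 0.5

    def __post_init__(self) -> None:
        if self.model not in MODEL_PARAMS:
            raise ValueError(f"unknown model {self.model!r}")
        self.choices = np.ascontiguousarray(self.choices, dtype=np.int8)
        self.outcomes = np.ascontiguousarray(self.outcomes, dtype=np.int8)
        if self.choices.shape != self.outcomes.shape:
            raise ValueError("choices and outcomes must have matching shapes")
        self.S, self.T = self.choices.shape
        if self.S < 2:
            raise ValueError("hierarchical fit needs at least 2 subjects")
        self.param_names = [name for name, _ in MODEL_PARAMS[self.model]]
        self.K = len(self.param_names)
        self.ub = np.array(
            [self.beta_max if b is None else b for _, b in MODEL_PARAMS[self.model]]
        )
        self.dim = 2 * self.K + self.S * self.K

    # -- layout helpers -------------------------------------------------
    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        K, S = self.K, self.S
        mu = theta[:K]
        eta = theta[K : 2 * K]
        z = theta[2 * K :].reshape(S, K)
        return mu, eta, z

    def natives(self, theta: np.ndarray) -> np.ndarray:
        """Subject-level native parameters, shape (S, K)."""
        mu, eta, z = self.unpack(theta)
        u = mu[None, :] + np.exp(eta)[None, :] * z
        return self.ub[None, :] * ndtr(u)

    def group_natives(self, theta: np.ndarray) -> np.ndarray:
        """Native-scale group-level location: ub * Phi(mu), shape (K,)."""
        mu, _, _ = self.unpack(theta)
        return self.ub * ndtr(mu)

    def _subject_nll_grad(self, nat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.model == "RP":
            return _kernels.rp_nll_grad(
                self.choices, self.outcomes, nat[:, 0], nat[:, 1], nat[:, 2], self.v0
            )
        if self.model == "RW":
            nll, g = _kernels.rp_nll_grad(
                self.choices, self.outcomes, nat[:, 0], nat[:, 0], nat[:, 1], self.v0
            )
            out = np.empty((self.S, 2))
            out[:, 0] = g[:, 0] + g[:, 1]  # shared learning rate
            out[:, 1] = g[:, 2]
            return nll, out
        nll, g = _kernels.ewa_nll_grad(
            self.choices, self.outcomes, nat[:, 0], nat[:, 1], nat[:, 2], self.v0
        )
        return nll, g

    def subject_nll(self, nat: np.ndarray) -> np.ndarray:
        """Per-subject NLL at native parameters (S, K) — no gradient."""
        if self.model == "RP":
            return _kernels.rp_nll(
                self.choices, self.outcomes, nat[:, 0], nat[:, 1], nat[:, 2], self.v0
            )
        if self.model == "RW":
            return _kernels.rp_nll(
                self.choices, self.outcomes, nat[:, 0], nat[:, 0], nat[:, 1], self.v0
            )
        return _kernels.ewa_nll(
            self.choices, self.outcomes, nat[:, 0], nat[:, 1], nat[:, 2], self.v0
        )

    # -- density ---------------------------------------------------------
    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Unnormalized log posterior density and its gradient."""
        K, S = self.K, self.S
        mu, eta, z = self.unpack(theta)
        sigma = np.exp(eta)
        ss = self.priors.sigma_scale
        ms = self.priors.mu_scale
        ml = self.priors.mu_loc

        lp = -0.5 * np.sum(((mu - ml) / ms) ** 2)
        lp += np.sum(-0.5 * (sigma / ss) ** 2 + eta)  # half-normal + log-Jacobian
        lp += -0.5 * np.sum(z * z)

        u = mu[None, :] + sigma[None, :] * z
        pdf_u = _phi_pdf(u)
        nat = self.ub[None, :] * ndtr(u)
        nll, gnat = self._subject_nll_grad(nat)
        lp -= float(np.sum(nll))

        # d(-nll)/d u_{sk}
        dl_du = -gnat * self.ub[None, :] * pdf_u

        grad = np.empty_like(theta)
        grad[:K] = -(mu - ml) / ms**2 + dl_du.sum(axis=0)
        grad[K : 2 * K] = (-(sigma / ss) ** 2 + 1.0) + (dl_du * z).sum(axis=0) * sigma
        grad[2 * K :] = (-z + dl_du * sigma[None, :]).ravel()
        return float(lp), grad

    def logp(self, theta: np.ndarray) -> float:
        return self.logp_grad(theta)[0]

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        theta = np.zeros(self.dim)
        theta[self.K : 2 * self.K] = np.log(self.priors.sigma_scale)
        theta += 0.1 * rng.standard_normal(self.dim)
        return theta
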