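"""Hierarchical Bayesian estimation of RL model parameters per study cell.

A *cell* is one treatment-group × context combination (e.g. OT × stable);
the study design yields four independent fits, one per cell, each with its
own group-level location and scale per model parameter and non-centered
subject-level deviates (see :mod:`revlearn.hier`).  Sampling is HMC
(:mod:`revlearn.hmc`); convergence is summarized by split-R̂ and models are
compared with PSIS-LOO / LOOIC (:mod:`revlearn.diagnostics`).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import _kernels
from .diagnostics import LooResult, psis_loo, split_rhat
from .hier import MODEL_PARAMS, CellPosterior, PriorSpec
from .hmc import sample_hmc
from .task import TrialSchedule

__all__ = [
    "FitConfig",
    "PosteriorFit",
    "fit_hierarchical",
    "compare_models",
    "posterior_predictive_accuracy",
    "PriorSpec",
]


@dataclass(frozen=True)
class FitConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    target_accept: float = 0.8
    beta_max: float = 10.0
    max_leapfrog: int = 32
    v0: float = 0.5

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("chains must be >= 2 (required for split-Rhat)")
        if self.warmup < 10 or self.draws < 4:
            raise ValueError("warmup/draws too small")


def _data_hash(choices: np.ndarray, outcomes: np.ndarray, subjects: list[str]) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(choices).tobytes())
    h.update(np.ascontiguousarray(outcomes).tobytes())
    h.update("|".join(subjects).encode())
    return h.hexdigest()[:16]


@dataclass
class PosteriorFit:
    """MCMC draws and diagnostics for one model fitted to one cell."""

    model: str
    cell: tuple[str, str]  # (group, context)
    subjects: list[str]
    param_names: list[str]
    mu: np.ndarray  # (chains, draws, K) unconstrained group locations
    sigma: np.ndarray  # (chains, draws, K) group scales
    subject_params: np.ndarray  # (chains, draws, S, K) native scale
    log_lik: np.ndarray  # (chains, draws, S) per-subject pointwise log-lik
    rhat: dict[str, float]
    config: FitConfig
    data_hash: str
    accept_rate: np.ndarray = field(default=None)
    divergences: np.ndarray = field(default=None)

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0] * self.mu.shape[1]

    def group_native_mean(self) -> dict[str, float]:
        """Posterior mean of the native-scale group location ub*Phi(mu)."""
        ub = _upper_bounds(self.model, self.config.beta_max)
        out = {}
        for k, name in enumerate(self.param_names):
            out[name] = float(np.mean(ub[k] * ndtr(self.mu[..., k])))
        return out

    def group_native_interval(self, prob: float = 0.95) -> dict[str, tuple[float, float]]:
        ub = _upper_bounds(self.model, self.config.beta_max)
        lo, hi = (1 - prob) / 2 * 100, (1 + prob) / 2 * 100
        out = {}
        for k, name in enumerate(self.param_names):
            nat = ub[k] * ndtr(self.mu[..., k]).ravel()
            out[name] = (float(np.percentile(nat, lo)), float(np.percentile(nat, hi)))
        return out

    def subject_posterior_mean(self) -> pd.DataFrame:
        means = self.subject_params.mean(axis=(0, 1))  # (S, K)
        df = pd.DataFrame(means, columns=self.param_names)
        df.insert(0, "subject", self.subjects)
        return df

    def max_rhat(self, group_level_only: bool = False) -> float:
        items = self.rhat.items()
        if group_level_only:
            items = [(k, v) for k, v in items if k.startswith(("mu_", "sigma_"))]
        vals = [v for _, v in items if np.isfinite(v)]
        return max(vals) if vals else float("nan")

    def loo(self) -> LooResult:
        return psis_loo(self.log_lik)

    # -- serialization ----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            d / "draws.npz",
            mu=self.mu,
            sigma=self.sigma,
            subject_params=self.subject_params,
            log_lik=self.log_lik,
        )
        pd.DataFrame(
            {"parameter": list(self.rhat), "rhat": list(self.rhat.values())}
        ).to_csv(d / "rhat.csv", index=False)
        meta = {
            "model": self.model,
            "cell": list(self.cell),
            "subjects": self.subjects,
            "param_names": self.param_names,
            "data_hash": self.data_hash,
            "config": {
                k: getattr(self.config, k)
                for k in ("chains", "warmup", "draws", "seed", "target_accept", "beta_max")
            },
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=1))

    @staticmethod
    def load(directory: str | Path) -> "PosteriorFit":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        arrs = np.load(d / "draws.npz")
        rhat_df = pd.read_csv(d / "rhat.csv")
        return PosteriorFit(
            model=meta["model"],
            cell=tuple(meta["cell"]),
            subjects=meta["subjects"],
            param_names=meta["param_names"],
            mu=arrs["mu"],
            sigma=arrs["sigma"],
            subject_params=arrs["subject_params"],
            log_lik=arrs["log_lik"],
            rhat=dict(zip(rhat_df["parameter"], rhat_df["rhat"])),
            config=FitConfig(**meta["config"]),
            data_hash=meta["data_hash"],
        )


def _upper_bounds(model: str, beta_max: float) -> np.ndarray:
    return np.array([beta_max if b is None else b for _, b in MODEL_PARAMS[model]])


def trial_arrays(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pivot a trial table (one cell) into (choices, outcomes, subjects).

    Requires every subject to contribute the same number of trials (the task
    is fixed-length); choices coded 0 = A, 1 = B.
    """
    if len(data) == 0:
        raise ValueError("empty trial table")
    subjects = sorted(data["subject"].unique())
    counts = data.groupby("subject").size()
    if counts.nunique() != 1:
        raise ValueError("all subjects must have the same number of trials")
    T = int(counts.iloc[0])
    choices = np.empty((len(subjects), T), dtype=np.int8)
    outcomes = np.empty((len(subjects), T), dtype=np.int8)
    for i, s in enumerate(subjects):
        sub = data[data["subject"] == s].sort_values("trial")
        choices[i] = (sub["choice"].to_numpy() == "B").astype(np.int8)
        out = sub["outcome"].to_numpy()
        if not np.isin(out, (0, 1)).all():
            raise ValueError(f"non-binary outcome for subject {s}")
        outcomes[i] = out.astype(np.int8)
    return choices, outcomes, subjects


def fit_hierarchical(
    data: pd.DataFrame,
    model: str = "RP",
    priors: PriorSpec | None = None,
    config: FitConfig | None = None,
    cell: tuple[str, str] | None = None,
) -> PosteriorFit:
    """Fit one model to one cell's trial table by HMC.

    ``data`` must contain columns subject, trial, choice, outcome (and
    normally group/context, used to label the fit).  Non-convergence never
    raises: R̂ is reported in ``fit.rhat`` and left to the caller.
    """
    priors = priors or PriorSpec()
    config = config or FitConfig()
    if cell is None:
        g = data["group"].iloc[0] if "group" in data else "NA"
        c = data["context"].iloc[0] if "context" in data else "NA"
        cell = (str(g), str(c))

    choices, outcomes, subjects = trial_arrays(data)
    post = CellPosterior(
        choices=choices,
        outcomes=outcomes,
        model=model,
        priors=priors,
        beta_max=config.beta_max,
        v0=config.v0,
    )
    res = sample_hmc(
        post.logp_grad,
        post.initial_point,
        n_chains=config.chains,
        n_warmup=config.warmup,
        n_draws=config.draws,
        seed=config.seed,
        target_accept=config.target_accept,
        max_leapfrog=config.max_leapfrog,
    )

    C, D, _ = res.draws.shape
    K, S = post.K, post.S
    mu = res.draws[:, :, :K]
    sigma = np.exp(res.draws[:, :, K : 2 * K])
    z = res.draws[:, :, 2 * K :].reshape(C, D, S, K)
    u = mu[:, :, None, :] + sigma[:, :, None, :] * z
    subject_params = post.ub[None, None, None, :] * ndtr(u)

    log_lik = np.empty((C, D, S))
    for c in range(C):
        for d in range(D):
            log_lik[c, d] = -post.subject_nll(subject_params[c, d])

    rhat: dict[str, float] = {}
    for k, name in enumerate(post.param_names):
        rhat[f"mu_{name}"] = split_rhat(mu[:, :, k])
        rhat[f"sigma_{name}"] = split_rhat(sigma[:, :, k])
    for s in range(S):
        for k, name in enumerate(post.param_names):
            rhat[f"{name}[{subjects[s]}]"] = split_rhat(subject_params[:, :, s, k])

    return PosteriorFit(
        model=model,
        cell=cell,
        subjects=subjects,
        param_names=post.param_names,
        mu=mu,
        sigma=sigma,
        subject_params=subject_params,
        log_lik=log_lik,
        rhat=rhat,
        config=config,
        data_hash=_data_hash(choices, outcomes, subjects),
        accept_rate=res.accept_rate,
        divergences=res.divergences,
    )


@dataclass
class ModelComparison:
    table: pd.DataFrame  # rows: model; columns: cell labels (LOOIC values)
    winners: dict[str, str | None]  # cell label -> winning model (None on tie)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ModelComparison(\n{self.table}\nwinners={self.winners})"


def compare_models(fits: list[PosteriorFit]) -> ModelComparison:
    """LOOIC comparison table, one column per cell, one row per model.

    All fits of the same cell must share the same underlying data (hash
    checked).  The per-cell winner is the model with the lowest LOOIC; ties
    are flagged as None.
    """
    cells: dict[str, dict[str, float]] = {}
    hashes: dict[str, str] = {}
    for fit in fits:
        label = f"{fit.cell[1]}_{fit.cell[0]}"
        if label in hashes and hashes[label] != fit.data_hash:
            raise ValueError(f"fits for cell {label} were made on different data")
        hashes[label] = fit.data_hash
        cells.setdefault(label, {})[fit.model] = fit.loo().looic
    table = pd.DataFrame(cells).sort_index()
    winners: dict[str, str | None] = {}
    for label, col in table.items():
        col = col.dropna()
        best = col.idxmin()
        ties = col[np.isclose(col, col.min(), rtol=0, atol=1e-9)]
        winners[str(label)] = None if len(ties) > 1 else str(best)
    return ModelComparison(table=table, winners=winners)


def posterior_predictive_accuracy(
    fit: PosteriorFit,
    schedule: TrialSchedule,
    n_draws: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Per-trial posterior-predictive probability of the optimal choice.

    For a thinned subset of posterior draws, every subject's native parameters
    simulate fresh choices on ``schedule``; the optimal-choice indicator is
    averaged over draws and subjects.  Only defined for the RP/RW family.
    """
    if fit.model not in ("RP", "RW"):
        raise ValueError("posterior predictive simulation implemented for RP/RW")
    rng = np.random.default_rng(seed)
    C, D, S, K = fit.subject_params.shape
    flat = fit.subject_params.reshape(C * D, S, K)
    take = min(n_draws, C * D)
    idx = rng.choice(C * D, size=take, replace=False)
    high_is_A = (schedule.high_shape == "A").astype(np.int8)
    rewarded_is_A = (schedule.rewarded_shape == "A").astype(np.int8)
    T = len(schedule)
    acc = np.zeros(T)
    for i in idx:
        nat = flat[i]
        if fit.model == "RP":
            ap, an, be = nat[:, 0], nat[:, 1], nat[:, 2]
        else:
            ap = an = nat[:, 0]
            be = nat[:, 1]
        u = rng.random((S, T))
        opt = _kernels.rp_simulate_optimal(
            high_is_A, rewarded_is_A, ap, an, be, u, fit.config.v0
        )
        acc += opt.mean(axis=0)
    return acc / take
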