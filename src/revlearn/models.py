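"""Trial-by-trial reinforcement-learning observation models.

Three models of two-armed probabilistic learning with binary outcomes:

``RP`` (reward–punishment)
    Delta-rule update of the chosen option with separate learning rates for
    rewarded (``alpha_pos``) and unrewarded (``alpha_neg``) trials:
    ``v_c <- v_c + alpha * (R - v_c)``.  The unchosen value is untouched.

``RW`` (Rescorla–Wagner)
    Same update with a single learning rate (``alpha_pos == alpha_neg``).

``EWA`` (experience-weighted attraction)
    Per-option experience weight ``n`` with decay ``rho`` and value decay
    ``phi``: ``n' = rho*n + 1``; ``v' = (phi*n*v + R) / n'`` for the chosen
    option only.

Choice follows a softmax on the value difference with inverse temperature
``beta``: ``P(A) = 1 / (1 + exp(-beta*(v_A - v_B)))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from .task import TrialSchedule

__all__ = [
    "RLParams",
    "ValueState",
    "init_state",
    "update_state",
    "choice_probability",
    "negative_log_likelihood",
    "simulate_choices",
    "choice_accuracy",
    "MODELS",
]

Model = Literal["RP", "RW", "EWA"]
MODELS: tuple[str, ...] = ("RP", "RW", "EWA")

#: initial expected value — midpoint of the binary outcome range, so the first
#: prediction error is symmetric for reward and punishment
V0: float = 0.5


@dataclass(frozen=True)
class RLParams:
    alpha_pos: float = 0.0
    alpha_neg: float = 0.0
    beta: float = 0.0
    phi: float = 0.0  # EWA value decay
    rho: float = 0.0  # EWA experience decay

    def __post_init__(self) -> None:
        for name in ("alpha_pos", "alpha_neg", "phi", "rho"):
            x = getattr(self, name)
            if not (0.0 <= x <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {x}")
        if not (self.beta >= 0.0):
            raise ValueError(f"beta must be >= 0, got {self.beta}")

    @staticmethod
    def rw(alpha: float, beta: float) -> "RLParams":
        return RLParams(alpha_pos=alpha, alpha_neg=alpha, beta=beta)


@dataclass(frozen=True)
class ValueState:
    v_A: float = V0
    v_B: float = V0
    n_A: float = 1.0  # EWA experience weights
    n_B: float = 1.0


def init_state(model: Model = "RP", v0: float = V0) -> ValueState:
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    return ValueState(v_A=v0, v_B=v0)


def update_state(
    state: ValueState,
    choice: str,
    outcome: int,
    params: RLParams,
    model: Model = "RP",
) -> ValueState:
    """Advance the value state after feedback on the chosen shape.

    Only the chosen option's value (and, for EWA, its experience weight)
    changes.  The update branch is selected by the realized outcome:
    outcome 1 is positive feedback, 0 negative.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if outcome not in (0, 1):
        raise ValueError(f"outcome must be 0 or 1, got {outcome!r}")
    if choice not in ("A", "B"):
        raise ValueError(f"choice must be 'A' or 'B', got {choice!r}")

    v = state.v_A if choice == "A" else state.v_B
    if model == "EWA":
        n = state.n_A if choice == "A" else state.n_B
        n_new = params.rho * n + 1.0
        v_new = (params.phi * n * v + outcome) / n_new
        if choice == "A":
            return replace(state, v_A=v_new, n_A=n_new)
        return replace(state, v_B=v_new, n_B=n_new)

    alpha = params.alpha_pos if outcome == 1 else params.alpha_neg
    v_new = v + alpha * (outcome - v)
    if choice == "A":
        return replace(state, v_A=v_new)
    return replace(state, v_B=v_new)


def choice_probability(state: ValueState, beta: float) -> float:
    """Softmax probability of choosing shape A; overflow-safe for any beta*dv."""
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    x = beta * (state.v_A - state.v_B)
    # logistic in a form that never overflows
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _validate_trials(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if len(trials) == 0:
        raise ValueError("empty trial sequence")
    choices = trials["choice"].to_numpy()
    outcomes = trials["outcome"].to_numpy()
    if not np.isin(outcomes, (0, 1)).all():
        raise ValueError("outcomes must be binary 0/1")
    return choices, outcomes


def negative_log_likelihood(
    trials: pd.DataFrame,
    params: RLParams,
    model: Model = "RP",
    v0: float = V0,
) -> float:
    """Negative log-likelihood of one subject's choice sequence in one context.

    The state starts at :func:`init_state` and is advanced *after* each
    trial's feedback, so trial ``t``'s choice probability uses values learned
    from trials ``0..t-1``.
    """
    for name in ("alpha_pos", "alpha_neg", "beta", "phi", "rho"):
        if math.isnan(getattr(params, name)):
            raise ValueError(f"NaN parameter: {name}")
    choices, outcomes = _validate_trials(trials)
    state = init_state(model, v0=v0)
    nll = 0.0
    for choice, outcome in zip(choices, outcomes):
        p_a = choice_probability(state, params.beta)
        p = p_a if choice == "A" else 1.0 - p_a
        nll -= math.log(p)
        state = update_state(state, choice, int(outcome), params, model)
    return nll


def simulate_choices(
    schedule: TrialSchedule,
    params: RLParams,
    model: Model = "RP",
    seed: int | np.random.Generator = 0,
    subject: str = "s0",
    group: str = "NA",
    context: str | None = None,
    v0: float = V0,
) -> pd.DataFrame:
    """Simulate an agent on a schedule; returns a trial table.

    The outcome is 1 iff the chosen shape is the schedule's rewarded shape on
    that trial (coupled outcomes).  Columns: subject, group, context, trial,
    choice, outcome.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = init_state(model, v0=v0)
    rewarded = schedule.rewarded_shape
    blocks = schedule.block
    draws = rng.random(len(schedule))
    rows_choice: list[str] = []
    rows_outcome: list[int] = []
    for t in range(len(schedule)):
        p_a = choice_probability(state, params.beta)
        choice = "A" if draws[t] < p_a else "B"
        outcome = int(choice == rewarded[t])
        rows_choice.append(choice)
        rows_outcome.append(outcome)
        state = update_state(state, choice, outcome, params, model)
    ctx = blocks if context is None else np.repeat(context, len(schedule))
    return pd.DataFrame(
        {
            "subject": subject,
            "group": group,
            "context": ctx,
            "trial": np.arange(len(schedule)),
            "choice": rows_choice,
            "outcome": rows_outcome,
        }
    )


def choice_accuracy(trials: pd.DataFrame, schedule: TrialSchedule) -> float:
    """Fraction of trials on which the currently high-probability shape was
    chosen (optimal choice; not the same as the rewarded shape)."""
    if len(trials) != len(schedule):
        raise ValueError(
            f"trial table length {len(trials)} does not match schedule length {len(schedule)}"
        )
    order = trials.sort_values("trial")
    return float((order["choice"].to_numpy() == schedule.high_shape).mean())
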