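"""Stable/volatile probabilistic reward schedules for the two-shape
associative-learning task.

The task presents two shapes (A, B) on every trial; exactly one of them is
rewarded.  In the *stable* block one shape carries a high reward probability
(default 0.75) throughout.  In the *volatile* block the high-probability
shape (default p = 0.80) swaps every ``run_length`` trials (default 20).
Defaults give 80 stable + 100 volatile = 180 trials.

Outcomes are coupled: a single Bernoulli draw per trial assigns the reward to
exactly one shape, so the two shapes' reward probabilities are complementary
(75/25, 80/20).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "TaskDesign",
    "TrialSchedule",
    "make_schedule",
    "reversal_points",
    "stable_design",
    "volatile_design",
]

Shape = Literal["A", "B"]


class ConfigurationError(ValueError):
    """Invalid task/run configuration; the message names the offending field."""


@dataclass(frozen=True)
class TaskDesign:
    """Block structure and reward contingencies of the task."""

    stable_trials: int = 80
    volatile_trials: int = 100
    stable_p_high: float = 0.75
    volatile_p_high: float = 0.80
    run_length: int = 20
    block_order: Literal["stable_first", "volatile_first"] = "stable_first"
    initial_high_shape: Shape = "A"

    def __post_init__(self) -> None:
        if self.stable_trials < 0:
            raise ConfigurationError("stable_trials must be >= 0")
        if self.volatile_trials < 0:
            raise ConfigurationError("volatile_trials must be >= 0")
        if self.stable_trials + self.volatile_trials <= 0:
            raise ConfigurationError("stable_trials + volatile_trials must be positive")
        for name in ("stable_p_high", "volatile_p_high"):
            p = getattr(self, name)
            if not (0.5 < p <= 1.0):
                raise ConfigurationError(f"{name} must lie in (0.5, 1], got {p}")
        if self.run_length <= 0:
            raise ConfigurationError("run_length must be positive")
        if self.volatile_trials % self.run_length != 0:
            raise ConfigurationError(
                f"volatile_trials ({self.volatile_trials}) must be divisible by "
                f"run_length ({self.run_length})"
            )
        if self.block_order not in ("stable_first", "volatile_first"):
            raise ConfigurationError(f"block_order invalid: {self.block_order!r}")
        if self.initial_high_shape not in ("A", "B"):
            raise ConfigurationError(f"initial_high_shape invalid: {self.initial_high_shape!r}")

    @property
    def n_trials(self) -> int:
        return self.stable_trials + self.volatile_trials


def stable_design(**kw) -> TaskDesign:
    """An 80-trial stable-only design (75/25 by default)."""
    return TaskDesign(volatile_trials=0, **kw)


def volatile_design(**kw) -> TaskDesign:
    """A 100-trial volatile-only design (80/20, reversing every 20 by default)."""
    return TaskDesign(stable_trials=0, **kw)


@dataclass(frozen=True)
class TrialSchedule:
    """Realized per-trial schedule.

    ``table`` has columns ``trial`` (0-based), ``block`` ({stable, volatile}),
    ``high_shape`` and ``rewarded_shape`` ({A, B}).
    """

    table: pd.DataFrame
    design: TaskDesign
    seed: int = field(default=0)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def high_shape(self) -> np.ndarray:
        return self.table["high_shape"].to_numpy()

    @property
    def rewarded_shape(self) -> np.ndarray:
        return self.table["rewarded_shape"].to_numpy()

    @property
    def block(self) -> np.ndarray:
        return self.table["block"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @staticmethod
    def read_csv(path: str | Path, design: TaskDesign | None = None, seed: int = 0) -> "TrialSchedule":
        table = pd.read_csv(path)
        required = {"trial", "block", "high_shape", "rewarded_shape"}
        missing = required - set(table.columns)
        if missing:
            raise ConfigurationError(f"schedule file missing columns: {sorted(missing)}")
        if design is None:
            design = _infer_design(table)
        return TrialSchedule(table=table, design=design, seed=seed)


def _infer_design(table: pd.DataFrame) -> TaskDesign:
    n_stable = int((table["block"] == "stable").sum())
    n_vol = int((table["block"] == "volatile").sum())
    run = n_vol
    if n_vol:
        hs = table.loc[table["block"] == "volatile", "high_shape"].to_numpy()
        changes = np.nonzero(hs[1:] != hs[:-1])[0]
        if changes.size:
            run = int(changes[0] + 1)
    return TaskDesign(
        stable_trials=n_stable,
        volatile_trials=n_vol,
        run_length=max(run, 1),
        block_order="stable_first"
        if n_stable == 0 or n_vol == 0 or table["block"].iloc[0] == "stable"
        else "volatile_first",
    )


def _other(shape: str) -> str:
    return "B" if shape == "A" else "A"


def make_schedule(design: TaskDesign, seed: int) -> TrialSchedule:
    """Realize a trial schedule from a design.

    The high-probability-shape trajectory is deterministic given the design;
    only the per-trial outcome draws consume the seed.  On each trial a single
    Bernoulli(p_high) draw decides whether the reward lands on the current
    high shape or on the other one.
    """
    rng = np.random.default_rng(seed)
    blocks: list[str] = []
    high: list[str] = []
    p_high: list[float] = []

    def add_stable() -> None:
        blocks.extend(["stable"] * design.stable_trials)
        high.extend([design.initial_high_shape] * design.stable_trials)
        p_high.extend([design.stable_p_high] * design.stable_trials)

    def add_volatile() -> None:
        shape = design.initial_high_shape
        for t in range(design.volatile_trials):
            if t > 0 and t % design.run_length == 0:
                shape = _other(shape)
            blocks.append("volatile")
            high.append(shape)
            p_high.append(design.volatile_p_high)

    if design.block_order == "stable_first":
        add_stable()
        add_volatile()
    else:
        add_volatile()
        add_stable()

    high_arr = np.asarray(high)
    on_high = rng.random(design.n_trials) < np.asarray(p_high)
    rewarded = np.where(on_high, high_arr, np.vectorize(_other)(high_arr))

    table = pd.DataFrame(
        {
            "trial": np.arange(design.n_trials),
            "block": blocks,
            "high_shape": high_arr,
            "rewarded_shape": rewarded,
        }
    )
    return TrialSchedule(table=table, design=design, seed=seed)


def reversal_points(schedule: TrialSchedule) -> list[int]:
    """Trial indices at which the high-probability shape changes hands."""
    hs = schedule.high_shape
    return list(np.nonzero(hs[1:] != hs[:-1])[0] + 1)
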