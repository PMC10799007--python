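"""Delimited-text I/O and validation for trial tables and long tables."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

__all__ = ["read_trial_table", "write_trial_table", "read_long_table", "ValidationError"]

log = logging.getLogger("revlearn")

TRIAL_COLUMNS = ["subject", "group", "context", "trial", "choice", "outcome"]


class ValidationError(ValueError):
    pass


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a behavior table (CSV/TSV by extension).

    Non-response rows (missing/empty choice or outcome, or an outcome coded
    -1) are dropped with a logged count, mirroring the exclusion of invalid
    trials in real acquisitions.  Raises :class:`ValidationError` on missing
    columns, non-binary outcomes, or duplicate (subject, context, trial)
    keys, naming the offending row where applicable.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"trial table missing columns: {sorted(missing)}")

    n0 = len(df)
    valid_choice = df["choice"].isin(["A", "B"])
    valid_outcome = df["outcome"].notna() & df["outcome"].isin([0, 1, -1])
    nonresponse = ~valid_choice | df["outcome"].isna() | (df["outcome"] == -1)
    bad_outcome = df.index[df["outcome"].notna() & ~df["outcome"].isin([0, 1, -1])]
    if len(bad_outcome):
        raise ValidationError(
            f"non-binary outcome at row {int(bad_outcome[0])}: "
            f"{df.loc[bad_outcome[0], 'outcome']!r}"
        )
    del valid_outcome
    df = df[~nonresponse].copy()
    dropped = n0 - len(df)
    if dropped:
        log.info("dropped %d non-response/invalid trial(s) of %d", dropped, n0)
    df["outcome"] = df["outcome"].astype(int)
    df["trial"] = df["trial"].astype(int)

    dup = df.duplicated(subset=["subject", "context", "trial"])
    if dup.any():
        first = df.index[dup][0]
        raise ValidationError(
            f"duplicate (subject, context, trial) key at row {int(first)}: "
            f"{tuple(df.loc[first, ['subject', 'context', 'trial']])}"
        )
    return df.reset_index(drop=True)


def write_trial_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False, columns=[c for c in TRIAL_COLUMNS if c in df.columns])


def read_long_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format measure table (subject, group, context, value)."""
    df = pd.read_csv(path)
    missing = {"subject", "group", "context", "value"} - set(df.columns)
    if missing:
        raise ValidationError(f"long table missing columns: {sorted(missing)}")
    return df
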