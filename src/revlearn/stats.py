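"""Mixed-design group statistics.

The study design is a 2 × 2 split-plot: treatment (OT vs PLC) between
subjects, context (stable vs volatile) within subjects.  The ANOVA
decomposes each stratum separately — the between-subject effect is tested
against subjects-within-groups, the within-subject effect and the
interaction against the subject × context residual — and reports partial
eta squared (SS_effect / (SS_effect + SS_error)).  With unequal group sizes
the main effects use unweighted (Type III) marginal means, matching the
conventions of standard ANOVA software.

A two-level within factor satisfies sphericity trivially (epsilon = 1), so
the Greenhouse–Geisser correction is an explicit pass-through here.

Also provided: simple-effects t-tests, Pearson/Spearman correlations, the
Fisher z test for comparing two independent correlations, and plain
independent-samples t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "mixed_anova_2x2",
    "simple_effects",
    "correlation",
    "fisher_z_compare",
    "independent_t",
]


@dataclass
class AnovaResult:
    """F, dfs, p, and partial eta^2 per effect; access rows via ``table``."""

    table: pd.DataFrame  # index: treatment, context, interaction
    greenhouse_geisser_epsilon: float = 1.0  # 2-level within factor: exactly 1

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.loc[effect]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AnovaResult(\n{self.table}\n)"


def _check_long_table(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str], list[str]]:
    required = {"subject", "group", "context", "value"}
    if not required <= set(table.columns):
        raise ValueError(f"long table needs columns {sorted(required)}")
    groups = sorted(table["group"].unique())
    contexts = sorted(table["context"].unique())
    if len(groups) != 2 or len(contexts) != 2:
        raise ValueError("mixed_anova_2x2 requires exactly 2 groups and 2 within levels")
    counts = table.groupby(["subject", "context"]).size()
    if (counts != 1).any():
        raise ValueError("each subject needs exactly one value per context")
    per_subj = table.groupby("subject")["context"].nunique()
    if (per_subj != 2).any():
        raise ValueError("every subject must appear in both contexts (missing cells)")
    g_per_subj = table.groupby("subject")["group"].nunique()
    if (g_per_subj != 1).any():
        raise ValueError("subjects must be nested in exactly one group")
    n_per_group = table.drop_duplicates("subject").groupby("group").size()
    if (n_per_group < 2).any():
        raise ValueError("need at least 2 subjects per group")
    return table, groups, contexts


def mixed_anova_2x2(table: pd.DataFrame) -> AnovaResult:
    """Two-way mixed ANOVA (one between, one within factor, 2 levels each).

    ``table`` is long format with columns subject, group, context, value.
    """
    table, groups, contexts = _check_long_table(table)
    wide = table.pivot_table(index=["subject", "group"], columns="context", values="value")
    wide = wide.reset_index()
    g = wide["group"].to_numpy()
    y1 = wide[contexts[0]].to_numpy(dtype=float)
    y2 = wide[contexts[1]].to_numpy(dtype=float)
    n = np.array([(g == grp).sum() for grp in groups], dtype=float)
    N = int(n.sum())
    df_err = N - 2

    # between stratum: subject means against subjects-within-groups
    m = 0.5 * (y1 + y2)
    m_g = np.array([m[g == grp].mean() for grp in groups])
    # Type III: unweighted marginal contrast; SS on the per-subject scale x2 obs
    ss_treat = 2.0 * (m_g[0] - m_g[1]) ** 2 / (1.0 / n[0] + 1.0 / n[1])
    ss_sw = 2.0 * sum(((m[g == grp] - m_g[i]) ** 2).sum() for i, grp in enumerate(groups))
    ms_sw = ss_sw / df_err
    F_treat = ss_treat / ms_sw if ms_sw > 0 else (0.0 if ss_treat == 0 else np.inf)

    # within stratum: per-subject context differences
    d = y1 - y2
    d_g = np.array([d[g == grp].mean() for grp in groups])
    ss_err_d = sum(((d[g == grp] - d_g[i]) ** 2).sum() for i, grp in enumerate(groups))
    # y = mean ± d/2, so SS on the observation scale carries a factor 1/2
    ss_ctx = 0.5 * ((d_g[0] + d_g[1]) / 2.0) ** 2 * 4.0 / (1.0 / n[0] + 1.0 / n[1])
    ss_int = 0.5 * (d_g[0] - d_g[1]) ** 2 / (1.0 / n[0] + 1.0 / n[1])
    ss_err_w = 0.5 * ss_err_d
    ms_err_w = ss_err_w / df_err

    def f_p_eta(ss_eff: float, ms_err: float, ss_err: float) -> tuple[float, float, float]:
        if ms_err > 0:
            F = ss_eff / ms_err
        else:
            F = 0.0 if ss_eff == 0 else np.inf
        p = float(sps.f.sf(F, 1, df_err)) if np.isfinite(F) else 0.0
        denom = ss_eff + ss_err
        eta = float(ss_eff / denom) if denom > 0 else 0.0
        return float(F), p, eta

    rows = {}
    for name, ss_eff, ms_err, ss_err in (
        ("treatment", ss_treat, ms_sw, ss_sw),
        ("context", ss_ctx, ms_err_w, ss_err_w),
        ("interaction", ss_int, ms_err_w, ss_err_w),
    ):
        F, p, eta = f_p_eta(ss_eff, ms_err, ss_err)
        rows[name] = {"F": F, "df1": 1, "df2": df_err, "p": p, "partial_eta_sq": eta}
    return AnovaResult(table=pd.DataFrame(rows).T)


def simple_effects(
    table: pd.DataFrame, within_level: str, variant: str = "student"
) -> tuple[float, float, float]:
    """OT-vs-PLC t-test at one context level: returns (t, df, p).

    No multiplicity correction is applied.
    """
    table, groups, contexts = _check_long_table(table)
    if within_level not in contexts:
        raise ValueError(f"unknown context level {within_level!r} (have {contexts})")
    sub = table[table["context"] == within_level]
    x = sub.loc[sub["group"] == groups[0], "value"].to_numpy(dtype=float)
    y = sub.loc[sub["group"] == groups[1], "value"].to_numpy(dtype=float)
    return independent_t(x, y, variant=variant)


def correlation(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation; returns (r, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return float(r), float(p)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher z test for two independent correlations; returns (z, two-sided p).

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)).  The subtraction
    order is the caller's: swapping the argument pairs negates z.
    """
    for r, n, tag in ((r1, n1, "r1"), (r2, n2, "r2")):
        if not (abs(r) < 1):
            raise ValueError(f"|{tag}| must be < 1, got {r}")
        if n <= 3:
            raise ValueError(f"n for {tag} must exceed 3, got {n}")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def independent_t(x, y, variant: str = "student") -> tuple[float, float, float]:
    """Two-sample t-test; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per sample")
    if variant not in ("student", "welch"):
        raise ValueError(f"variant must be 'student' or 'welch', got {variant!r}")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            df = len(x) + len(y) - 2
            return 0.0, float(df), 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    res = sps.ttest_ind(x, y, equal_var=(variant == "student"))
    if variant == "student":
        df = len(x) + len(y) - 2
    else:
        df = float(res.df)
    return float(res.statistic), float(df), float(res.pvalue)
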