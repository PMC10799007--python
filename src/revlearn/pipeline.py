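"""End-to-end pipeline: synthesize → fit → compare → ERP → group statistics.

Every stage derives its randomness from one global seed through a
documented scheme (``numpy.random.SeedSequence([seed, *stage_key])``), so
stages can be re-run in isolation and two runs with the same configuration
are numerically identical.  All tabular outputs are CSV; a JSON manifest
records the configuration, per-stage seeds, and SHA-256 hashes of every
artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as _cohort
from .fit import FitConfig, compare_models, fit_hierarchical
from .hier import PriorSpec
from .stats import correlation, fisher_z_compare, mixed_anova_2x2, simple_effects

log = logging.getLogger("revlearn")

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGE_SEEDS = {"cohort": 10, "behavior": 11, "fit": 12, "epochs": 13}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2^31)."""
    ss = np.random.SeedSequence([int(seed), _STAGE_SEEDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    out_dir: str = "revlearn_run"
    seed: int = 0
    n_ot: int = 8
    n_plc: int = 8
    models: list[str] = field(default_factory=lambda: ["RP", "RW"])
    chains: int = 2
    warmup: int = 300
    draws: int = 300
    beta_max: float = 10.0
    erp_components: list[str] = field(default_factory=lambda: ["ERN", "FRN", "P300", "N2PC"])
    n_epochs_per_condition: int = 20
    null_effects: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        known = {"RP", "RW", "EWA"}
        bad = set(self.models) - known
        if bad:
            raise ValueError(f"unknown model tag(s): {sorted(bad)}; known: {sorted(known)}")
        from .erp import COMPONENTS

        bad_c = set(self.erp_components) - set(COMPONENTS)
        if bad_c:
            raise ValueError(f"unknown ERP component(s): {sorted(bad_c)}")

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return PipelineConfig(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis on a synthetic cohort; returns the report dir."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save_csv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False)
        artifacts[name] = _sha256(p)

    # -- stage 1: synthetic cohort + behavior ---------------------------
    log.info("stage synthesize: n=%d/%d", config.n_ot, config.n_plc)
    base = _cohort.null_config() if config.null_effects else _cohort.default_effect_config()
    spec = _cohort.CohortSpec(
        n_ot=config.n_ot,
        n_plc=config.n_plc,
        means=base.means,
        erp=_cohort.ErpSpec(n_per_condition=config.n_epochs_per_condition),
    )
    study = _cohort.draw_cohort(spec, seed=stage_seed(config.seed, "cohort"))
    behavior = _cohort.generate_behavior(study, seed=stage_seed(config.seed, "behavior"))
    save_csv(study.params, "true_parameters.csv")
    save_csv(study.anxiety, "anxiety.csv")
    save_csv(behavior, "behavior.csv")
    for (subject, context), sched in list(study.schedules.items())[:1]:
        sched.table.to_csv(out / "example_schedule.csv", index=False)
        artifacts["example_schedule.csv"] = _sha256(out / "example_schedule.csv")

    # -- stage 2: hierarchical fits per cell, LOOIC comparison ----------
    fits = []
    rhat_rows = []
    fit_seed0 = stage_seed(config.seed, "fit")
    for model in config.models:
        for i, (group, context) in enumerate(
            [(g, c) for g in ("OT", "PLC") for c in ("stable", "volatile")]
        ):
            cell_data = behavior[(behavior["group"] == group) & (behavior["context"] == context)]
            cfg = FitConfig(
                chains=config.chains,
                warmup=config.warmup,
                draws=config.draws,
                seed=(fit_seed0 + 1000 * config.models.index(model) + i) % (2**31),
                beta_max=config.beta_max,
            )
            log.info("stage fit: %s %s/%s", model, group, context)
            fit = fit_hierarchical(cell_data, model, PriorSpec(), cfg)
            fits.append(fit)
            rhat_rows.append(
                {
                    "model": model,
                    "group": group,
                    "context": context,
                    "max_rhat": fit.max_rhat(),
                    "max_rhat_group_level": fit.max_rhat(group_level_only=True),
                }
            )
    save_csv(pd.DataFrame(rhat_rows), "rhat.csv")
    comp = compare_models(fits)
    comp_out = comp.table.copy()
    comp_out.loc["winner"] = [comp.winners[str(c)] for c in comp_out.columns]
    comp_out.index.name = "model"
    p = out / "looic_comparison.csv"
    comp_out.to_csv(p)
    artifacts["looic_comparison.csv"] = _sha256(p)

    # -- stage 3: ERP scores -------------------------------------------
    log.info("stage erp: %s", config.erp_components)
    bundle = _cohort.generate_epochs(study, seed=stage_seed(config.seed, "epochs"))
    scores = bundle.score_table(components=config.erp_components)
    save_csv(scores, "erp_scores.csv")

    # -- stage 4: group statistics --------------------------------------
    log.info("stage stats")
    stat_rows = []
    acc = _cohort.accuracy_table(study)
    for label, long in [("accuracy", acc)] + [
        (p_, _cohort.parameter_table(study, p_)) for p_ in ("alpha_pos", "alpha_neg", "beta")
    ]:
        res = mixed_anova_2x2(long)
        for effect, row in res.table.iterrows():
            stat_rows.append({"measure": label, "effect": effect, **row.to_dict()})
        for ctx in ("stable", "volatile"):
            t, df, pv = simple_effects(long, ctx)
            stat_rows.append(
                {"measure": label, "effect": f"simple[{ctx}]", "F": t**2, "df1": 1, "df2": df, "p": pv}
            )
    save_csv(pd.DataFrame(stat_rows), "anova.csv")

    corr_rows = []
    merged = study.params.merge(study.anxiety, on=["subject", "group"])
    for ctx in ("stable", "volatile"):
        sub = merged[merged["context"] == ctx]
        r, pv = correlation(sub["anxiety"], sub["beta"], method="spearman")
        corr_rows.append({"pair": f"anxiety~beta[{ctx}]", "method": "spearman", "r": r, "p": pv})
    # treatment-wise correlation difference (both subtraction orders)
    acc_vol = acc[acc["context"] == "volatile"].merge(scores, on=["subject", "group"])
    if "N2PC" in acc_vol.columns:
        per = {}
        for g in ("OT", "PLC"):
            sub = acc_vol[acc_vol["group"] == g]
            per[g] = (correlation(sub["value"], sub["N2PC"], "spearman")[0], len(sub))
        z_ot_plc, p1 = fisher_z_compare(per["OT"][0], per["OT"][1], per["PLC"][0], per["PLC"][1])
        corr_rows.append({"pair": "acc~N2PC z(OT-PLC)", "method": "fisher_z", "r": z_ot_plc, "p": p1})
        corr_rows.append({"pair": "acc~N2PC z(PLC-OT)", "method": "fisher_z", "r": -z_ot_plc, "p": p1})
    save_csv(pd.DataFrame(corr_rows), "correlations.csv")

    # -- manifest -------------------------------------------------------
    manifest = {
        "config": {k: getattr(config, k) for k in vars(config)},
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_SEEDS},
        "study_hash": study.study_hash(),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("pipeline complete: %s", out)
    return out
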