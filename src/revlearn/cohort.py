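"""Synthetic study generator.

Builds a full two-group pharmacological study in silico: oxytocin (OT,
default n = 37) and placebo (PLC, n = 36) groups, each subject with
context-specific RP-model parameters, a unit-scaled trait-anxiety score
correlated (negatively, by default) with choice consistency, simulated
behavior on the stable (80-trial, 75/25) and volatile (100-trial, 80/20,
reversing every 20) schedules, and ERP epochs with injected ERN/FRN/P300/
N2pc components plus noise.

The default effect configuration encodes the group × context orderings the
analysis is designed to detect: learning rates higher under volatility in
both groups, the OT group's learning rates higher than placebo's in the
volatile context only (punishment learning rate lower under OT in the
stable context), and choice consistency (inverse temperature) higher in the
stable context, with an OT advantage there only.  Cell means on the native
scale are this package's own choices with moderate effect sizes; the
injected P300 (3.75 vs 5.57 µV) and N2pc (-0.29 vs 0.18 µV) group means are
the published group averages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .erp import COMPONENTS, EpochSet
from .models import RLParams, choice_accuracy, simulate_choices
from .task import TaskDesign, TrialSchedule, make_schedule, stable_design, volatile_design

__all__ = [
    "CohortSpec",
    "ErpSpec",
    "SyntheticStudy",
    "EpochBundle",
    "default_effect_config",
    "null_config",
    "draw_cohort",
    "generate_behavior",
    "generate_epochs",
    "accuracy_table",
    "parameter_table",
]

GROUPS = ("OT", "PLC")
CONTEXTS = ("stable", "volatile")


@dataclass(frozen=True)
class ErpSpec:
    """Injected-component configuration for synthetic epochs.

    Amplitude means/SDs are µV.  P300 and N2pc group means/SDs default to the
    published group averages; ERN and FRN use plausible difference-wave
    amplitudes (the study reports no group means for them).  Bump centers sit
    on the 250 Hz sample grid inside each component's analysis window.
    """

    p300_mean: dict = field(default_factory=lambda: {"OT": 3.75, "PLC": 5.57})
    p300_sd: dict = field(default_factory=lambda: {"OT": 2.59, "PLC": 3.31})
    n2pc_mean: dict = field(default_factory=lambda: {"OT": -0.29, "PLC": 0.18})
    n2pc_sd: dict = field(default_factory=lambda: {"OT": 0.59, "PLC": 0.70})
    ern_mean: dict = field(default_factory=lambda: {"OT": -3.0, "PLC": -4.0})
    ern_sd: dict = field(default_factory=lambda: {"OT": 1.5, "PLC": 1.5})
    frn_mean: dict = field(default_factory=lambda: {"OT": -2.5, "PLC": -3.5})
    frn_sd: dict = field(default_factory=lambda: {"OT": 1.5, "PLC": 1.5})
    noise_sd: float = 1.0
    noise_kind: str = "white"  # or "pink" (1/f)
    n_per_condition: int = 60
    sfreq: float = 250.0
    dc_offset_sd: float = 2.0  # removed by baseline correction
    artifact_fraction: float = 0.0
    artifact_uv: float = 120.0

    # bump centers (ms) and widths (ms); centers on the sample grid
    centers: dict = field(
        default_factory=lambda: {"ERN": 28.0, "FRN": 300.0, "P300": 448.0, "N2PC": 224.0}
    )
    widths: dict = field(
        default_factory=lambda: {"ERN": 12.0, "FRN": 25.0, "P300": 60.0, "N2PC": 14.0}
    )


#: native-scale per-cell means of the default effect configuration
_DEFAULT_MEANS: dict[tuple[str, str], dict[str, float]] = {
    ("OT", "stable"): {"alpha_pos": 0.30, "alpha_neg": 0.20, "beta": 5.5},
    ("PLC", "stable"): {"alpha_pos": 0.30, "alpha_neg": 0.30, "beta": 4.0},
    ("OT", "volatile"): {"alpha_pos": 0.75, "alpha_neg": 0.65, "beta": 2.5},
    ("PLC", "volatile"): {"alpha_pos": 0.60, "alpha_neg": 0.50, "beta": 2.5},
}

_NULL_MEANS: dict[str, float] = {"alpha_pos": 0.45, "alpha_neg": 0.35, "beta": 3.5}


@dataclass(frozen=True)
class CohortSpec:
    """Group-level generative configuration of a synthetic study."""

    n_ot: int = 37
    n_plc: int = 36
    means: dict = field(default_factory=lambda: {f"{g}/{c}": dict(m) for (g, c), m in _DEFAULT_MEANS.items()})
    sds: dict = field(default_factory=lambda: {"alpha_pos": 0.15, "alpha_neg": 0.15, "beta": 1.0})
    anxiety_beta_corr: float = -0.27
    beta_max: float = 10.0
    erp: ErpSpec = field(default_factory=ErpSpec)

    def __post_init__(self) -> None:
        if self.n_ot < 2 or self.n_plc < 2:
            raise ValueError("group sizes must be >= 2")
        if not (-1.0 < self.anxiety_beta_corr < 1.0):
            raise ValueError("anxiety_beta_corr must lie in (-1, 1)")
        if any(s < 0 for s in self.sds.values()):
            raise ValueError("parameter scales must be >= 0")

    def cell_mean(self, group: str, context: str) -> dict[str, float]:
        return self.means[f"{group}/{context}"]

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @staticmethod
    def from_dict(d: dict) -> "CohortSpec":
        d = dict(d)
        if "erp" in d and isinstance(d["erp"], dict):
            d["erp"] = ErpSpec(**d["erp"])
        return CohortSpec(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @staticmethod
    def from_json(path: str | Path) -> "CohortSpec":
        return CohortSpec.from_dict(json.loads(Path(path).read_text()))


def default_effect_config() -> CohortSpec:
    """The study-structured effect configuration (see module docstring)."""
    return CohortSpec()


def null_config() -> CohortSpec:
    """Zero-effect variant: every group × context cell shares the same means."""
    return CohortSpec(means={f"{g}/{c}": dict(_NULL_MEANS) for g in GROUPS for c in CONTEXTS})


@dataclass
class SyntheticStudy:
    """A drawn synthetic cohort: true parameters, anxiety, behavior, epochs."""

    spec: CohortSpec
    seed: int
    params: pd.DataFrame  # subject, group, context, alpha_pos, alpha_neg, beta
    anxiety: pd.DataFrame  # subject, group, anxiety
    behavior: pd.DataFrame | None = None
    schedules: dict = field(default_factory=dict)  # (subject, context) -> TrialSchedule
    epochs: "EpochBundle | None" = None

    @property
    def subjects(self) -> pd.DataFrame:
        return self.anxiety[["subject", "group"]]

    def study_hash(self) -> str:
        h = hashlib.sha256()
        h.update(json.dumps(self.spec.to_dict(), sort_keys=True).encode())
        h.update(str(self.seed).encode())
        h.update(self.params.round(12).to_csv(index=False).encode())
        if self.behavior is not None:
            h.update(self.behavior.to_csv(index=False).encode())
        return h.hexdigest()[:16]


def _child_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ValueError(
        f"truncated-normal rejection failed: mean={mean}, sd={sd}, bounds=({lo}, {hi})"
    )


def draw_cohort(spec: CohortSpec, seed: int = 0) -> SyntheticStudy:
    """Draw subject-level true parameters and trait-anxiety scores.

    Parameters come from per-cell normals truncated to the native ranges.
    The inverse temperature is drawn jointly with a latent anxiety trait via
    a Gaussian copula so that corr(anxiety, beta) ≈ ``anxiety_beta_corr`` in
    each context; anxiety itself is unit-scaled (z-scores).
    """
    rng = np.random.default_rng(_child_seed(seed, 1))
    r = spec.anxiety_beta_corr
    rows = []
    anx_rows = []
    subj_id = 0
    for group, n in (("OT", spec.n_ot), ("PLC", spec.n_plc)):
        for _ in range(n):
            sid = f"{group.lower()}{subj_id:03d}"
            subj_id += 1
            a = rng.standard_normal()
            anx_rows.append({"subject": sid, "group": group, "anxiety": a})
            for context in CONTEXTS:
                m = spec.cell_mean(group, context)
                ap = _trunc_normal(rng, m["alpha_pos"], spec.sds["alpha_pos"], 0.0, 1.0)
                an = _trunc_normal(rng, m["alpha_neg"], spec.sds["alpha_neg"], 0.0, 1.0)
                sd_b = spec.sds["beta"]
                if sd_b == 0:
                    be = float(np.clip(m["beta"], 0.0, spec.beta_max))
                else:
                    be = None
                    for _ in range(1000):
                        g = r * a + np.sqrt(1.0 - r * r) * rng.standard_normal()
                        cand = m["beta"] + sd_b * g
                        if 0.0 <= cand <= spec.beta_max:
                            be = float(cand)
                            break
                    if be is None:
                        raise ValueError("beta draw failed; check means/scales vs beta_max")
                rows.append(
                    {
                        "subject": sid,
                        "group": group,
                        "context": context,
                        "alpha_pos": ap,
                        "alpha_neg": an,
                        "beta": be,
                    }
                )
    return SyntheticStudy(
        spec=spec,
        seed=seed,
        params=pd.DataFrame(rows),
        anxiety=pd.DataFrame(anx_rows),
    )


def generate_behavior(
    study: SyntheticStudy,
    designs: dict[str, TaskDesign] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate every subject's choices in both contexts (fresh schedules).

    Each subject × context gets an independent schedule realization and an
    independent choice stream, both derived deterministically from the seed.
    The result (also stored on ``study.behavior``) has one row per trial.
    """
    if designs is None:
        designs = {"stable": stable_design(), "volatile": volatile_design()}
    seed = study.seed if seed is None else seed
    tables = []
    for i, row in study.params.iterrows():
        context = row["context"]
        ctx_idx = CONTEXTS.index(context)
        sched = make_schedule(designs[context], seed=_child_seed(seed, 2, i, ctx_idx))
        params = RLParams(row["alpha_pos"], row["alpha_neg"], row["beta"])
        tt = simulate_choices(
            sched,
            params,
            "RP",
            seed=_child_seed(seed, 3, i, ctx_idx),
            subject=row["subject"],
            group=row["group"],
            context=context,
        )
        study.schedules[(row["subject"], context)] = sched
        tables.append(tt)
    behavior = pd.concat(tables, ignore_index=True)
    study.behavior = behavior
    return behavior


def accuracy_table(study: SyntheticStudy) -> pd.DataFrame:
    """Per subject × context optimal-choice accuracy (long format for ANOVA)."""
    if study.behavior is None:
        raise ValueError("run generate_behavior first")
    rows = []
    for (subject, context), grp in study.behavior.groupby(["subject", "context"]):
        sched = study.schedules[(subject, context)]
        rows.append(
            {
                "subject": subject,
                "group": grp["group"].iloc[0],
                "context": context,
                "value": choice_accuracy(grp, sched),
            }
        )
    return pd.DataFrame(rows).sort_values(["subject", "context"]).reset_index(drop=True)


def parameter_table(study: SyntheticStudy, param: str) -> pd.DataFrame:
    """True-parameter long table (subject, group, context, value) for ANOVA."""
    df = study.params[["subject", "group", "context", param]].rename(columns={param: "value"})
    return df.reset_index(drop=True)


class EpochBundle:
    """Lazily materialized synthetic ERP epochs for every subject.

    Per-subject component amplitudes are drawn eagerly (they are small);
    the epoch arrays themselves are rebuilt deterministically on demand so a
    73-subject, four-component bundle never sits in memory at once.
    """

    def __init__(self, study: SyntheticStudy, erp: ErpSpec, seed: int):
        self.erp = erp
        self.seed = seed
        rng = np.random.default_rng(_child_seed(seed, 4))
        rows = []
        for _, subj in study.anxiety.iterrows():
            g = subj["group"]
            rows.append(
                {
                    "subject": subj["subject"],
                    "group": g,
                    "ERN": rng.normal(erp.ern_mean[g], erp.ern_sd[g]),
                    "FRN": rng.normal(erp.frn_mean[g], erp.frn_sd[g]),
                    "P300": rng.normal(erp.p300_mean[g], erp.p300_sd[g]),
                    "N2PC": rng.normal(erp.n2pc_mean[g], erp.n2pc_sd[g]),
                }
            )
        self.amplitudes = pd.DataFrame(rows)
        self._index = {r["subject"]: i for i, r in self.amplitudes.iterrows()}

    def subjects(self) -> list[str]:
        return list(self.amplitudes["subject"])

    def epochs(self, subject: str, component: str) -> EpochSet:
        """Build the epoch set for one subject and component."""
        if component not in COMPONENTS:
            raise KeyError(f"unknown component {component!r}")
        i = self._index[subject]
        amp = float(self.amplitudes.loc[i, component])
        rng = np.random.default_rng(
            _child_seed(self.seed, 5, i, list(COMPONENTS).index(component))
        )
        return _build_epochs(component, amp, self.erp, rng)

    def score_table(self, components: list[str] | None = None, threshold: float = 80.0) -> pd.DataFrame:
        """Extract all component scores through :mod:`revlearn.erp`."""
        from .erp import component_score

        components = components or list(COMPONENTS)
        rows = []
        for _, r in self.amplitudes.iterrows():
            entry = {"subject": r["subject"], "group": r["group"]}
            for comp in components:
                es = self.epochs(r["subject"], comp)
                entry[comp] = component_score(es, COMPONENTS[comp], threshold=threshold)
            rows.append(entry)
        return pd.DataFrame(rows)


_EPOCH_SPANS = {  # lock, tmin (s), tmax (s)
    "ERN": ("response", -0.8, 0.5),
    "FRN": ("feedback", -0.2, 1.0),
    "P300": ("stimulus", -0.2, 1.0),
    "N2PC": ("stimulus", -0.1, 0.4),
}

_CHANNELS = ["FCz", "Pz", "PO7", "PO8"]


def _gauss_bump(times_ms: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((times_ms - center) / width) ** 2)


def _noise(rng: np.random.Generator, erp: ErpSpec, shape: tuple[int, ...]) -> np.ndarray:
    if erp.noise_sd == 0:
        return np.zeros(shape)
    if erp.noise_kind == "white":
        return rng.normal(0.0, erp.noise_sd, shape)
    if erp.noise_kind == "pink":
        white = rng.normal(0.0, 1.0, shape)
        f = np.fft.rfftfreq(shape[-1], d=1.0)
        scale = np.where(f > 0, 1.0 / np.sqrt(f), 0.0)
        pink = np.fft.irfft(np.fft.rfft(white, axis=-1) * scale, n=shape[-1], axis=-1)
        sd = pink.std()
        return pink / (sd if sd > 0 else 1.0) * erp.noise_sd
    raise ValueError(f"unknown noise kind {erp.noise_kind!r}")


def _build_epochs(component: str, amp: float, erp: ErpSpec, rng: np.random.Generator) -> EpochSet:
    lock, tmin, tmax = _EPOCH_SPANS[component]
    n_samples = int(round((tmax - tmin) * erp.sfreq)) + 1
    times_ms = (tmin + np.arange(n_samples) / erp.sfreq) * 1000.0
    n = erp.n_per_condition
    bump = _gauss_bump(times_ms, erp.centers[component], erp.widths[component])

    if component == "P300":
        n_epochs = n
        labels = pd.DataFrame({"correctness": ["correct"] * n})
    elif component == "ERN":
        n_epochs = 2 * n
        labels = pd.DataFrame({"correctness": ["incorrect"] * n + ["correct"] * n})
    elif component == "FRN":
        n_epochs = 2 * n
        labels = pd.DataFrame({"valence": ["negative"] * n + ["positive"] * n})
    else:  # N2PC
        n_epochs = 2 * n
        labels = pd.DataFrame(
            {"correctness": ["correct"] * 2 * n, "target_side": ["left"] * n + ["right"] * n}
        )

    data = _noise(rng, erp, (n_epochs, len(_CHANNELS), n_samples))
    if erp.dc_offset_sd > 0:
        data += rng.normal(0.0, erp.dc_offset_sd, (n_epochs, len(_CHANNELS), 1))

    fcz, pz, po7, po8 = (_CHANNELS.index(c) for c in ("FCz", "Pz", "PO7", "PO8"))
    if component == "P300":
        data[:, pz, :] += amp * bump
    elif component == "ERN":
        data[:n, fcz, :] += amp * bump  # incorrect trials only
    elif component == "FRN":
        data[:n, fcz, :] += amp * bump  # negative feedback only
    else:  # N2pc: contralateral electrode gets the component
        data[:n, po8, :] += amp * bump  # left targets -> right-sided electrode
        data[n:, po7, :] += amp * bump  # right targets -> left-sided electrode

    if erp.artifact_fraction > 0:
        n_bad = int(round(erp.artifact_fraction * n_epochs))
        bad = rng.choice(n_epochs, size=n_bad, replace=False)
        for b in bad:
            t0 = rng.integers(0, n_samples - 5)
            data[b, rng.integers(0, len(_CHANNELS)), t0 : t0 + 5] += erp.artifact_uv

    return EpochSet(
        data=data,
        sfreq=erp.sfreq,
        tmin=tmin,
        ch_names=list(_CHANNELS),
        labels=labels,
        lock=lock,
    )


def generate_epochs(study: SyntheticStudy, erp: ErpSpec | None = None, seed: int | None = None) -> EpochBundle:
    """Attach a lazily-built ERP epoch bundle to the study."""
    bundle = EpochBundle(study, erp or study.spec.erp, study.seed if seed is None else seed)
    study.epochs = bundle
    return bundle
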