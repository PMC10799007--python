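"""ERP component extraction: ERN, FRN, P300, and N2pc.

Epochs are microvolt arrays of shape (epochs, channels, samples) with
per-epoch condition labels.  Component measures follow the conventional
recipe: baseline-correct, discard epochs exceeding an absolute-voltage
threshold, average per condition within subject, then take the signed peak
(windowed extremum of the component's polarity), on a difference wave where
the component is defined as a contrast:

========  ========== =============== ============ ========= ====================
name      lock       epoch (ms)      baseline     window    measure
========  ========== =============== ============ ========= ====================
ERN       response   -800..500       -800..-700   0..60     min of incorrect-correct @ FCz
FRN       feedback   -200..1000      -200..0      252..352  min of negative-positive @ FCz
P300      stimulus   -200..1000      -200..0      300..600  max of correct average @ Pz
N2pc      stimulus   -100..400       -100..0      200..252  min of contra-ipsi @ PO7/PO8
========  ========== =============== ============ ========= ====================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "EpochSet",
    "ComponentSpec",
    "COMPONENTS",
    "baseline_correct",
    "reject_artifacts",
    "condition_average",
    "peak_measure",
    "component_score",
    "n2pc_score",
    "N2pcResult",
]

Polarity = Literal["negative", "positive"]


@dataclass
class EpochSet:
    """Epoched EEG with condition labels.

    ``data`` is (n_epochs, n_channels, n_samples) in microvolts; ``tmin`` is
    the time of the first sample in seconds relative to the lock event.
    ``labels`` carries one row per epoch (e.g. columns ``correctness``,
    ``valence``, ``target_side``).
    """

    data: np.ndarray
    sfreq: float
    tmin: float
    ch_names: list[str]
    labels: pd.DataFrame = field(default_factory=pd.DataFrame)
    lock: str = "stimulus"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel count does not match ch_names")
        if len(self.labels) == 0:
            self.labels = pd.DataFrame(index=range(self.data.shape[0]))
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels must have one row per epoch")
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        return (self.tmin + np.arange(n) / self.sfreq) * 1000.0

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present (have {self.ch_names})") from None

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return replace(
            self, data=self.data[mask], labels=self.labels.loc[mask].reset_index(drop=True)
        )

    def _window_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        lo, hi = window_ms
        t = self.times_ms
        if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
            raise ValueError(
                f"window {window_ms} ms outside epoch span [{t[0]:.1f}, {t[-1]:.1f}] ms"
            )
        return (t >= lo - 1e-9) & (t <= hi + 1e-9)

    # -- long-format text I/O -------------------------------------------
    def to_long_frame(self) -> pd.DataFrame:
        n_e, n_c, n_s = self.data.shape
        idx = pd.MultiIndex.from_product(
            [range(n_e), self.ch_names, np.round(self.times_ms, 6)],
            names=["epoch", "channel", "time_ms"],
        )
        df = pd.DataFrame({"uv": self.data.ravel()}, index=idx).reset_index()
        return df.merge(
            self.labels.reset_index(names="epoch"), on="epoch", how="left"
        )

    @staticmethod
    def from_long_frame(df: pd.DataFrame, sfreq: float, lock: str = "stimulus") -> "EpochSet":
        required = {"epoch", "channel", "time_ms", "uv"}
        if not required <= set(df.columns):
            raise ValueError(f"long-format epochs need columns {sorted(required)}")
        ch_names = list(pd.unique(df["channel"]))
        epochs = np.sort(df["epoch"].unique())
        times = np.sort(df["time_ms"].unique())
        wide = df.pivot_table(index=["epoch", "channel"], columns="time_ms", values="uv")
        data = np.stack(
            [wide.loc[(e, slice(None))].loc[ch_names].to_numpy() for e in epochs]
        )
        label_cols = [c for c in df.columns if c not in required]
        labels = df.drop_duplicates("epoch").set_index("epoch").loc[epochs, label_cols]
        return EpochSet(
            data=data,
            sfreq=sfreq,
            tmin=times[0] / 1000.0,
            ch_names=ch_names,
            labels=labels.reset_index(drop=True),
            lock=lock,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ComponentSpec:
    name: str
    channels: tuple[str, ...]
    baseline: tuple[float, float]  # ms
    window: tuple[float, float]  # ms
    polarity: Polarity
    contrast: Literal["incorrect-correct", "negative-positive", "none", "contra-ipsi"]
    lock: str = "stimulus"


COMPONENTS: dict[str, ComponentSpec] = {
    "ERN": ComponentSpec(
        "ERN", ("FCz",), (-800.0, -700.0), (0.0, 60.0), "negative", "incorrect-correct", "response"
    ),
    "FRN": ComponentSpec(
        "FRN", ("FCz",), (-200.0, 0.0), (252.0, 352.0), "negative", "negative-positive", "feedback"
    ),
    "P300": ComponentSpec(
        "P300", ("Pz",), (-200.0, 0.0), (300.0, 600.0), "positive", "none", "stimulus"
    ),
    "N2PC": ComponentSpec(
        "N2PC", ("PO7", "PO8"), (-100.0, 0.0), (200.0, 252.0), "negative", "contra-ipsi", "stimulus"
    ),
}


def baseline_correct(epochs: EpochSet, window: tuple[float, float]) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over ``window`` (ms)."""
    mask = epochs._window_mask(window)
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base)


def reject_artifacts(
    epochs: EpochSet,
    threshold: float = 80.0,
    channels: list[str] | None = None,
) -> tuple[EpochSet, float]:
    """Drop epochs whose absolute voltage strictly exceeds ``threshold`` µV.

    Only ``channels`` are screened when given (the analyzed electrodes);
    boundary values exactly at the threshold are retained.  Returns the kept
    epochs and the rejected fraction; raises if nothing survives.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    data = epochs.data
    if channels is not None:
        idx = [epochs.channel_index(c) for c in channels]
        data = data[:, idx, :]
    bad = (np.abs(data) > threshold).any(axis=(1, 2))
    frac = float(bad.mean()) if len(bad) else 0.0
    if bad.all():
        raise ValueError("all epochs exceeded the artifact threshold")
    return epochs.select(~bad), frac


def condition_average(
    epochs: EpochSet, column: str | None = None, value: str | None = None
) -> np.ndarray:
    """Pointwise mean waveform (channels, samples) over epochs in a condition."""
    if column is None:
        sel = epochs
    else:
        if column not in epochs.labels.columns:
            raise ValueError(f"no label column {column!r}")
        sel = epochs.select((epochs.labels[column] == value).to_numpy())
    if sel.n_epochs == 0:
        raise ValueError(f"no epochs with {column} == {value!r}")
    return sel.data.mean(axis=0)


def peak_measure(
    waveform: np.ndarray,
    times_ms: np.ndarray,
    window: tuple[float, float],
    polarity: Polarity,
) -> tuple[float, float]:
    """Signed windowed extremum of a 1-D waveform and its latency (ms).

    ``negative`` takes the minimum, ``positive`` the maximum; ties break to
    the earliest latency (argmin/argmax convention).
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1:
        raise ValueError("peak_measure expects a single-channel waveform")
    lo, hi = window
    if lo < times_ms[0] - 1e-9 or hi > times_ms[-1] + 1e-9:
        raise ValueError(f"window {window} ms outside waveform span")
    mask = (times_ms >= lo - 1e-9) & (times_ms <= hi + 1e-9)
    seg = waveform[mask]
    seg_t = times_ms[mask]
    i = int(np.argmin(seg)) if polarity == "negative" else int(np.argmax(seg))
    return float(seg[i]), float(seg_t[i])


@dataclass
class N2pcResult:
    contra: np.ndarray
    ipsi: np.ndarray
    times_ms: np.ndarray
    score: float
    latency_ms: float


def n2pc_score(
    epochs: EpochSet,
    window: tuple[float, float] = (200.0, 252.0),
    baseline: tuple[float, float] | None = (-100.0, 0.0),
    threshold: float | None = 80.0,
) -> N2pcResult:
    """Contralateral-minus-ipsilateral negativity at PO7/PO8.

    ipsi = mean(PO7 | left targets, PO8 | right targets);
    contra = mean(PO7 | right targets, PO8 | left targets);
    score = negative peak of (contra - ipsi) in ``window``.
    """
    for ch in ("PO7", "PO8"):
        epochs.channel_index(ch)
    if "target_side" not in epochs.labels.columns:
        raise ValueError("n2pc requires a 'target_side' label column")
    if baseline is not None:
        epochs = baseline_correct(epochs, baseline)
    if threshold is not None:
        epochs, _ = reject_artifacts(epochs, threshold, channels=["PO7", "PO8"])
    sides = set(epochs.labels["target_side"])
    if not {"left", "right"} <= sides:
        raise ValueError(f"both target sides required, got {sorted(sides)}")
    po7 = epochs.channel_index("PO7")
    po8 = epochs.channel_index("PO8")
    left = condition_average(epochs, "target_side", "left")
    right = condition_average(epochs, "target_side", "right")
    ipsi = 0.5 * (left[po7] + right[po8])
    contra = 0.5 * (right[po7] + left[po8])
    score, lat = peak_measure(contra - ipsi, epochs.times_ms, window, "negative")
    return N2pcResult(
        contra=contra, ipsi=ipsi, times_ms=epochs.times_ms, score=score, latency_ms=lat
    )


def component_score(
    epochs: EpochSet,
    spec: ComponentSpec,
    threshold: float | None = 80.0,
    mode: Literal["difference_wave", "peak_difference"] = "difference_wave",
) -> float:
    """Subject-level component amplitude (µV) per the component's recipe.

    ``difference_wave`` (default) takes the peak of the difference of
    condition averages; ``peak_difference`` takes the difference of the two
    conditions' peaks.
    """
    if spec.contrast == "contra-ipsi":
        return n2pc_score(
            epochs, window=spec.window, baseline=spec.baseline, threshold=threshold
        ).score

    epochs = baseline_correct(epochs, spec.baseline)
    if threshold is not None:
        epochs, _ = reject_artifacts(epochs, threshold, channels=list(spec.channels))
    ch = epochs.channel_index(spec.channels[0])
    t = epochs.times_ms

    if spec.contrast == "none":
        if "correctness" in epochs.labels.columns:
            avg = condition_average(epochs, "correctness", "correct")
        else:
            avg = condition_average(epochs)
        return peak_measure(avg[ch], t, spec.window, spec.polarity)[0]

    if spec.contrast == "incorrect-correct":
        column, pos_lab, neg_lab = "correctness", "incorrect", "correct"
    elif spec.contrast == "negative-positive":
        column, pos_lab, neg_lab = "valence", "negative", "positive"
    else:  # pragma: no cover - exhaustive
        raise ValueError(f"unknown contrast {spec.contrast!r}")
    a = condition_average(epochs, column, pos_lab)[ch]
    b = condition_average(epochs, column, neg_lab)[ch]
    if mode == "difference_wave":
        return peak_measure(a - b, t, spec.window, spec.polarity)[0]
    pa = peak_measure(a, t, spec.window, spec.polarity)[0]
    pb = peak_measure(b, t, spec.window, spec.polarity)[0]
    return pa - pb
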