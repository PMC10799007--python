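"""ERP extraction: baselining, rejection, averaging, peak measures."""

import numpy as np
import pandas as pd
import pytest

import revlearn as rl
from revlearn.erp import COMPONENTS, EpochSet, N2pcResult

CH = ["FCz", "Pz", "PO7", "PO8"]


def make_epochs(data, labels=None, tmin=-0.2, sfreq=250.0, lock="stimulus"):
    return EpochSet(
        data=np.asarray(data, dtype=float), sfreq=sfreq, tmin=tmin,
        ch_names=CH, labels=labels if labels is not None else pd.DataFrame(),
        lock=lock,
    )


def bump(times_ms, center, width, amp):
    return amp * np.exp(-0.5 * ((times_ms - center) / width) ** 2)


@pytest.fixture
def times_300():
    # -200..992 ms at 250 Hz
    return (-0.2 + np.arange(300) / 250.0) * 1000.0


class TestBaselineCorrect:
    def test_constant_epoch_becomes_zero(self):
        es = make_epochs(np.full((3, 4, 300), 7.0))
        out = rl.baseline_correct(es, (-200, 0))
        assert np.allclose(out.data, 0.0)

    def test_zero_mean_baseline_unchanged(self, times_300):
        sig = bump(times_300, 400, 50, 5.0)
        es = make_epochs(np.tile(sig, (2, 4, 1)))
        out = rl.baseline_correct(es, (-200, 0))
        assert np.allclose(out.data, es.data, atol=1e-6)

    def test_offset_removed_bump_preserved(self, times_300):
        sig = 3.0 + bump(times_300, 400, 50, 5.0)
        es = make_epochs(sig[None, None, :].repeat(4, axis=1))
        out = rl.baseline_correct(es, (-200, 0))
        expected = bump(times_300, 400, 50, 5.0)
        assert np.allclose(out.data[0, 0], expected, atol=1e-6)

    def test_window_outside_span_rejected(self):
        es = make_epochs(np.zeros((1, 4, 300)))
        with pytest.raises(ValueError, match="outside"):
            rl.baseline_correct(es, (-900, -800))

    def test_commutes_with_averaging(self):
        rng = np.random.default_rng(0)
        es = make_epochs(rng.normal(0, 5, (20, 4, 300)))
        avg_then = rl.baseline_correct(
            make_epochs(es.data.mean(axis=0, keepdims=True)), (-200, 0)
        ).data[0]
        then_avg = rl.baseline_correct(es, (-200, 0)).data.mean(axis=0)
        assert np.allclose(avg_then, then_avg, atol=1e-10)


class TestRejectArtifacts:
    def test_excursions_removed_and_fraction_reported(self):
        data = np.zeros((10, 4, 300))
        data[3, 0, 50] = 100.0
        data[7, 2, 10] = -100.0
        kept, frac = rl.reject_artifacts(make_epochs(data), 80.0)
        assert kept.n_epochs == 8
        assert frac == pytest.approx(0.2)

    def test_infinite_threshold_keeps_all(self):
        data = np.full((5, 4, 300), 500.0)
        kept, frac = rl.reject_artifacts(make_epochs(data), np.inf)
        assert kept.n_epochs == 5 and frac == 0.0

    def test_boundary_value_retained(self):
        data = np.zeros((2, 4, 300))
        data[0, 0, 0] = 80.0
        kept, frac = rl.reject_artifacts(make_epochs(data), 80.0)
        assert kept.n_epochs == 2

    def test_channel_restriction(self):
        data = np.zeros((2, 4, 300))
        data[0, CH.index("PO7"), 5] = 200.0
        kept, _ = rl.reject_artifacts(make_epochs(data), 80.0, channels=["FCz"])
        assert kept.n_epochs == 2

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 20, (20, 4, 300))
        once, f1 = rl.reject_artifacts(make_epochs(data), 80.0)
        twice, f2 = rl.reject_artifacts(once, 80.0)
        assert twice.n_epochs == once.n_epochs and f2 == 0.0

    def test_all_rejected_raises(self):
        data = np.full((3, 4, 300), 200.0)
        with pytest.raises(ValueError, match="all epochs"):
            rl.reject_artifacts(make_epochs(data), 80.0)


class TestConditionAverage:
    def test_single_epoch_is_itself(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(1, 4, 300))
        assert np.allclose(rl.condition_average(make_epochs(data)), data[0])

    def test_opposite_epochs_cancel(self):
        x = np.random.default_rng(3).normal(size=(4, 300))
        es = make_epochs(np.stack([x, -x]))
        assert np.allclose(rl.condition_average(es), 0.0, atol=1e-12)

    def test_noise_shrinks_with_sqrt_n(self, times_300):
        rng = np.random.default_rng(4)
        template = bump(times_300, 400, 50, 5.0)
        data = template + rng.normal(0, 1.0, (50, 4, 300))
        avg = rl.condition_average(make_epochs(data))
        rms = np.sqrt(np.mean((avg - template) ** 2))
        assert rms < 4 * 1.0 / np.sqrt(50)

    def test_empty_selection_rejected(self):
        es = make_epochs(np.zeros((2, 4, 300)), pd.DataFrame({"correctness": ["correct"] * 2}))
        with pytest.raises(ValueError, match="no epochs"):
            rl.condition_average(es, "correctness", "incorrect")


class TestPeakMeasure:
    def test_flat_waveform_gives_zero(self, times_300):
        amp, _ = rl.peak_measure(np.zeros(300), times_300, (300, 600), "positive")
        assert amp == 0.0

    def test_bump_peak_and_latency(self, times_300):
        wave = bump(times_300, 400, 50, 5.0)
        amp, lat = rl.peak_measure(wave, times_300, (300, 600), "positive")
        assert amp == pytest.approx(5.0, abs=1e-9)
        assert lat == pytest.approx(400.0, abs=2.1)

    def test_window_excluding_peak_gives_edge_value(self, times_300):
        wave = bump(times_300, 400, 50, 5.0)
        amp, _ = rl.peak_measure(wave, times_300, (500, 600), "positive")
        assert amp < 5.0

    def test_negative_polarity_takes_minimum(self, times_300):
        wave = bump(times_300, 400, 50, -3.0)
        amp, _ = rl.peak_measure(wave, times_300, (300, 600), "negative")
        assert amp == pytest.approx(-3.0, abs=1e-9)


class TestComponentScore:
    def test_identical_conditions_score_zero(self, times_300):
        data = np.tile(bump(times_300, 30, 12, -2.0), (10, 4, 1))
        labels = pd.DataFrame({"correctness": ["incorrect"] * 5 + ["correct"] * 5})
        es = make_epochs(data, labels, tmin=-0.8, lock="response")
        spec = COMPONENTS["ERN"]
        assert rl.component_score(es, spec) == pytest.approx(0.0, abs=1e-9)

    def test_ern_noiseless_recovery(self):
        t = (-0.8 + np.arange(326) / 250.0) * 1000.0
        data = np.zeros((10, 4, 326))
        data[:5, 0, :] = bump(t, 28, 12, -4.0)  # incorrect trials at FCz
        labels = pd.DataFrame({"correctness": ["incorrect"] * 5 + ["correct"] * 5})
        es = make_epochs(data, labels, tmin=-0.8, lock="response")
        assert rl.component_score(es, COMPONENTS["ERN"]) == pytest.approx(-4.0, abs=1e-9)

    def test_p300_noiseless_recovery_at_printed_amplitude(self, times_300):
        data = np.zeros((6, 4, 300))
        data[:, 1, :] = bump(times_300, 448, 60, 5.57)  # Pz
        labels = pd.DataFrame({"correctness": ["correct"] * 6})
        es = make_epochs(data, labels)
        assert rl.component_score(es, COMPONENTS["P300"]) == pytest.approx(5.57, abs=1e-9)

    def test_peak_difference_mode_differs_in_general(self, times_300):
        rng = np.random.default_rng(5)
        data = rng.normal(0, 1, (20, 4, 300))
        data[:10, 0, :] += bump(times_300, 300, 25, -3.0)
        labels = pd.DataFrame({"valence": ["negative"] * 10 + ["positive"] * 10})
        es = make_epochs(data, labels, lock="feedback")
        a = rl.component_score(es, COMPONENTS["FRN"], mode="difference_wave")
        b = rl.component_score(es, COMPONENTS["FRN"], mode="peak_difference")
        assert a != b

    def test_missing_condition_rejected(self, times_300):
        data = np.zeros((4, 4, 300))
        labels = pd.DataFrame({"valence": ["negative"] * 4})
        es = make_epochs(data, labels, lock="feedback")
        with pytest.raises(ValueError, match="no epochs"):
            rl.component_score(es, COMPONENTS["FRN"])


class TestN2pc:
    def t_n2pc(self):
        return (-0.1 + np.arange(126) / 250.0) * 1000.0

    def labels(self, n=10):
        return pd.DataFrame({"target_side": ["left"] * (n // 2) + ["right"] * (n // 2)})

    def test_symmetric_channels_score_zero(self):
        rng = np.random.default_rng(6)
        data = np.zeros((10, 4, 126))
        sig = rng.normal(0, 1, (10, 126))
        data[:, 2, :] = sig  # PO7
        data[:, 3, :] = sig  # PO8 identical
        es = make_epochs(data, self.labels(), tmin=-0.1)
        res = rl.n2pc_score(es)
        assert res.score == pytest.approx(0.0, abs=1e-9)

    def test_contralateral_bump_recovered(self):
        t = self.t_n2pc()
        data = np.zeros((10, 4, 126))
        sig = bump(t, 224, 14, -2.0)
        data[:5, 3, :] = sig  # left targets -> PO8 (contra)
        data[5:, 2, :] = sig  # right targets -> PO7 (contra)
        es = make_epochs(data, self.labels(), tmin=-0.1)
        res = rl.n2pc_score(es)
        assert isinstance(res, N2pcResult)
        assert res.score == pytest.approx(-2.0, abs=1e-9)

    def test_label_swap_mirrors_waveforms(self):
        rng = np.random.default_rng(7)
        data = rng.normal(0, 1, (10, 4, 126))
        es = make_epochs(data, self.labels(), tmin=-0.1)
        res = rl.n2pc_score(es)
        swapped = self.labels()
        swapped["target_side"] = swapped["target_side"].map({"left": "right", "right": "left"})
        es2 = make_epochs(data, swapped, tmin=-0.1)
        res2 = rl.n2pc_score(es2)
        assert np.allclose(res.contra, res2.ipsi, atol=1e-12)
        assert np.allclose(res.ipsi, res2.contra, atol=1e-12)

    def test_one_sided_targets_rejected(self):
        data = np.zeros((4, 4, 126))
        labels = pd.DataFrame({"target_side": ["left"] * 4})
        with pytest.raises(ValueError, match="both target sides"):
            rl.n2pc_score(make_epochs(data, labels, tmin=-0.1))


def test_long_frame_round_trip():
    rng = np.random.default_rng(8)
    data = rng.normal(size=(4, 4, 50))
    labels = pd.DataFrame({"correctness": ["correct", "incorrect"] * 2})
    es = make_epochs(data, labels, tmin=-0.1)
    back = EpochSet.from_long_frame(es.to_long_frame(), sfreq=250.0)
    assert np.allclose(np.sort(back.data.ravel()), np.sort(es.data.ravel()), atol=1e-9)
    assert back.data.shape == es.data.shape
    assert set(back.labels["correctness"]) == {"correct", "incorrect"}
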