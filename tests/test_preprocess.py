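"""Preprocessing contracts: filter responses, ICA removal, epoching, SNR."""

import numpy as np
import pytest

from eegharx import SimulationConfig, generate_recording
from eegharx.preprocess import (
    EpochSet,
    FilterSpec,
    apply_filter,
    bandpass_spec,
    estimate_snr_and_reject,
    notch_spec,
    preprocess_recording,
    remove_artifact_components,
    segment_epochs,
)
from eegharx.simulate import ACTIVITIES, RawRecording

FS = 250.0


def sinusoid_recording(freqs_amps, duration_s=10.0, channels=("Fz", "Oz")):
    t = np.arange(int(duration_s * FS)) / FS
    x = sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)
    samples = np.tile(x, (len(channels), 1))
    return RawRecording(
        channel_labels=list(channels), sampling_rate_hz=FS, samples=samples,
        annotations=[(0.0, duration_s, "resting")],
    )


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestFilters:
    def test_notch_attenuates_60hz_by_20db(self):
        rec = sinusoid_recording([(60.0, 10.0)])
        out = apply_filter(rec, notch_spec(60.0))
        assert rms(out.samples) <= 0.1 * rms(rec.samples)

    def test_zero_in_zero_out(self):
        rec = sinusoid_recording([(60.0, 0.0)])
        out = apply_filter(rec, bandpass_spec())
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_passband_preserves_10hz_rms(self):
        rec = sinusoid_recording([(10.0, 5.0)])
        out = apply_filter(rec, bandpass_spec())
        assert rms(out.samples) == pytest.approx(rms(rec.samples), rel=0.05)

    def test_zero_phase_no_lag(self):
        rec = sinusoid_recording([(10.0, 1.0)])
        out = apply_filter(rec, bandpass_spec())
        x, y = rec.samples[0], out.samples[0]
        lags = np.arange(-20, 21)
        xc = [np.dot(x[max(0, l):len(x) + min(0, l)],
                     y[max(0, -l):len(y) + min(0, -l)]) for l in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_band_edges_validated(self):
        with pytest.raises(ValueError, match="Nyquist"):
            FilterSpec("band_pass", 0.5, 130.0).validate(FS)
        with pytest.raises(ValueError):
            FilterSpec("band_pass", 10.0, 5.0).validate(FS)


class TestICA:
    def test_blink_component_removed_via_reference(self, rng):
        n = int(30 * FS)
        t = np.arange(n) / FS
        eeg = rng.standard_normal((4, n))
        blink = np.zeros(n)
        for s in range(0, n - 200, int(2.5 * FS)):
            blink[s : s + 100] += np.hanning(100)
        blink *= 40.0
        mix = np.array([1.0, 0.3, 0.1, 0.05])
        contaminated = eeg + mix[:, None] * blink
        samples = np.vstack([contaminated, 4.0 * blink + rng.standard_normal(n)])
        rec = RawRecording(
            channel_labels=["Fz", "C1", "T7", "Oz", "EOG"],
            sampling_rate_hz=FS, samples=samples,
        )
        before = abs(np.corrcoef(rec.channel("Fz"), blink)[0, 1])
        out = remove_artifact_components(rec, ["EOG"], 0.7)
        after = abs(np.corrcoef(out.channel("Fz"), blink)[0, 1])
        assert before > 0.8
        assert after <= 0.2

    def test_empty_reference_list_is_identity(self, rng):
        rec = RawRecording(
            channel_labels=["Fz", "Oz"], sampling_rate_hz=FS,
            samples=rng.standard_normal((2, 1000)),
        )
        out = remove_artifact_components(rec, [])
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_threshold_one_is_ica_round_trip(self, rng):
        samples = rng.standard_normal((3, 5000))
        rec = RawRecording(
            channel_labels=["Fz", "C1", "EOG"], sampling_rate_hz=FS, samples=samples,
        )
        out = remove_artifact_components(rec, ["EOG"], correlation_threshold=1.0)
        np.testing.assert_allclose(out.samples[:2], rec.samples[:2], atol=1e-6)

    def test_too_few_samples_raises(self, rng):
        rec = RawRecording(
            channel_labels=["Fz", "C1", "C2", "EOG"], sampling_rate_hz=FS,
            samples=rng.standard_normal((4, 3)),
        )
        with pytest.raises(ValueError, match="samples"):
            remove_artifact_components(rec, ["EOG"])


class TestSegmentation:
    def _rec(self, annotations, duration_s):
        n = int(duration_s * FS)
        return RawRecording(
            channel_labels=["Fz"], sampling_rate_hz=FS,
            samples=np.zeros((1, n)), annotations=annotations,
        )

    def test_exact_division(self):
        rec = self._rec([(0.0, 100.0, "resting")], 100.0)
        eps = segment_epochs(rec, 10.0)
        assert eps.n_epochs == 10
        assert set(eps.labels) == {"resting"}

    def test_remainder_dropped(self):
        rec = self._rec([(0.0, 95.0, "resting")], 95.0)
        assert segment_epochs(rec, 10.0).n_epochs == 9

    def test_per_interval_segmentation_in_order(self):
        rec = self._rec([(0.0, 30.0, "reading"), (30.0, 50.0, "walking")], 50.0)
        eps = segment_epochs(rec, 10.0)
        assert eps.labels == ["reading"] * 3 + ["walking"] * 2

    def test_no_annotations_gives_empty_set(self):
        rec = self._rec([], 20.0)
        assert segment_epochs(rec, 10.0).n_epochs == 0


class TestSNR:
    def _epochs(self, epoch):
        return EpochSet(
            epochs=epoch[None, None, :], labels=["resting"], starts_s=[0.0],
            channel_labels=["Fz"], sampling_rate_hz=FS, epoch_length_s=10.0,
        )

    def test_pure_in_band_sinusoid_kept(self):
        t = np.arange(int(10 * FS)) / FS
        eps = estimate_snr_and_reject(self._epochs(np.sin(2 * np.pi * 10 * t)), 25.0)
        assert eps.kept[0]
        assert eps.snr_db[0] > 25.0

    def test_equal_in_and_out_of_band_power_rejected(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 60 * t)
        eps = estimate_snr_and_reject(self._epochs(x), 25.0)
        assert eps.snr_db[0] == pytest.approx(0.0, abs=1.0)
        assert not eps.kept[0]

    def test_rejected_fraction_tracks_motion_fraction(self):
        cfg = SimulationConfig(
            epochs_per_activity={a: 15 for a in ACTIVITIES},
            motion_epoch_fraction=0.2, seed=6,
        )
        rec = generate_recording(cfg)
        eps = preprocess_recording(rec)
        frac = 1 - eps.n_kept / eps.n_epochs
        assert frac == pytest.approx(0.2, abs=0.05)
        # the rejected epochs are exactly the ground-truth corrupted ones
        assert sorted(np.where(~eps.kept)[0]) == rec.ground_truth["motion_epochs"]


class TestPipelineProperties:
    def test_filtering_preserves_counts_and_rejection_only_decreases(self):
        cfg = SimulationConfig(
            epochs_per_activity={a: 5 for a in ACTIVITIES},
            motion_epoch_fraction=0.2, seed=7,
        )
        rec = generate_recording(cfg)
        eps = preprocess_recording(rec)
        assert eps.n_epochs == sum(cfg.epochs_per_activity.values())
        assert eps.n_kept <= eps.n_epochs
        assert eps.labels == rec.ground_truth["epoch_activities"]
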