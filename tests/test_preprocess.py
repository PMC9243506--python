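"""Montage selection, Butterworth filtering, epoching, baseline correction,
artifact rejection and decimation."""

import numpy as np
import pytest
from scipy import signal

import p300wide as pw
from p300wide.montage import DEFAULT_MONTAGE


def _sine_recording(freq, fs=1000.0, seconds=10.0, amplitude=10.0):
    t = np.arange(int(fs * seconds)) / fs
    data = amplitude * np.sin(2 * np.pi * freq * t)[None, :]
    return pw.ContinuousRecording(data=data, fs=fs, channel_names=["Cz"], markers=[])


class TestChannelSelection:
    def test_64_channel_recording_is_reduced_to_the_30_montage(self, rng):
        extra = [f"X{i}" for i in range(34)]
        names = list(DEFAULT_MONTAGE) + extra
        rng.shuffle(names)
        rec = pw.ContinuousRecording(
            data=rng.standard_normal((64, 500)), fs=100.0, channel_names=names, markers=[]
        )
        out = pw.select_channels(rec)
        assert out.n_channels == 30
        assert out.channel_names == list(DEFAULT_MONTAGE)
        for i, ch in enumerate(DEFAULT_MONTAGE):
            np.testing.assert_array_equal(out.data[i], rec.data[names.index(ch)])

    def test_identity_when_already_montage_ordered(self, rng):
        rec = pw.ContinuousRecording(
            data=rng.standard_normal((30, 100)),
            fs=100.0,
            channel_names=list(DEFAULT_MONTAGE),
            markers=[],
        )
        out = pw.select_channels(rec)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_missing_channel_error_names_it(self, rng):
        names = [c for c in DEFAULT_MONTAGE if c != "FCz"] + ["nope"]
        rec = pw.ContinuousRecording(
            data=rng.standard_normal((30, 100)), fs=100.0, channel_names=names, markers=[]
        )
        with pytest.raises(ValueError, match="FCz"):
            pw.select_channels(rec)


class TestBandpass:
    def test_10_hz_passband_tone_is_preserved(self):
        # oracle: analytic Butterworth magnitude at 10 Hz is ~1; the 0.1 Hz
        # edge has multi-second transients, so use a long signal and its core
        rec = _sine_recording(10.0, seconds=60.0)
        out = pw.bandpass_filter(rec)
        mid = out.data[0, 20000:40000]
        assert np.abs(mid).max() == pytest.approx(10.0, rel=0.05)

    def test_60_hz_stopband_tone_is_attenuated(self):
        # oracle: |H(60 Hz)| for an order-3 Butterworth with 30 Hz edge < 0.15
        rec = _sine_recording(60.0)
        out = pw.bandpass_filter(rec, pw.FilterSpec(mode="causal"))
        gain = np.abs(out.data[0, 5000:]).max() / 10.0
        b, a = signal.butter(3, [0.1, 30.0], btype="bandpass", fs=1000.0)
        _, h = signal.freqz(b, a, worN=[60.0], fs=1000.0)
        assert gain < 0.15
        assert gain == pytest.approx(np.abs(h[0]), abs=0.02)

    def test_dc_is_removed_by_the_highpass_edge(self):
        rec = pw.ContinuousRecording(
            data=np.full((1, 30000), 7.0), fs=1000.0, channel_names=["Cz"], markers=[]
        )
        out = pw.bandpass_filter(rec)
        assert np.abs(out.data[0, 10000:20000]).max() < 0.5

    def test_sampling_rate_must_exceed_twice_the_upper_edge(self):
        rec = pw.ContinuousRecording(
            data=np.zeros((1, 100)), fs=50.0, channel_names=["Cz"], markers=[]
        )
        with pytest.raises(ValueError, match="too low"):
            pw.bandpass_filter(rec)


class TestEpoching:
    def test_one_epoch_per_marker_and_900_ms_duration(self, sparse_cfg, quiet_profile):
        sched = pw.generate_flash_schedule(sparse_cfg, (0, 0), seed=1)
        rec = pw.synthesize_recording(sched, quiet_profile, sparse_cfg, seed=2)
        epochs = pw.segment_epochs(rec)
        assert len(epochs) == 104
        assert epochs.t_end_ms - epochs.t_start_ms == 900.0
        assert epochs.n_samples == round(0.9 * rec.fs)

    def test_edge_clipped_marker_is_dropped(self):
        fs = 100.0
        markers = [
            pw.EventMarker(onset_sample=5, code=1, line_index=0, is_target=False),  # too early
            pw.EventMarker(onset_sample=300, code=2, line_index=1, is_target=True),
        ]
        rec = pw.ContinuousRecording(
            data=np.zeros((2, 600)), fs=fs, channel_names=["a", "b"], markers=markers
        )
        epochs = pw.segment_epochs(rec)
        assert len(epochs) == 1
        assert epochs.labels.tolist() == [1]

    def test_no_markers_gives_empty_epoch_set(self):
        rec = pw.ContinuousRecording(
            data=np.zeros((2, 600)), fs=100.0, channel_names=["a", "b"], markers=[]
        )
        assert len(pw.segment_epochs(rec)) == 0


class TestBaseline:
    def test_baseline_window_mean_is_zero_after_correction(self, run_epochs):
        corrected = pw.baseline_correct(run_epochs)
        n_base = int(round(-corrected.t_start_ms * corrected.fs / 1000.0))
        means = corrected.epochs[:, :, :n_base].mean(axis=2)
        np.testing.assert_allclose(means, 0.0, atol=1e-10)

    def test_correction_is_idempotent(self, run_epochs):
        once = pw.baseline_correct(run_epochs)
        twice = pw.baseline_correct(once)
        np.testing.assert_allclose(twice.epochs, once.epochs, atol=1e-12)

    def test_constant_offset_epoch_becomes_zero(self):
        eset = pw.EpochSet(
            epochs=np.full((1, 2, 90), 7.0),
            labels=np.array([0]),
            subject_ids=np.array(["a"], dtype=object),
            fs=100.0,
        )
        out = pw.baseline_correct(eset)
        np.testing.assert_allclose(out.epochs, 0.0, atol=1e-12)


class TestArtifactRejection:
    def test_within_bounds_keeps_everything(self, run_epochs):
        kept, mask = pw.reject_artifacts(run_epochs)
        assert not mask.any()
        assert len(kept) == len(run_epochs)

    def test_single_150_uv_sample_rejects_exactly_that_epoch(self, run_epochs):
        dirty = run_epochs.epochs.copy()
        dirty[17, 3, 40] = 150.0
        eset = pw.EpochSet(
            epochs=dirty, labels=run_epochs.labels, subject_ids=run_epochs.subject_ids, fs=run_epochs.fs
        )
        kept, mask = pw.reject_artifacts(eset)
        assert mask.sum() == 1 and mask[17]
        assert len(kept) == len(eset) - 1

    def test_rejection_equals_brute_force_extrema_scan(self, rng):
        epochs = rng.standard_normal((60, 5, 90)) * 60.0
        eset = pw.EpochSet(
            epochs=epochs,
            labels=np.zeros(60, dtype=int),
            subject_ids=np.array(["s"] * 60, dtype=object),
            fs=100.0,
        )
        kept, mask = pw.reject_artifacts(eset, threshold=100.0)
        brute = np.array(
            [any(v > 100.0 or v < -100.0 for v in ep.ravel()) for ep in epochs]
        )
        np.testing.assert_array_equal(mask, brute)
        assert len(kept) == int((~brute).sum())


class TestDecimation:
    def test_900_samples_at_1_khz_become_90(self, sparse_cfg, quiet_profile):
        sched = pw.generate_flash_schedule(sparse_cfg, (0, 0), seed=1)
        rec = pw.synthesize_recording(sched, quiet_profile, sparse_cfg, seed=2)
        epochs = pw.segment_epochs(rec)
        out = pw.decimate_epochs(epochs)
        assert out.n_samples == 90
        assert out.fs == 100.0

    def test_identity_when_already_at_target_rate(self, run_epochs):
        out = pw.decimate_epochs(run_epochs, target_fs=run_epochs.fs)
        assert out is run_epochs

    def test_non_integer_factor_is_rejected(self, run_epochs):
        with pytest.raises(ValueError, match="integer"):
            pw.decimate_epochs(run_epochs, target_fs=64.0)

    def test_bandlimited_signal_matches_ideal_resampling(self):
        # oracle: a pure tone below the new Nyquist can be resampled exactly
        # by evaluating the analytic signal at the slow rate
        fs = 1000.0
        t = np.arange(900) / fs
        tone = 10 * np.sin(2 * np.pi * 11.3 * t)
        eset = pw.EpochSet(
            epochs=np.tile(tone, (1, 1, 1)),
            labels=np.array([0]),
            subject_ids=np.array(["a"], dtype=object),
            fs=fs,
        )
        out = pw.decimate_epochs(eset)
        ideal = 10 * np.sin(2 * np.pi * 11.3 * (np.arange(90) / 100.0))
        core = slice(10, 80)  # FIR edge transients excluded
        err = np.sqrt(np.mean((out.epochs[0, 0][core] - ideal[core]) ** 2))
        assert err / np.sqrt(np.mean(ideal[core] ** 2)) < 0.02


class TestFullChain:
    def test_output_shape_and_label_counts(self, sparse_cfg):
        prof = pw.SubjectProfile(
            subject_id="P", sex="M", age_group="young",
            p300_amplitude=8.0, p300_latency=350.0, noise_scale=6.0,
        )
        sched = pw.generate_flash_schedule(sparse_cfg, (2, 2), seed=3)
        rec = pw.synthesize_recording(sched, prof, sparse_cfg, seed=4)
        epochs, rejected = pw.preprocess_recording(rec)
        assert epochs.epochs.shape == (len(epochs), 30, 90)
        assert len(epochs) + rejected.sum() == 104
        if not rejected.any():
            assert int(epochs.labels.sum()) == 16
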