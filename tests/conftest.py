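import numpy as np
import pytest

import p300wide as pw


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sparse_cfg():
    """Paradigm with 1 s between flashes so epoch windows never overlap
    (exact artifact-count checks need disjoint windows)."""
    return pw.ParadigmConfig(flash_duration_ms=100.0, inter_flash_interval_ms=900.0)


@pytest.fixture(scope="session")
def quiet_profile():
    """A deterministic, noise-free subject (for noise-free-limit checks)."""
    return pw.SubjectProfile(
        subject_id="Q1",
        sex="M",
        age_group="young",
        p300_amplitude=8.0,
        p300_latency=350.0,
        latency_jitter_sd=0.0,
        noise_scale=0.0,
    )


@pytest.fixture
def small_recording(rng):
    """A 4-channel toy recording with a handful of markers."""
    fs = 200.0
    data = rng.standard_normal((4, int(fs * 6))) * 5.0
    markers = [
        pw.EventMarker(onset_sample=int(fs * t), code=i + 1, line_index=i, is_target=(i == 0))
        for i, t in enumerate([1.0, 2.0, 3.0, 4.0])
    ]
    return pw.ContinuousRecording(
        data=data, fs=fs, channel_names=["c1", "c2", "c3", "c4"], markers=markers, subject_id="T1"
    )


@pytest.fixture
def run_epochs(sparse_cfg, quiet_profile):
    """One preprocessed run (104 epochs) of a clean synthetic subject."""
    sched = pw.generate_flash_schedule(sparse_cfg, (2, 3), seed=7)
    prof = pw.SubjectProfile(
        subject_id="R1", sex="F", age_group="mid",
        p300_amplitude=8.0, p300_latency=360.0, noise_scale=6.0,
    )
    rec = pw.synthesize_recording(sched, prof, sparse_cfg, seed=8)
    epochs, _ = pw.preprocess_recording(rec)
    return epochs
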