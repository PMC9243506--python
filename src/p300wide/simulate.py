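"""Synthetic P300 matrix-speller EEG.

Emulates the oddball speller paradigm: a 6x7 character matrix whose 6 rows
and 7 columns flash in random order; one *sequence* flashes all 13 lines once
(2 of them crossing the attended character, so targets are 2 of 13); one *run*
is 8 sequences (104 flashes) and outputs one character; one *session* is 5
runs.

The evoked response is modeled as a Gaussian-windowed positive deflection
whose amplitude and latency are subject-specific and linked to sex and age
group — the between-subject structure a memorizing (wide) model can exploit.
The background is 1/f-power noise plus a 10 Hz alpha sinusoid per channel.
No volume-conduction forward model or physiological artifacts are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import ContinuousRecording, EventMarker
from .montage import DEFAULT_MONTAGE, default_spatial_weights

__all__ = [
    "ParadigmConfig",
    "SubjectProfile",
    "FlashEvent",
    "CohortHeterogeneity",
    "generate_flash_schedule",
    "synthesize_erp_template",
    "synthesize_recording",
    "synthesize_session",
    "inject_artifacts",
    "sample_profiles",
    "generate_cohort",
]

#: Temporal standard deviation of the Gaussian ERP bump, ms.
ERP_WIDTH_MS = 55.0


@dataclass(frozen=True)
class ParadigmConfig:
    """Speller paradigm timing and structure.

    Flash duration and inter-flash interval are not dictated by the paradigm
    structure; the defaults (100 ms flash, 75 ms ISI, i.e. 175 ms stimulus
    onset asynchrony) follow common row/column speller practice and are fully
    configurable.
    """

    n_rows: int = 6
    n_cols: int = 7
    sequences_per_run: int = 8
    runs_per_session: int = 5
    sessions: int = 1
    flash_duration_ms: float = 100.0
    inter_flash_interval_ms: float = 75.0
    inter_run_interval_ms: float = 1000.0
    lead_in_ms: float = 1000.0
    fs_acquisition: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("matrix must have at least one row and column")
        if self.sequences_per_run < 1 or self.runs_per_session < 1 or self.sessions < 1:
            raise ValueError("counts must be >= 1")

    @property
    def n_lines(self) -> int:
        return self.n_rows + self.n_cols

    @property
    def soa_ms(self) -> float:
        """Stimulus onset asynchrony (flash duration + ISI)."""
        return self.flash_duration_ms + self.inter_flash_interval_ms

    @property
    def flashes_per_run(self) -> int:
        return self.n_lines * self.sequences_per_run


@dataclass
class SubjectProfile:
    """Participant attributes plus the latent ERP parameters of this subject."""

    subject_id: str
    sex: str  # 'M' or 'F'
    age_group: str
    p300_amplitude: float  # peak of the evoked deflection at the best channel, uV
    p300_latency: float  # ms after flash onset
    latency_jitter_sd: float = 8.0  # trial-to-trial latency jitter, ms
    noise_scale: float = 8.0  # background RMS per channel, uV
    nontarget_amplitude: float = 0.0  # optional small deflection on non-targets
    spatial_weights: np.ndarray | None = None  # per-channel gain, centro-parietal max
    channel_names: list[str] = field(default_factory=lambda: list(DEFAULT_MONTAGE))

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.p300_amplitude < 0:
            raise ValueError("p300_amplitude must be >= 0")
        if not 0 < self.p300_latency < 800:
            raise ValueError("p300_latency must lie in (0, 800) ms")
        if self.spatial_weights is None:
            self.spatial_weights = default_spatial_weights(self.channel_names)
        self.spatial_weights = np.asarray(self.spatial_weights, dtype=float)
        if len(self.spatial_weights) != len(self.channel_names):
            raise ValueError("spatial_weights must have one entry per channel")


@dataclass(frozen=True)
class FlashEvent:
    sequence_index: int
    line_index: int
    onset_ms: float
    is_target: bool


def _target_lines(cfg: ParadigmConfig, target_position: tuple[int, int]) -> set[int]:
    row, col = target_position
    if not (0 <= row < cfg.n_rows and 0 <= col < cfg.n_cols):
        raise ValueError(f"target {target_position} outside the {cfg.n_rows}x{cfg.n_cols} grid")
    return {row, cfg.n_rows + col}


def generate_flash_schedule(
    cfg: ParadigmConfig, target_position: tuple[int, int], seed: int
) -> list[FlashEvent]:
    """Flash schedule for one run (``sequences_per_run`` x ``n_lines`` flashes).

    Within each sequence the 13 line indices appear in a uniformly random
    order; onsets are spaced by the stimulus onset asynchrony. Exactly two
    flashes per sequence (the target's row and column) are targets.
    """
    targets = _target_lines(cfg, target_position)
    rng = np.random.default_rng(seed)
    events: list[FlashEvent] = []
    t = 0.0
    for s in range(cfg.sequences_per_run):
        for line in rng.permutation(cfg.n_lines):
            events.append(FlashEvent(s, int(line), t, int(line) in targets))
            t += cfg.soa_ms
    return events


def synthesize_erp_template(
    profile: SubjectProfile, fs: float, length_ms: float, width_ms: float = ERP_WIDTH_MS
) -> np.ndarray:
    """Per-channel evoked waveform ``(n_channels, round(length_ms*fs/1000))``.

    A Gaussian bump peaking ``p300_latency`` ms after onset with peak
    ``p300_amplitude`` uV on the maximum-gain channel, scaled per channel by
    the profile's spatial weights.
    """
    if not 0 <= profile.p300_latency < length_ms:
        raise ValueError(
            f"latency {profile.p300_latency} ms outside template window of {length_ms} ms"
        )
    n = int(round(length_ms * fs / 1000.0))
    t_ms = np.arange(n) * 1000.0 / fs
    bump = profile.p300_amplitude * np.exp(
        -0.5 * ((t_ms - profile.p300_latency) / width_ms) ** 2
    )
    return profile.spatial_weights[:, None] * bump[None, :]


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int, fs: float) -> np.ndarray:
    """Unit-RMS noise with power ~ 1/f per channel (flat below 0.5 Hz)."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(f, 0.5))
    shaping[0] = 0.0  # no DC
    pink = np.fft.irfft(spec * shaping[None, :], n=n_samples, axis=1)
    rms = pink.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return pink / rms


def synthesize_recording(
    schedule: list[FlashEvent],
    profile: SubjectProfile,
    cfg: ParadigmConfig,
    seed: int,
    tail_ms: float = 1000.0,
) -> ContinuousRecording:
    """Continuous EEG realizing a flash schedule for one subject.

    Background = ``noise_scale`` x (1/f noise + 0.5 amplitude 10 Hz alpha);
    the subject's ERP template is added at every target onset with Gaussian
    per-trial latency jitter. Markers reproduce the schedule exactly (onsets
    shifted by the paradigm's lead-in).
    """
    if not schedule:
        raise ValueError("schedule must be non-empty")
    fs = cfg.fs_acquisition
    rng = np.random.default_rng(seed)
    n_ch = len(profile.channel_names)
    last_onset = max(e.onset_ms for e in schedule)
    n_samples = int(round((cfg.lead_in_ms + last_onset + cfg.soa_ms + tail_ms) * fs / 1000.0))

    data = profile.noise_scale * _pink_noise(rng, n_ch, n_samples, fs)
    t = np.arange(n_samples) / fs
    phases = rng.uniform(0, 2 * np.pi, size=n_ch)
    data += 0.5 * profile.noise_scale * np.sin(
        2 * np.pi * 10.0 * t[None, :] + phases[:, None]
    )

    template = synthesize_erp_template(profile, fs, 800.0)
    nt_template = None
    if profile.nontarget_amplitude > 0:
        nt_template = synthesize_erp_template(
            replace(profile, p300_amplitude=profile.nontarget_amplitude), fs, 800.0
        )
    markers: list[EventMarker] = []
    for ev in schedule:
        onset = int(round((cfg.lead_in_ms + ev.onset_ms) * fs / 1000.0))
        markers.append(
            EventMarker(
                onset_sample=onset,
                code=ev.line_index + 1,
                line_index=ev.line_index,
                is_target=ev.is_target,
            )
        )
        tpl = template if ev.is_target else nt_template
        if tpl is None:
            continue
        jitter = int(round(rng.normal(0.0, profile.latency_jitter_sd) * fs / 1000.0))
        start = onset + jitter
        stop = min(start + tpl.shape[1], n_samples)
        lo = max(start, 0)
        if lo < stop:
            data[:, lo:stop] += tpl[:, lo - start : stop - start]

    return ContinuousRecording(
        data=data,
        fs=fs,
        channel_names=list(profile.channel_names),
        markers=markers,
        subject_id=profile.subject_id,
    )


def synthesize_session(
    profile: SubjectProfile,
    cfg: ParadigmConfig,
    seed: int,
    targets: list[tuple[int, int]] | None = None,
) -> ContinuousRecording:
    """One session (``runs_per_session`` runs back to back) as one recording.

    Each run spells one randomly chosen (or given) character; runs are
    separated by ``inter_run_interval_ms``.
    """
    rng = np.random.default_rng(seed)
    if targets is None:
        targets = [
            (int(rng.integers(cfg.n_rows)), int(rng.integers(cfg.n_cols)))
            for _ in range(cfg.runs_per_session)
        ]
    if len(targets) != cfg.runs_per_session:
        raise ValueError("need one target character per run")
    run_span = cfg.flashes_per_run * cfg.soa_ms
    combined: list[FlashEvent] = []
    for r, tgt in enumerate(targets):
        offset = r * (run_span + cfg.inter_run_interval_ms)
        for ev in generate_flash_schedule(cfg, tgt, int(rng.integers(2**31))):
            combined.append(replace(ev, onset_ms=ev.onset_ms + offset))
    return synthesize_recording(combined, profile, cfg, seed=int(rng.integers(2**31)))


def inject_artifacts(
    rec: ContinuousRecording, k: int, amplitude: float, seed: int
) -> tuple[ContinuousRecording, list[int]]:
    """Add high-amplitude artifacts into ``k`` distinct epoch windows.

    A smooth positive bump of peak ``1.5 * amplitude`` (so it survives the
    0.1-30 Hz bandpass comfortably above ``amplitude``) is added on one
    channel at the center of each chosen epoch. Returns the new recording and
    the affected marker indices. With overlapping epoch windows (short SOA)
    neighbouring epochs may also exceed the rejection threshold; use a sparse
    schedule when exact counts matter.
    """
    if amplitude <= 100:
        raise ValueError("artifact amplitude must exceed 100 uV to trigger rejection")
    if k > len(rec.markers):
        raise ValueError(f"k={k} exceeds the {len(rec.markers)} epochs implied by markers")
    rng = np.random.default_rng(seed)
    data = rec.data.copy()
    chosen = sorted(rng.choice(len(rec.markers), size=k, replace=False).tolist()) if k else []
    fs = rec.fs
    width = int(round(0.040 * fs))  # 40 ms Gaussian sd
    for idx in chosen:
        onset = rec.markers[idx].onset_sample
        center = onset + int(round(0.35 * fs))  # mid-epoch, clear of the baseline window
        lo = max(center - 4 * width, 0)
        hi = min(center + 4 * width, data.shape[1])
        tt = np.arange(lo, hi)
        ch = int(rng.integers(rec.n_channels))
        data[ch, lo:hi] += 1.5 * amplitude * np.exp(-0.5 * ((tt - center) / width) ** 2)
    out = ContinuousRecording(
        data=data,
        fs=fs,
        channel_names=list(rec.channel_names),
        markers=list(rec.markers),
        subject_id=rec.subject_id,
    )
    return out, chosen


@dataclass(frozen=True)
class CohortHeterogeneity:
    """Distributions of the subject-specific ERP parameters.

    Amplitude and latency depend on sex and age group (linearly in the age
    bin index), realizing the individual-differences premise the wide branch
    is meant to memorize. Units: uV and ms.
    """

    age_groups: tuple[str, ...] = ("young", "mid", "older")
    amplitude_base: float = 8.0
    amplitude_sex_shift: float = 0.8  # added for females
    amplitude_age_slope: float = -1.0  # per age bin
    amplitude_sd: float = 0.8
    latency_base: float = 320.0
    latency_sex_shift: float = 10.0  # added for females
    latency_age_slope: float = 40.0  # per age bin
    latency_sd: float = 15.0
    latency_jitter_sd: float = 8.0
    noise_mean: float = 8.0
    noise_sd: float = 1.0

    def amplitude_mean(self, sex: str, age_index: int) -> float:
        return (
            self.amplitude_base
            + (self.amplitude_sex_shift if sex == "F" else 0.0)
            + self.amplitude_age_slope * age_index
        )

    def latency_mean(self, sex: str, age_index: int) -> float:
        return (
            self.latency_base
            + (self.latency_sex_shift if sex == "F" else 0.0)
            + self.latency_age_slope * age_index
        )


def sample_profiles(
    n_subjects: int,
    heterogeneity: CohortHeterogeneity | None = None,
    seed: int = 0,
    channel_names: list[str] | None = None,
) -> list[SubjectProfile]:
    """Draw subject profiles from the heterogeneity distributions."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    het = heterogeneity or CohortHeterogeneity()
    channels = list(channel_names or DEFAULT_MONTAGE)
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_subjects):
        sex = "M" if rng.random() < 0.5 else "F"
        age_index = int(rng.integers(len(het.age_groups)))
        amp = max(0.5, rng.normal(het.amplitude_mean(sex, age_index), het.amplitude_sd))
        lat = float(np.clip(rng.normal(het.latency_mean(sex, age_index), het.latency_sd), 150, 650))
        noise = max(1.0, rng.normal(het.noise_mean, het.noise_sd))
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:02d}",
                sex=sex,
                age_group=het.age_groups[age_index],
                p300_amplitude=float(amp),
                p300_latency=lat,
                latency_jitter_sd=het.latency_jitter_sd,
                noise_scale=float(noise),
                channel_names=channels,
            )
        )
    return profiles


def generate_cohort(
    n_subjects: int = 8,
    heterogeneity: CohortHeterogeneity | None = None,
    cfg: ParadigmConfig | None = None,
    seed: int = 0,
) -> list[tuple[SubjectProfile, list[ContinuousRecording]]]:
    """Simulate a cohort: one profile plus one recording per session each.

    Deterministic in (config, heterogeneity, seed).
    """
    cfg = cfg or ParadigmConfig()
    rng = np.random.default_rng(seed)
    profiles = sample_profiles(n_subjects, heterogeneity, seed=int(rng.integers(2**31)))
    cohort = []
    for profile in profiles:
        recs = [
            synthesize_session(profile, cfg, seed=int(rng.integers(2**31)))
            for _ in range(cfg.sessions)
        ]
        cohort.append((profile, recs))
    return cohort
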