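"""Preprocessing chain: montage selection, 0.1-30 Hz third-order Butterworth
bandpass, stimulus-locked epoching (-100..+800 ms), baseline correction on
the pre-stimulus interval, +/-100 uV artifact rejection, and decimation to
the model's 100 Hz working rate (90 samples per 900 ms epoch).

Filtering is zero-phase (forward-backward, doubling the effective magnitude
order) by default for offline analysis; a causal mode is provided for the
online path. Artifact rejection is applied *after* baseline correction so a
constant offset cannot trigger it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import EPOCH_T_END_MS, EPOCH_T_START_MS, ContinuousRecording, EpochSet
from .montage import DEFAULT_MONTAGE

__all__ = [
    "MontageSpec",
    "FilterSpec",
    "select_channels",
    "bandpass_filter",
    "segment_epochs",
    "baseline_correct",
    "reject_artifacts",
    "decimate_epochs",
    "preprocess_recording",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MontageSpec:
    """An ordered set of exactly 30 channel labels."""

    channels: tuple[str, ...] = DEFAULT_MONTAGE

    def __post_init__(self) -> None:
        if len(self.channels) != 30:
            raise ValueError(f"montage must list exactly 30 channels, got {len(self.channels)}")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("montage labels must be unique")


@dataclass(frozen=True)
class FilterSpec:
    low_hz: float = 0.1
    high_hz: float = 30.0
    order: int = 3
    mode: str = "zero_phase"  # or "causal"

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.mode not in ("zero_phase", "causal"):
            raise ValueError(f"mode must be 'zero_phase' or 'causal', got {self.mode!r}")


def select_channels(rec: ContinuousRecording, montage: MontageSpec | None = None) -> ContinuousRecording:
    """Keep (and reorder to) the montage's 30 channels."""
    montage = montage or MontageSpec()
    index = {name: i for i, name in enumerate(rec.channel_names)}
    missing = [c for c in montage.channels if c not in index]
    if missing:
        raise ValueError(f"recording is missing montage channels: {', '.join(missing)}")
    rows = [index[c] for c in montage.channels]
    return ContinuousRecording(
        data=rec.data[rows],
        fs=rec.fs,
        channel_names=list(montage.channels),
        markers=list(rec.markers),
        subject_id=rec.subject_id,
    )


def bandpass_filter(rec: ContinuousRecording, spec: FilterSpec | None = None) -> ContinuousRecording:
    spec = spec or FilterSpec()
    if rec.fs <= 2 * spec.high_hz:
        raise ValueError(
            f"sampling rate {rec.fs} Hz too low for a {spec.high_hz} Hz upper edge"
        )
    sos = signal.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=rec.fs, output="sos"
    )
    if spec.mode == "zero_phase":
        filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    else:
        filtered = signal.sosfilt(sos, rec.data, axis=1)
    return ContinuousRecording(
        data=filtered,
        fs=rec.fs,
        channel_names=list(rec.channel_names),
        markers=list(rec.markers),
        subject_id=rec.subject_id,
    )


def segment_epochs(rec: ContinuousRecording) -> EpochSet:
    """One epoch per marker over [-100 ms, +800 ms), labeled by is_target.

    Markers whose window would run past either edge of the recording are
    dropped (count logged).
    """
    if not rec.markers:
        logger.warning("recording has no markers; returning empty EpochSet")
    fs = rec.fs
    n_epoch = int(round(0.9 * fs))
    offset = int(round(EPOCH_T_START_MS * fs / 1000.0))
    epochs, labels = [], []
    dropped = 0
    for m in rec.markers:
        start = m.onset_sample + offset
        stop = start + n_epoch
        if start < 0 or stop > rec.n_samples:
            dropped += 1
            continue
        epochs.append(rec.data[:, start:stop])
        labels.append(int(m.is_target))
    if dropped:
        logger.info("segment_epochs: dropped %d edge-clipped epochs", dropped)
    shape = (len(epochs), rec.n_channels, n_epoch)
    stack = np.stack(epochs) if epochs else np.empty(shape)
    return EpochSet(
        epochs=stack,
        labels=np.array(labels, dtype=np.int8),
        subject_ids=np.array([rec.subject_id] * len(epochs), dtype=object),
        fs=fs,
        t_start_ms=EPOCH_T_START_MS,
        t_end_ms=EPOCH_T_END_MS,
    )


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each epoch's per-channel mean over the pre-stimulus window."""
    if epochs.t_start_ms > -1e-9:
        raise ValueError("epoch window does not include a pre-stimulus baseline interval")
    n_base = int(round(-epochs.t_start_ms * epochs.fs / 1000.0))
    baseline = epochs.epochs[:, :, :n_base].mean(axis=2, keepdims=True)
    return EpochSet(
        epochs=epochs.epochs - baseline,
        labels=epochs.labels,
        subject_ids=epochs.subject_ids,
        fs=epochs.fs,
        t_start_ms=epochs.t_start_ms,
        t_end_ms=epochs.t_end_ms,
    )


def reject_artifacts(
    epochs: EpochSet, threshold: float = 100.0
) -> tuple[EpochSet, np.ndarray]:
    """Drop epochs with any sample outside [-threshold, +threshold] uV.

    Returns the kept epochs and the boolean rejection mask (True = rejected).
    """
    if len(epochs) == 0:
        return epochs, np.zeros(0, dtype=bool)
    amax = np.abs(epochs.epochs).max(axis=(1, 2))
    rejected = amax > threshold
    return epochs.select(~rejected), rejected


def decimate_epochs(epochs: EpochSet, target_fs: float = 100.0) -> EpochSet:
    """Anti-alias lowpass then downsample each epoch to ``target_fs``.

    The decimation factor fs/target_fs must be an integer; 900 ms at 100 Hz
    is exactly 90 samples. Identity when fs already equals target_fs.
    """
    factor = epochs.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"decimation factor {factor} is not an integer (fs={epochs.fs}, target={target_fs})"
        )
    factor = int(round(factor))
    if factor == 1:
        return epochs
    out = signal.decimate(epochs.epochs, factor, axis=2, ftype="fir", zero_phase=True)
    return EpochSet(
        epochs=out,
        labels=epochs.labels,
        subject_ids=epochs.subject_ids,
        fs=target_fs,
        t_start_ms=epochs.t_start_ms,
        t_end_ms=epochs.t_end_ms,
    )


def preprocess_recording(
    rec: ContinuousRecording,
    montage: MontageSpec | None = None,
    filter_spec: FilterSpec | None = None,
    threshold: float = 100.0,
    target_fs: float = 100.0,
) -> tuple[EpochSet, np.ndarray]:
    """The full offline chain; returns (clean 30x90 epochs, rejection mask)."""
    rec = select_channels(rec, montage)
    rec = bandpass_filter(rec, filter_spec)
    epochs = segment_epochs(rec)
    epochs = baseline_correct(epochs)
    epochs, rejected = reject_artifacts(epochs, threshold)
    epochs = decimate_epochs(epochs, target_fs)
    logger.info(
        "preprocess: kept %d epochs, rejected %d", len(epochs), int(rejected.sum())
    )
    return epochs, rejected
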