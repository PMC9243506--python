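"""Core in-memory containers for continuous EEG and stimulus-locked epochs.

Conventions used throughout the package:

* amplitudes are always microvolts (readers rescale on the way in);
* sample indexing is 0-based and epoch windows are half-open ``[start, end)``;
* epoch windows run from 100 ms before to 800 ms after the flash, i.e.
  900 ms, which at the model's 100 Hz working rate is exactly 90 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EventMarker", "ContinuousRecording", "EpochSet", "EPOCH_T_START_MS", "EPOCH_T_END_MS"]

#: Epoch window relative to the flash onset, in milliseconds.
EPOCH_T_START_MS = -100.0
EPOCH_T_END_MS = 800.0


@dataclass(frozen=True)
class EventMarker:
    """One row/column flash of the speller matrix.

    Parameters
    ----------
    onset_sample : int
        0-based sample index of the flash onset within the recording.
    code : int
        Integer flash code as carried by the acquisition marker channel.
    line_index : int
        Which line flashed: 0-5 are the six rows, 6-12 the seven columns.
    is_target : bool
        True when the flashed line contains the attended character.
    """

    onset_sample: int
    code: int
    line_index: int
    is_target: bool

    def __post_init__(self) -> None:
        if self.onset_sample < 0:
            raise ValueError(f"onset_sample must be >= 0, got {self.onset_sample}")
        if not 0 <= self.line_index <= 12:
            raise ValueError(f"line_index must be in [0, 12], got {self.line_index}")


@dataclass
class ContinuousRecording:
    """Multichannel EEG in microvolts with flash markers.

    ``data`` is ``(n_channels, n_samples)``; ``markers`` are kept ordered by
    onset sample.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    markers: list[EventMarker] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got shape {self.data.shape}")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} data rows"
            )
        for m in self.markers:
            if m.onset_sample >= self.data.shape[1]:
                raise ValueError(
                    f"marker onset {m.onset_sample} outside recording of "
                    f"{self.data.shape[1]} samples"
                )
        self.markers = sorted(self.markers, key=lambda m: m.onset_sample)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Stack of stimulus-locked epochs with binary target labels.

    ``epochs`` is ``(n, n_channels, n_samples)``; ``labels`` is 0/1 with 1
    marking a target flash; ``subject_ids`` holds one identifier per epoch so
    sets from several participants can be concatenated.
    """

    epochs: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    fs: float
    t_start_ms: float = EPOCH_T_START_MS
    t_end_ms: float = EPOCH_T_END_MS

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.epochs.ndim != 3:
            raise ValueError(f"epochs must be 3-D (n, channels, samples), got {self.epochs.shape}")
        n = self.epochs.shape[0]
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise ValueError(
                f"lengths disagree: {n} epochs, {len(self.labels)} labels, "
                f"{len(self.subject_ids)} subject ids"
            )
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be binary 0/1, found {sorted(bad)}")
        self.labels = self.labels.astype(np.int8)
        if abs((self.t_end_ms - self.t_start_ms) - 900.0) > 1e-9:
            raise ValueError(
                f"epoch window must span 900 ms, got {self.t_end_ms - self.t_start_ms}"
            )
        expected = int(round(0.9 * self.fs))
        if n > 0 and self.epochs.shape[2] != expected:
            raise ValueError(
                f"epochs have {self.epochs.shape[2]} samples but 900 ms at {self.fs} Hz "
                f"is {expected}"
            )

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset of epochs (boolean mask or integer indices)."""
        mask = np.asarray(mask)
        return EpochSet(
            epochs=self.epochs[mask],
            labels=self.labels[mask],
            subject_ids=self.subject_ids[mask],
            fs=self.fs,
            t_start_ms=self.t_start_ms,
            t_end_ms=self.t_end_ms,
        )


def concatenate_epochs(sets: list[EpochSet]) -> EpochSet:
    """Stack several epoch sets (same fs/window) into one."""
    if not sets:
        raise ValueError("need at least one EpochSet")
    fs = sets[0].fs
    for s in sets[1:]:
        if s.fs != fs or s.t_start_ms != sets[0].t_start_ms:
            raise ValueError("epoch sets disagree on fs or window")
    return EpochSet(
        epochs=np.concatenate([s.epochs for s in sets], axis=0),
        labels=np.concatenate([s.labels for s in sets]),
        subject_ids=np.concatenate([s.subject_ids for s in sets]),
        fs=fs,
        t_start_ms=sets[0].t_start_ms,
        t_end_ms=sets[0].t_end_ms,
    )
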