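"""Evaluation harnesses: within-subject CV, leave-one-subject-out,
random split-half over subjects, online sliding-window prediction, and
character decoding for the matrix speller.

All harnesses accept a *classifier factory* — a zero-argument callable
returning an object with ``fit(X, y, subject_ids=..., profiles=...)`` and
``predict_proba(X, subject_ids=..., profiles=...)`` — so the wide-and-deep
detector, its ablations and plain scikit-learn baselines all run under the
same contract. Results come back as a tidy DataFrame (participant x
classifier x fold/repeat -> accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import signal as _signal
from sklearn.model_selection import StratifiedKFold

from .containers import ContinuousRecording, EpochSet, concatenate_epochs
from .network import CombinedModel, combined_predict
from .preprocess import FilterSpec, MontageSpec, bandpass_filter, preprocess_recording
from .simulate import ParadigmConfig

__all__ = [
    "ExperimentConfig",
    "accuracy",
    "within_subject_cv",
    "leave_one_subject_out",
    "split_half",
    "online_sliding_predict",
    "decode_character",
    "build_dataset",
]


@dataclass(frozen=True)
class ExperimentConfig:
    design: str = "within_subject"  # or "leave_one_out", "split_half"
    n_folds: int = 5
    train_fraction: float = 0.8
    n_train_subjects: int = 4
    n_repeats: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def accuracy(probs, labels, threshold: float = 0.5) -> float:
    """Fraction of epochs where (p >= threshold) matches the label."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels lengths differ")
    if probs.size == 0:
        raise ValueError("empty input")
    return float(np.mean((probs >= threshold).astype(int) == labels))


def _proba(clf, X, subject_ids=None, profiles=None) -> np.ndarray:
    p = clf.predict_proba(X, subject_ids=subject_ids, profiles=profiles)
    p = np.asarray(p)
    return p[:, 1] if p.ndim == 2 else p.ravel()


def build_dataset(cohort, **preprocess_kwargs):
    """Preprocess a simulated cohort into the harness inputs.

    Returns ``(epochs_by_subject, profiles)`` where each subject's sessions
    are preprocessed to clean 30x90 epoch sets and concatenated.
    """
    epochs_by_subject: dict[str, EpochSet] = {}
    profiles: dict[str, object] = {}
    for profile, recordings in cohort:
        sets = [preprocess_recording(rec, **preprocess_kwargs)[0] for rec in recordings]
        epochs_by_subject[profile.subject_id] = (
            sets[0] if len(sets) == 1 else concatenate_epochs(sets)
        )
        profiles[profile.subject_id] = profile
    return epochs_by_subject, profiles


def within_subject_cv(
    dataset: Mapping[str, EpochSet],
    classifier_factory: Callable,
    cfg: ExperimentConfig | None = None,
    profiles: Mapping[str, object] | None = None,
    classifier_name: str | None = None,
) -> pd.DataFrame:
    """Stratified k-fold CV per subject (each test fold is 1/k of the data).

    Stratification preserves the 2:11 target ratio in every fold; the fold
    assignment is seeded.
    """
    cfg = cfg or ExperimentConfig()
    rows = []
    for sid, eset in dataset.items():
        y = np.asarray(eset.labels)
        counts = np.bincount(y, minlength=2)
        if counts.min() < cfg.n_folds:
            raise ValueError(
                f"subject {sid}: minority class has {counts.min()} epochs, "
                f"fewer than {cfg.n_folds} folds"
            )
        skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
        for fold, (tr, te) in enumerate(skf.split(eset.epochs, y)):
            clf = classifier_factory()
            clf.fit(
                eset.epochs[tr], y[tr], subject_ids=eset.subject_ids[tr], profiles=profiles
            )
            p = _proba(clf, eset.epochs[te], eset.subject_ids[te], profiles)
            rows.append(
                {
                    "participant": sid,
                    "classifier": classifier_name or type(clf).__name__,
                    "fold": fold,
                    "accuracy": accuracy(p, y[te]),
                }
            )
    return pd.DataFrame(rows)


def leave_one_subject_out(
    dataset: Mapping[str, EpochSet],
    classifier_factory: Callable,
    cfg: ExperimentConfig | None = None,
    profiles: Mapping[str, object] | None = None,
    classifier_name: str | None = None,
) -> pd.DataFrame:
    """Train on all subjects but one, test on the held-out one.

    The held-out subject's id is absent from the training vocabulary, so the
    wide/embedding features fall back to the unknown-subject convention
    (zero subject block; demographics still encoded).
    """
    cfg = cfg or ExperimentConfig(design="leave_one_out")
    ids = list(dataset.keys())
    if len(ids) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    rows = []
    for sid in ids:
        train_sets = [dataset[s] for s in ids if s != sid]
        train = concatenate_epochs(train_sets)
        train_profiles = (
            {s: profiles[s] for s in ids if s != sid} if profiles is not None else None
        )
        clf = classifier_factory()
        clf.fit(train.epochs, train.labels, subject_ids=train.subject_ids, profiles=train_profiles)
        test = dataset[sid]
        p = _proba(clf, test.epochs, test.subject_ids, profiles)
        rows.append(
            {
                "participant": sid,
                "classifier": classifier_name or type(clf).__name__,
                "accuracy": accuracy(p, np.asarray(test.labels)),
            }
        )
    return pd.DataFrame(rows)


def split_half(
    dataset: Mapping[str, EpochSet],
    classifier_factory: Callable,
    cfg: ExperimentConfig | None = None,
    profiles: Mapping[str, object] | None = None,
    classifier_name: str | None = None,
) -> pd.DataFrame:
    """Random disjoint train/test subject splits, repeated.

    Default: 4 training subjects, the rest tested, 4 repeats.
    """
    cfg = cfg or ExperimentConfig(design="split_half")
    ids = list(dataset.keys())
    if len(ids) < 2 * cfg.n_train_subjects:
        raise ValueError(
            f"need >= {2 * cfg.n_train_subjects} subjects for disjoint "
            f"{cfg.n_train_subjects}-subject train/test splits"
        )
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for rep in range(cfg.n_repeats):
        perm = rng.permutation(len(ids))
        train_ids = [ids[i] for i in perm[: cfg.n_train_subjects]]
        test_ids = [ids[i] for i in perm[cfg.n_train_subjects :]]
        train = concatenate_epochs([dataset[s] for s in train_ids])
        train_profiles = (
            {s: profiles[s] for s in train_ids} if profiles is not None else None
        )
        clf = classifier_factory()
        clf.fit(train.epochs, train.labels, subject_ids=train.subject_ids, profiles=train_profiles)
        for sid in test_ids:
            test = dataset[sid]
            p = _proba(clf, test.epochs, test.subject_ids, profiles)
            rows.append(
                {
                    "participant": sid,
                    "classifier": classifier_name or type(clf).__name__,
                    "repeat": rep,
                    "accuracy": accuracy(p, np.asarray(test.labels)),
                }
            )
    return pd.DataFrame(rows)


def online_sliding_predict(
    stream: ContinuousRecording,
    model: CombinedModel,
    profile,
    window_s: float = 1.0,
    hop_s: float = 0.5,
    montage: MontageSpec | None = None,
    target_fs: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Online path: every ``hop_s`` seconds score the most recent 1 s buffer.

    Each buffer is causally bandpass filtered, cropped to its trailing
    900 ms, baseline-corrected on the first 100 ms of that crop, decimated to
    the working rate and scored. The participant embedding is computed once
    (cached inside the model). Returns (window-end times in s, probabilities);
    empty when the stream is shorter than one window.
    """
    import warnings

    from .preprocess import select_channels

    if stream.duration_s < window_s:
        warnings.warn("stream shorter than one analysis window; no output")
        return np.array([]), np.array([])
    rec = select_channels(stream, montage) if montage or stream.n_channels != model.n_channels else stream
    fs = rec.fs
    spec = FilterSpec(mode="causal")
    sos = _signal.butter(spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs, output="sos")
    win = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    crop = int(round(0.9 * fs))
    n_base = int(round(0.1 * fs))
    factor = int(round(fs / target_fs))
    times, probs = [], []
    for end in range(win, rec.n_samples + 1, hop):
        buf = rec.data[:, end - win : end]
        filt = _signal.sosfilt(sos, buf, axis=1)
        seg = filt[:, -crop:]
        seg = seg - seg[:, :n_base].mean(axis=1, keepdims=True)
        if factor > 1:
            seg = _signal.decimate(seg, factor, axis=1, ftype="fir", zero_phase=True)
        probs.append(combined_predict(seg, profile, model))
        times.append(end / fs)
    return np.asarray(times), np.asarray(probs)


def decode_character(
    probs,
    line_indices,
    cfg: ParadigmConfig | None = None,
) -> tuple[int, int]:
    """Decode one spelled character from a run's per-flash probabilities.

    Sums the probabilities each line received over the run's sequences; the
    predicted row is the best of lines 0..5 and the column the best of lines
    6..12. Ties resolve to the lowest index.
    """
    cfg = cfg or ParadigmConfig()
    probs = np.asarray(probs, dtype=float)
    line_indices = np.asarray(line_indices)
    if probs.shape != line_indices.shape:
        raise ValueError("probs and line_indices lengths differ")
    scores = np.zeros(cfg.n_lines)
    counts = np.zeros(cfg.n_lines, dtype=int)
    for p, li in zip(probs, line_indices):
        scores[li] += p
        counts[li] += 1
    if (counts != cfg.sequences_per_run).any():
        bad = int(np.flatnonzero(counts != cfg.sequences_per_run)[0])
        raise ValueError(
            f"line {bad} covered {counts[bad]} times, expected {cfg.sequences_per_run}"
        )
    row = int(np.argmax(scores[: cfg.n_rows]))
    col = int(np.argmax(scores[cfg.n_rows :]))
    return row, col
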