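"""Wide-branch input assembly.

The wide (memorizing) branch sees ``x = [d1, d2, dphi]``:

* ``d1`` — the dense EEG epoch, flattened row-major (channel-major) from
  its (30, 90) working shape to 2700 values;
* ``d2`` — one-hot participant attributes (subject id, sex, age group) in
  disjoint blocks of total length ``T``;
* ``dphi`` — cross-product transformations: each cross feature is the
  product (for 0/1 inputs, the logical AND) of a selected subset of the
  one-hot entries.

A subject id outside the training vocabulary encodes as an all-zero subject
block, so a never-seen participant can still be scored from demographics
alone (the convention the leave-one-subject-out harness relies on).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SparseFeatureSpec",
    "CrossSpec",
    "one_hot_encode",
    "cross_products",
    "assemble_wide_input",
]


@dataclass(frozen=True)
class SparseFeatureSpec:
    """Vocabularies for the one-hot participant blocks (order is fixed)."""

    subjects: tuple[str, ...]
    sexes: tuple[str, ...] = ("M", "F")
    age_groups: tuple[str, ...] = ("young", "mid", "older")

    def __post_init__(self) -> None:
        for name, vocab in (
            ("subjects", self.subjects),
            ("sexes", self.sexes),
            ("age_groups", self.age_groups),
        ):
            if len(set(vocab)) != len(vocab):
                raise ValueError(f"{name} vocabulary has duplicates")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def total_length(self) -> int:
        """T = S + #sexes + #age bins."""
        return len(self.subjects) + len(self.sexes) + len(self.age_groups)

    @property
    def block_slices(self) -> dict[str, slice]:
        s, x, a = len(self.subjects), len(self.sexes), len(self.age_groups)
        return {
            "subject": slice(0, s),
            "sex": slice(s, s + x),
            "age_group": slice(s + x, s + x + a),
        }

    @classmethod
    def from_profiles(cls, profiles) -> "SparseFeatureSpec":
        """Build the vocabulary from an iterable of subject profiles.

        The subject vocabulary is exactly the profiles seen; the age-group
        vocabulary starts from the canonical study bins (so a held-out
        participant from an unobserved bin still encodes) and appends any
        extra bins the profiles use.
        """
        subjects = []
        ages = list(cls.__dataclass_fields__["age_groups"].default)
        for p in profiles:
            if p.subject_id not in subjects:
                subjects.append(p.subject_id)
            if p.age_group not in ages:
                ages.append(p.age_group)
        return cls(subjects=tuple(subjects), age_groups=tuple(ages))

    @classmethod
    def empty(cls) -> "SparseFeatureSpec":
        """A degenerate spec with no vocab at all (T counts only sex bits)."""
        return cls(subjects=(), sexes=(), age_groups=())


@dataclass(frozen=True)
class CrossSpec:
    """Which one-hot entries each cross feature multiplies.

    ``mask`` is boolean with one row per cross feature and one column per
    one-hot entry; every row must select at least two entries (an empty or
    singleton product is not a cross).
    """

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("cross mask must be 2-D (k x T)")
        if mask.shape[0] and (mask.sum(axis=1) < 2).any():
            bad = int(np.flatnonzero(mask.sum(axis=1) < 2)[0])
            raise ValueError(f"cross feature {bad} selects fewer than 2 entries")
        object.__setattr__(self, "mask", mask)

    @property
    def n_features(self) -> int:
        return self.mask.shape[0]

    @classmethod
    def pairwise(cls, spec: SparseFeatureSpec) -> "CrossSpec":
        """All pairwise crosses between entries of distinct field blocks
        (sex x age, subject x sex, subject x age) — the default."""
        T = spec.total_length
        blocks = spec.block_slices
        pairs = []
        order = [("sex", "age_group"), ("subject", "sex"), ("subject", "age_group")]
        for a, b in order:
            for i in range(blocks[a].start, blocks[a].stop):
                for j in range(blocks[b].start, blocks[b].stop):
                    row = np.zeros(T, dtype=bool)
                    row[i] = row[j] = True
                    pairs.append(row)
        return cls(np.array(pairs, dtype=bool).reshape(len(pairs), T))

    @classmethod
    def none(cls, spec: SparseFeatureSpec) -> "CrossSpec":
        return cls(np.zeros((0, spec.total_length), dtype=bool))


def one_hot_encode(profile, spec: SparseFeatureSpec) -> np.ndarray:
    """Length-T 0/1 vector with one active bit per field block.

    An out-of-vocabulary subject id leaves the subject block all zero; an
    unknown sex or age group is an error (those vocabularies are closed).
    """
    d2 = np.zeros(spec.total_length, dtype=np.float64)
    blocks = spec.block_slices
    if profile.subject_id in spec.subjects:
        d2[blocks["subject"].start + spec.subjects.index(profile.subject_id)] = 1.0
    if spec.sexes:
        if profile.sex not in spec.sexes:
            raise ValueError(f"sex {profile.sex!r} not in vocabulary {spec.sexes}")
        d2[blocks["sex"].start + spec.sexes.index(profile.sex)] = 1.0
    if spec.age_groups:
        if profile.age_group not in spec.age_groups:
            raise ValueError(
                f"age_group {profile.age_group!r} not in vocabulary {spec.age_groups}"
            )
        d2[blocks["age_group"].start + spec.age_groups.index(profile.age_group)] = 1.0
    return d2


def cross_products(d2: np.ndarray, cross: CrossSpec) -> np.ndarray:
    """psi_k = prod over the entries row k selects; AND for 0/1 inputs."""
    d2 = np.asarray(d2, dtype=np.float64)
    if d2.shape[-1] != cross.mask.shape[1]:
        raise ValueError(
            f"d2 has length {d2.shape[-1]} but cross spec expects {cross.mask.shape[1]}"
        )
    if cross.n_features == 0:
        return np.zeros(d2.shape[:-1] + (0,))
    # prod over selected entries == exp of masked log would fail at 0; use
    # where-trick: replace unselected entries by 1 and reduce.
    expanded = np.where(cross.mask, d2[..., None, :], 1.0)
    return expanded.prod(axis=-1)


def assemble_wide_input(
    epoch: np.ndarray,
    d2: np.ndarray,
    dphi: np.ndarray,
    expected_shape: tuple[int, int] = (30, 90),
) -> np.ndarray:
    """Concatenate [flatten(epoch), d2, dphi]; flattening is row-major."""
    epoch = np.asarray(epoch, dtype=np.float64)
    if epoch.shape != expected_shape:
        raise ValueError(f"epoch shape {epoch.shape} != expected {expected_shape}")
    return np.concatenate([epoch.ravel(order="C"), np.asarray(d2), np.asarray(dphi)])
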