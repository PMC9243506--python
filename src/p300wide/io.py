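"""File I/O: EDF/EDF+ and the package's portable container format.

EDF+ reading goes through :func:`mne.io.read_raw_edf`; flash markers travel as
EDF+ annotations with descriptions of the form ``flash/<code>/<line>/<T|N>``.
Because no EDF writer is available as a library dependency, a minimal EDF+C
writer (16-bit samples, one annotations signal) is implemented here; it exists
mainly so synthetic recordings can be exported and the read path exercised.
EDF stores 16-bit integers, so an EDF round trip is exact only up to the
per-channel quantization step; the container round trip is bit-exact.

Container schema (a zip archive, ``schema_version`` 1):

``recording`` kind
    ``meta.json``  — fs, channel_names, subject_id, markers (list of
    {onset_sample, code, line_index, is_target}), kind, schema_version
    ``data.npy``   — float64 array (channels, samples), microvolts

``epochs`` kind
    ``meta.json``  — fs, t_start_ms, t_end_ms, labels, subject_ids, kind,
    schema_version
    ``epochs.npy`` — float64 array (n, channels, samples), microvolts
"""

from __future__ import annotations

import io as _stdio
import json
import zipfile
from pathlib import Path

import numpy as np

from .containers import ContinuousRecording, EpochSet, EventMarker

__all__ = [
    "read_recording",
    "write_recording",
    "read_epochs",
    "write_epochs",
]

_SCHEMA_VERSION = 1
_ANNOT_PREFIX = "flash"


class FormatError(ValueError):
    """A file parsed but did not contain what the format requires."""


# ---------------------------------------------------------------------------
# portable container
# ---------------------------------------------------------------------------

def _write_container(path, meta: dict, arrays: dict) -> None:
    meta = dict(meta, schema_version=_SCHEMA_VERSION)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta))
        for name, arr in arrays.items():
            buf = _stdio.BytesIO()
            np.save(buf, np.ascontiguousarray(arr))
            zf.writestr(f"{name}.npy", buf.getvalue())


def _read_container(path, kind: str, array_names: list[str]):
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            arrays = {n: np.load(_stdio.BytesIO(zf.read(f"{n}.npy"))) for n in array_names}
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: not a valid container file ({exc})") from exc
    if meta.get("kind") != kind:
        raise FormatError(f"{path}: container holds {meta.get('kind')!r}, expected {kind!r}")
    return meta, arrays


def write_epochs(epochs: EpochSet, path) -> None:
    """Write an :class:`EpochSet` to the portable container format (lossless)."""
    _write_container(
        path,
        {
            "kind": "epochs",
            "fs": epochs.fs,
            "t_start_ms": epochs.t_start_ms,
            "t_end_ms": epochs.t_end_ms,
            "labels": [int(v) for v in epochs.labels],
            "subject_ids": [str(s) for s in epochs.subject_ids],
        },
        {"epochs": epochs.epochs},
    )


def read_epochs(path) -> EpochSet:
    """Read an :class:`EpochSet` written by :func:`write_epochs`."""
    meta, arrays = _read_container(path, "epochs", ["epochs"])
    return EpochSet(
        epochs=arrays["epochs"],
        labels=np.asarray(meta["labels"]),
        subject_ids=np.asarray(meta["subject_ids"], dtype=object),
        fs=meta["fs"],
        t_start_ms=meta["t_start_ms"],
        t_end_ms=meta["t_end_ms"],
    )


def _marker_to_dict(m: EventMarker) -> dict:
    return {
        "onset_sample": int(m.onset_sample),
        "code": int(m.code),
        "line_index": int(m.line_index),
        "is_target": bool(m.is_target),
    }


def _write_recording_container(rec: ContinuousRecording, path) -> None:
    _write_container(
        path,
        {
            "kind": "recording",
            "fs": rec.fs,
            "channel_names": list(rec.channel_names),
            "subject_id": str(rec.subject_id),
            "markers": [_marker_to_dict(m) for m in rec.markers],
        },
        {"data": rec.data},
    )


def _read_recording_container(path) -> ContinuousRecording:
    meta, arrays = _read_container(path, "recording", ["data"])
    markers = [EventMarker(**m) for m in meta["markers"]]
    return ContinuousRecording(
        data=arrays["data"],
        fs=meta["fs"],
        channel_names=list(meta["channel_names"]),
        markers=markers,
        subject_id=meta["subject_id"],
    )


# ---------------------------------------------------------------------------
# EDF+
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _marker_annotation(m: EventMarker) -> str:
    return f"{_ANNOT_PREFIX}/{m.code}/{m.line_index}/{'T' if m.is_target else 'N'}"


def _parse_annotation(desc: str, onset_s: float, fs: float) -> EventMarker | None:
    parts = desc.split("/")
    if len(parts) != 4 or parts[0] != _ANNOT_PREFIX:
        return None
    return EventMarker(
        onset_sample=int(round(onset_s * fs)),
        code=int(parts[1]),
        line_index=int(parts[2]),
        is_target=parts[3] == "T",
    )


def _write_recording_edf(rec: ContinuousRecording, path, unit: str = "uV") -> None:
    """Write an EDF+C file: 16-bit channels plus one EDF Annotations signal.

    The recording is padded with zeros to a whole number of 1-second data
    records (EDF stores fixed-duration records). ``unit`` selects the
    physical dimension the file declares ("uV" or "mV"); amplitudes are
    converted from the recording's microvolts accordingly, so readers that
    honor the dimension recover the same signal.
    """
    scale_to_unit = {"uV": 1.0, "mV": 1e-3}
    if unit not in scale_to_unit:
        raise ValueError(f"unit must be 'uV' or 'mV', got {unit!r}")
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = rec.data.shape
    n_records = max(1, int(np.ceil(n_samp / fs)))

    # digital scaling per channel; pad the physical range so flat channels work
    data = rec.data * scale_to_unit[unit]
    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    span = np.maximum(phys_max - phys_min, 1e-3)
    phys_min = phys_min - 0.01 * span
    phys_max = phys_max + 0.01 * span
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min[:, None]) * scale[:, None] + dig_min).astype("<i2")
    pad = n_records * fs - n_samp
    if pad:
        zero_dig = np.round((0.0 - phys_min) * scale + dig_min).astype("<i2")
        digital = np.concatenate(
            [digital, np.tile(zero_dig[:, None], (1, pad)).astype("<i2")], axis=1
        )

    # TALs grouped into the record containing each onset
    tals_by_record: dict[int, list[bytes]] = {}
    for m in rec.markers:
        onset_s = m.onset_sample / fs
        r = min(int(onset_s), n_records - 1)
        tal = f"+{onset_s:.7f}\x14{_marker_annotation(m)}\x14\x00".encode("ascii")
        tals_by_record.setdefault(r, []).append(tal)
    annot_bytes_needed = max(
        (sum(map(len, v)) for v in tals_by_record.values()), default=0
    ) + 32  # room for the per-record timestamp TAL
    annot_n_samples = max(64, int(np.ceil(annot_bytes_needed / 2)))

    ns = n_ch + 1
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field(f"X X X {rec.subject_id or 'X'}", 80),
            _edf_field("Startdate 01-JAN-2001 X X X", 80),
            _edf_field("01.01.01", 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(256 * (ns + 1)), 8),
            _edf_field("EDF+C", 44),
            _edf_field(str(n_records), 8),
            _edf_field("1", 8),
            _edf_field(str(ns), 4),
        ]
    )
    labels = [str(c) for c in rec.channel_names] + ["EDF Annotations"]
    per_signal = [
        (labels, 16),
        (["" for _ in range(ns)], 80),  # transducer
        ([unit] * n_ch + [""], 8),  # physical dimension
        ([f"{v:.6g}"[:8] for v in phys_min] + ["-1"], 8),
        ([f"{v:.6g}"[:8] for v in phys_max] + ["1"], 8),
        ([str(dig_min)] * n_ch + [str(dig_min)], 8),
        ([str(dig_max)] * n_ch + [str(dig_max)], 8),
        (["" for _ in range(ns)], 80),  # prefiltering
        ([str(fs)] * n_ch + [str(annot_n_samples)], 8),
        (["" for _ in range(ns)], 32),  # reserved
    ]
    for values, width in per_signal:
        header += b"".join(_edf_field(v, width) for v in values)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes(order="C"))
            annot = f"+{r}\x14\x14\x00".encode("ascii") + b"".join(tals_by_record.get(r, []))
            fh.write(annot.ljust(2 * annot_n_samples, b"\x00"))


def _read_recording_edf(path) -> ContinuousRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data_uv = raw.get_data() * 1e6  # mne returns volts whatever the EDF dimension
    markers = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        m = _parse_annotation(str(desc), float(onset), fs)
        if m is not None:
            markers.append(m)
    subject = ""
    if raw.info.get("subject_info"):
        subject = raw.info["subject_info"].get("last_name") or ""
    return ContinuousRecording(
        data=data_uv,
        fs=fs,
        channel_names=list(raw.ch_names),
        markers=markers,
        subject_id=subject,
    )


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def write_recording(
    rec: ContinuousRecording, path, format: str = "container", edf_unit: str = "uV"
) -> None:
    """Write a recording as ``container`` (lossless) or ``edf`` (16-bit EDF+C)."""
    if format == "container":
        _write_recording_container(rec, path)
    elif format == "edf":
        _write_recording_edf(rec, path, unit=edf_unit)
    else:
        raise ValueError(f"unknown format {format!r}; use 'edf' or 'container'")


def read_recording(path, format: str | None = None) -> ContinuousRecording:
    """Read a continuous recording from EDF(+) or the portable container.

    When ``format`` is None it is inferred from the suffix (``.edf`` → EDF,
    anything else → container). Data is returned in microvolts and markers
    sorted by onset.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "container"
    if format == "edf":
        return _read_recording_edf(path)
    if format == "container":
        return _read_recording_container(path)
    raise ValueError(f"unknown format {format!r}; use 'edf' or 'container'")
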