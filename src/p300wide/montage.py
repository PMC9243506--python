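"""The 30-electrode working montage (10-20 system) and ERP spatial gains."""

from __future__ import annotations

import numpy as np

__all__ = ["DEFAULT_MONTAGE", "default_spatial_weights"]

#: The 30 standard 10-20 electrodes retained for analysis, in fixed order.
DEFAULT_MONTAGE: tuple[str, ...] = (
    "FP1", "FPz", "FP2",
    "F7", "F3", "Fz", "F4", "F8",
    "FC3", "FCz", "FC4",
    "T7", "C3", "Cz", "C4", "T8",
    "CP3", "CPz", "CP4",
    "P7", "P3", "Pz", "P4", "P8",
    "PO5", "POz", "PO6",
    "O1", "Oz", "O2",
)

# P300 topography: maximal over centro-parietal midline, falling off
# frontally and laterally.
_GAIN_BY_LABEL = {
    "Cz": 1.0, "CPz": 1.0, "Pz": 1.0,
    "C3": 0.8, "C4": 0.8, "CP3": 0.8, "CP4": 0.8, "P3": 0.8, "P4": 0.8,
    "FCz": 0.6, "FC3": 0.55, "FC4": 0.55, "POz": 0.7,
    "PO5": 0.5, "PO6": 0.5, "P7": 0.4, "P8": 0.4,
    "Fz": 0.45, "F3": 0.4, "F4": 0.4,
    "O1": 0.35, "Oz": 0.4, "O2": 0.35,
    "T7": 0.3, "T8": 0.3, "F7": 0.3, "F8": 0.3,
    "FP1": 0.25, "FPz": 0.25, "FP2": 0.25,
}


def default_spatial_weights(channel_names) -> np.ndarray:
    """Per-channel ERP gain (1.0 at the centro-parietal maximum)."""
    return np.array([_GAIN_BY_LABEL.get(str(c), 0.25) for c in channel_names], dtype=float)
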