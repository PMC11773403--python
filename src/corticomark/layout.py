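"""Approximate 2D scalp layout for a 63-channel 10-10 electrode set.

Positions are schematic head coordinates (x: left negative / right positive,
y: posterior negative / anterior positive, unit head radius). They are used
only for topography scoring and simulation gains, never for source modelling,
so a simple row/column scheme is sufficient.
"""

from __future__ import annotations

import numpy as np

# anterior-posterior coordinate per electrode row prefix
_ROW_Y = {
    "Fp": 0.85,
    "AF": 0.65,
    "F": 0.45,
    "FT": 0.22,
    "FC": 0.22,
    "T": 0.0,
    "C": 0.0,
    "TP": -0.22,
    "CP": -0.22,
    "P": -0.45,
    "PO": -0.65,
    "O": -0.85,
}

# lateral coordinate per electrode number (odd = left, even = right, z = 0)
_COL_X = {1: 0.15, 2: 0.15, 3: 0.35, 4: 0.35, 5: 0.55, 6: 0.55,
          7: 0.78, 8: 0.78, 9: 0.95, 10: 0.95}

STANDARD_63 = [
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
    "P9", "P10",
]

#: default sensorimotor channels (left M1 / S1 neighbourhood)
SENSORIMOTOR_CHANNELS = ["C3", "C1", "Cz", "FC3", "FC1", "CP3", "CP1"]


def _split_label(label: str) -> tuple[str, str]:
    i = len(label)
    while i > 0 and (label[i - 1].isdigit() or label[i - 1] == "z"):
        i -= 1
    return label[:i], label[i:]


def channel_position(label: str) -> tuple[float, float]:
    """Schematic (x, y) coordinate of one 10-10 electrode label."""
    prefix, suffix = _split_label(label)
    if prefix not in _ROW_Y:
        raise ValueError(f"unknown electrode row prefix in label {label!r}")
    y = _ROW_Y[prefix]
    if suffix == "z" or suffix == "":
        x = 0.0
    else:
        num = int(suffix)
        x = _COL_X[num] * (-1 if num % 2 == 1 else 1)
    return x, y


def positions_for(labels: list[str]) -> np.ndarray:
    """(n, 2) array of schematic positions for the given labels."""
    return np.array([channel_position(lb) for lb in labels], dtype=float)


def sensorimotor_template(labels: list[str],
                          roi: list[str] | None = None,
                          sigma: float = 0.35) -> np.ndarray:
    """Gaussian template topography peaking over the sensorimotor ROI.

    Returns a nonnegative weight per channel, normalised to unit norm, used
    as the reference map when scoring component topographies.
    """
    roi = roi if roi is not None else SENSORIMOTOR_CHANNELS
    pos = positions_for(labels)
    center = positions_for([c for c in roi]).mean(axis=0)
    d2 = ((pos - center) ** 2).sum(axis=1)
    w = np.exp(-d2 / (2.0 * sigma**2))
    return w / np.linalg.norm(w)
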