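"""The 16-lead 10-20 montage and its schematic 2D head layout.

Coordinates are schematic (top view, nose up): x grows to the subject's
right, y to the front, all electrodes inside the unit disc. They support
qualitative topographic maps, not anatomical source localization.
"""

from __future__ import annotations

import numpy as np

#: Channel order used everywhere in the package.
MONTAGE_16: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4",
    "O1", "O2", "F7", "F8", "T3", "T4", "T5", "T6",
)

# Outer ring at radius 0.9 (circumferential electrodes), inner ring at 0.5.
_R_OUT = 0.9
_R_IN = 0.5
_C45 = np.cos(np.pi / 4)

#: label -> (x, y) schematic coordinates.
LAYOUT_16: dict[str, tuple[float, float]] = {
    "Fp1": (-_R_OUT * np.sin(np.pi / 10), _R_OUT * np.cos(np.pi / 10)),
    "Fp2": (+_R_OUT * np.sin(np.pi / 10), _R_OUT * np.cos(np.pi / 10)),
    "F7": (-_R_OUT * np.sin(3 * np.pi / 10), _R_OUT * np.cos(3 * np.pi / 10)),
    "F8": (+_R_OUT * np.sin(3 * np.pi / 10), _R_OUT * np.cos(3 * np.pi / 10)),
    "T3": (-_R_OUT, 0.0),
    "T4": (+_R_OUT, 0.0),
    "T5": (-_R_OUT * np.sin(3 * np.pi / 10), -_R_OUT * np.cos(3 * np.pi / 10)),
    "T6": (+_R_OUT * np.sin(3 * np.pi / 10), -_R_OUT * np.cos(3 * np.pi / 10)),
    "O1": (-_R_OUT * np.sin(np.pi / 10), -_R_OUT * np.cos(np.pi / 10)),
    "O2": (+_R_OUT * np.sin(np.pi / 10), -_R_OUT * np.cos(np.pi / 10)),
    "F3": (-_R_IN * _C45, _R_IN * _C45),
    "F4": (+_R_IN * _C45, _R_IN * _C45),
    "C3": (-_R_IN, 0.0),
    "C4": (+_R_IN, 0.0),
    "P3": (-_R_IN * _C45, -_R_IN * _C45),
    "P4": (+_R_IN * _C45, -_R_IN * _C45),
}

#: Left/right homologous pairs (mirror symmetry in x).
MIRROR_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"), ("F3", "F4"), ("C3", "C4"), ("P3", "P4"),
    ("O1", "O2"), ("F7", "F8"), ("T3", "T4"), ("T5", "T6"),
)


def layout_array(channels: tuple[str, ...] = MONTAGE_16) -> np.ndarray:
    """Return an (n, 2) coordinate array in the given channel order."""
    unknown = [c for c in channels if c not in LAYOUT_16]
    if unknown:
        raise KeyError(f"unknown channel label(s): {unknown}")
    return np.array([LAYOUT_16[c] for c in channels], dtype=float)


def normalize_label(label: str) -> str:
    """Map a case-insensitive channel label onto the canonical montage label."""
    lut = {c.lower(): c for c in MONTAGE_16}
    key = label.strip().lower()
    if key not in lut:
        raise KeyError(f"channel {label!r} is not in the 16-lead montage")
    return lut[key]
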