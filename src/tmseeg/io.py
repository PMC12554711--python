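"""Reading and writing recordings and scale tables.

Recordings travel as EDF or as a plain CSV matrix (channel-label header plus
a metadata comment line). EDF reading goes through mne; EDF writing uses a
minimal 16-bit EDF encoder implemented here, round-trip checked against the
mne reader in the test suite. Channel labels are matched case-insensitively
against the 16-lead montage; channels outside the montage are ignored with a
logged warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .montage import MONTAGE_16
from .recording import EEGRecording
from .synthetic import SCALE_COLUMNS, _validate_scale_table

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- CSV matrix

def write_recording_csv(rec: EEGRecording, path) -> None:
    """Samples x channels CSV with a leading ``#`` metadata line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            f"# subject_id={rec.subject_id} session={rec.session} "
            f"sampling_rate={rec.sampling_rate}\n"
        )
        fh.write(",".join(rec.channels) + "\n")
        np.savetxt(fh, rec.data.T, delimiter=",", fmt="%.6f")


def _select_montage_channels(
    labels: list[str], data: np.ndarray
) -> tuple[tuple[str, ...], np.ndarray]:
    """Case-insensitive montage matching; extra channels dropped with a warning."""
    lut = {c.lower(): c for c in MONTAGE_16}
    keep_idx, keep_labels = [], []
    for i, lab in enumerate(labels):
        key = lab.strip().lower()
        if key in lut:
            keep_idx.append(i)
            keep_labels.append(lut[key])
        else:
            logger.warning("ignoring channel %r: not in the 16-lead montage", lab)
    if not keep_idx:
        raise ParameterError("no montage channels found in the file")
    # reorder into canonical montage order
    order = sorted(range(len(keep_labels)), key=lambda j: MONTAGE_16.index(keep_labels[j]))
    keep_idx = [keep_idx[j] for j in order]
    keep_labels = [keep_labels[j] for j in order]
    return tuple(keep_labels), data[keep_idx]


def read_recording_csv(path) -> EEGRecording:
    path = Path(path)
    with open(path) as fh:
        meta_line = fh.readline()
        if not meta_line.startswith("#"):
            raise ParameterError(f"{path}: first line must be a '# key=value ...' metadata line")
        meta = dict(item.split("=", 1) for item in meta_line[1:].split())
        frame = pd.read_csv(fh)
    try:
        subject_id = meta["subject_id"]
        session = meta["session"]
        fs = float(meta["sampling_rate"])
    except KeyError as exc:
        raise ParameterError(f"{path}: metadata line missing {exc}") from exc
    channels, data = _select_montage_channels(list(frame.columns), frame.to_numpy(dtype=float).T)
    return EEGRecording(subject_id, session, fs, data, channels)


# ----------------------------------------------------------------------- EDF

def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_recording_edf(rec: EEGRecording, path) -> None:
    """Write a recording as 16-bit EDF (one 1-s data record per second).

    Requires an integer sampling rate; the trailing partial second is
    truncated. Physical units are µV with a symmetric physical range.
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ParameterError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record, per signal
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ParameterError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_records * spr]
    ns = rec.n_channels

    phys_max = float(np.max(np.abs(data)))
    phys_max = max(phys_max, 1e-6) * 1.000001
    dig_min, dig_max = -32767, 32767

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field(f"subject_id={rec.subject_id}", 80),
            _edf_field(f"session={rec.session}", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (1 + ns), 8),
            _edf_field("", 44),
            _edf_field(n_records, 8),
            _edf_field(1, 8),
            _edf_field(ns, 4),
        ]
    )
    sig_header = b"".join(
        [
            b"".join(_edf_field(f"EEG {c}", 16) for c in rec.channels),
            b"".join(_edf_field("", 80) for _ in range(ns)),
            b"".join(_edf_field("uV", 8) for _ in range(ns)),
            b"".join(_edf_field(f"{-phys_max:.6g}"[:8], 8) for _ in range(ns)),
            b"".join(_edf_field(f"{phys_max:.6g}"[:8], 8) for _ in range(ns)),
            b"".join(_edf_field(dig_min, 8) for _ in range(ns)),
            b"".join(_edf_field(dig_max, 8) for _ in range(ns)),
            b"".join(_edf_field("", 80) for _ in range(ns)),
            b"".join(_edf_field(spr, 8) for _ in range(ns)),
            b"".join(_edf_field("", 32) for _ in range(ns)),
        ]
    )
    # EDF scales linearly between the printed physical and digital ranges;
    # re-derive the slope from the 8-char rounded header values so the
    # round-trip error is pure 16-bit quantization.
    pmin_r = float(f"{-phys_max:.6g}"[:8])
    pmax_r = float(f"{phys_max:.6g}"[:8])
    scale = (dig_max - dig_min) / (pmax_r - pmin_r)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for rec_i in range(n_records):
            block = data[:, rec_i * spr : (rec_i + 1) * spr]
            dig = np.clip(np.rint((block - pmin_r) * scale) + dig_min, dig_min, dig_max)
            fh.write(dig.astype("<i2").tobytes())


def read_recording_edf(path, subject_id: str | None = None, session: str | None = None) -> EEGRecording:
    """Read an EDF recording via mne; montage channels only, data in µV.

    ``subject_id``/``session`` default to the values stored in the EDF
    patient/recording-id fields by :func:`write_recording_edf`, falling back
    to the file stem and ``"pre"``.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = [lab.removeprefix("EEG ").strip() for lab in raw.ch_names]
    data_uv = raw.get_data() * 1e6
    channels, data = _select_montage_channels(labels, data_uv)
    if subject_id is None or session is None:
        with open(path, "rb") as fh:
            fh.seek(8)
            patient = fh.read(80).decode("ascii", "replace").strip()
            recording = fh.read(80).decode("ascii", "replace").strip()
        if subject_id is None:
            subject_id = patient.removeprefix("subject_id=") or Path(path).stem
        if session is None:
            session = recording.removeprefix("session=") if recording.startswith("session=") else "pre"
    return EEGRecording(subject_id, session, raw.info["sfreq"], data, channels)


def read_recording(path, **kwargs) -> EEGRecording:
    """Dispatch on extension: ``.edf`` via mne, anything else as CSV."""
    if str(path).lower().endswith(".edf"):
        return read_recording_edf(path, **kwargs)
    return read_recording_csv(path)


# --------------------------------------------------------------- scale table

def write_scale_table(table: pd.DataFrame, path) -> None:
    table[list(SCALE_COLUMNS)].to_csv(path, index=False)


def read_scale_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _validate_scale_table(df)
    return df
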