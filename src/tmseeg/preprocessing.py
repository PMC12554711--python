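"""Filtering, epoching, artifact screening, and canonical band decomposition.

The cleaning chain mirrors standard resting-EEG practice: a broadband
zero-phase band-pass (default 0.5-45 Hz), segmentation into 1-s windows,
amplitude-threshold epoch rejection, and per-band zero-phase filtering into
the five canonical bands (delta/theta/alpha/beta/gamma).

Band filtering operates on the concatenated clean signal rather than on
individual 1-s epochs: a 1-s delta epoch holds only 1-4 cycles, so per-epoch
filtering would be dominated by edge transients. The 1-s grid serves artifact
screening, not spectral estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ParameterError
from .recording import EEGRecording, EpochedEEG


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ParameterError(f"band {self.name}: low must be < high")


#: The five canonical EEG bands. Shared edges (4, 8, 13, 30 Hz) belong to the
#: upper band; gamma is closed at the 45 Hz global low-pass edge.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)

BAND_BY_NAME: dict[str, BandDefinition] = {b.name: b for b in CANONICAL_BANDS}

#: Default broadband passband: the nominal 0-45 Hz analysis range with a
#: 0.5 Hz high-pass replacing the DC edge (a true 0 Hz passband keeps slow
#: drift that corrupts entropy and moment features).
DEFAULT_LOW = 0.5
DEFAULT_HIGH = 45.0
_FILTER_ORDER = 4


def _sos(low: float, high: float, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if not 0 <= low < high:
        raise ParameterError(f"need 0 <= low < high, got [{low}, {high}]")
    if high >= nyq:
        raise ParameterError(f"high edge {high} Hz >= Nyquist {nyq} Hz")
    if low <= 0:
        return signal.butter(_FILTER_ORDER, high, btype="lowpass", fs=fs, output="sos")
    return signal.butter(_FILTER_ORDER, [low, high], btype="bandpass", fs=fs, output="sos")


def filter_array(data: np.ndarray, low: float, high: float, fs: float) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a channels x samples array."""
    sos = _sos(low, high, fs)
    return signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def bandpass_filter(
    rec: EEGRecording, low: float = DEFAULT_LOW, high: float = DEFAULT_HIGH
) -> EEGRecording:
    """Zero-phase 4th-order Butterworth band-pass, applied forward-backward.

    Returns a new recording of identical shape; passband gain is flat within
    ~1 dB and attenuation exceeds 20 dB one octave outside the edges.
    """
    filtered = filter_array(rec.data, low, high, rec.sampling_rate)
    return EEGRecording(rec.subject_id, rec.session, rec.sampling_rate, filtered, rec.channels)


def segment_epochs(rec: EEGRecording, epoch_length: float = 1.0) -> EpochedEEG:
    """Cut a recording into non-overlapping fixed-length epochs.

    The trailing remainder shorter than one epoch is discarded; every epoch
    starts out retained.
    """
    if epoch_length <= 0:
        raise ParameterError("epoch_length must be positive")
    n_samp = int(round(epoch_length * rec.sampling_rate))
    n_epochs = rec.n_samples // n_samp
    if n_epochs < 1:
        raise ParameterError(
            f"recording of {rec.duration:.3g} s is shorter than one {epoch_length} s epoch"
        )
    trimmed = rec.data[:, : n_epochs * n_samp]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, n_samp).transpose(1, 0, 2)
    return EpochedEEG(
        subject_id=rec.subject_id,
        session=rec.session,
        sampling_rate=rec.sampling_rate,
        epoch_length=epoch_length,
        channels=rec.channels,
        epochs=epochs.copy(),
        retained_mask=np.ones(n_epochs, dtype=bool),
    )


def reject_artifacts(ep: EpochedEEG, amplitude_threshold_uv: float = 100.0) -> EpochedEEG:
    """Flag epochs whose peak absolute amplitude on any channel exceeds the threshold.

    Amplitude-threshold screening stands in for manual ICA cleaning; data are
    flagged, never modified.
    """
    if amplitude_threshold_uv <= 0:
        raise ParameterError("amplitude_threshold_uv must be positive")
    peak = np.abs(ep.epochs).max(axis=(1, 2))
    mask = ep.retained_mask & (peak <= amplitude_threshold_uv)
    return EpochedEEG(
        ep.subject_id, ep.session, ep.sampling_rate, ep.epoch_length,
        ep.channels, ep.epochs, mask,
    )


def band_decompose(ep: EpochedEEG, band: BandDefinition) -> EpochedEEG:
    """Band-limit the retained signal to one canonical band.

    Retained epochs are concatenated per channel, zero-phase filtered to
    [low, high), and re-segmented on the same epoch grid. The output covers
    the retained epochs only (all marked retained): epochs dropped by
    artifact screening have no counterpart in the concatenated signal.
    """
    if ep.n_retained == 0:
        raise ParameterError("no retained epochs to decompose")
    cont = ep.concatenated()
    filtered = filter_array(cont, band.low, band.high, ep.sampling_rate)
    n_samp = int(round(ep.epoch_length * ep.sampling_rate))
    n_epochs = filtered.shape[1] // n_samp
    epochs = (
        filtered[:, : n_epochs * n_samp]
        .reshape(filtered.shape[0], n_epochs, n_samp)
        .transpose(1, 0, 2)
        .copy()
    )
    return EpochedEEG(
        ep.subject_id, ep.session, ep.sampling_rate, ep.epoch_length,
        ep.channels, epochs, np.ones(n_epochs, dtype=bool),
    )


def preprocess_recording(
    rec: EEGRecording,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
    epoch_length: float = 1.0,
    amplitude_threshold_uv: float = 100.0,
) -> EpochedEEG:
    """Full cleaning chain: band-pass -> epoch -> amplitude screening."""
    return reject_artifacts(
        segment_epochs(bandpass_filter(rec, low, high), epoch_length),
        amplitude_threshold_uv,
    )
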