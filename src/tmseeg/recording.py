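"""Core in-memory containers: a single-session EEG recording and epoched data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .montage import MONTAGE_16

SESSIONS = ("pre", "post")


@dataclass
class EEGRecording:
    """One subject/session multichannel recording, channels x samples, in µV.

    Channels follow the 16-lead 10-20 montage unless the caller supplies a
    different (unique, montage-valid) ordering.
    """

    subject_id: str
    session: str
    sampling_rate: float
    data: np.ndarray
    channels: tuple[str, ...] = field(default=MONTAGE_16)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.session not in SESSIONS:
            raise ParameterError(f"session must be one of {SESSIONS}, got {self.session!r}")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        if self.data.ndim != 2:
            raise ParameterError("data must be a 2-D channels x samples array")
        if len(self.channels) != self.data.shape[0]:
            raise ParameterError(
                f"{len(self.channels)} channel labels for {self.data.shape[0]} data rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ParameterError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class EpochedEEG:
    """Fixed-length non-overlapping epochs cut from one recording.

    ``epochs`` is epoch x channel x sample; ``retained_mask`` flags the epochs
    that survived artifact screening (data itself is never altered by
    screening, only flagged).
    """

    subject_id: str
    session: str
    sampling_rate: float
    epoch_length: float
    channels: tuple[str, ...]
    epochs: np.ndarray
    retained_mask: np.ndarray

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.retained_mask = np.asarray(self.retained_mask, dtype=bool)
        if self.epochs.ndim != 3:
            raise ParameterError("epochs must be epoch x channel x sample")
        n_samp = int(round(self.epoch_length * self.sampling_rate))
        if self.epochs.shape[2] != n_samp:
            raise ParameterError(
                f"epoch sample count {self.epochs.shape[2]} != epoch_length*sampling_rate {n_samp}"
            )
        if self.retained_mask.shape != (self.epochs.shape[0],):
            raise ParameterError("retained_mask length must equal the epoch count")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_retained(self) -> int:
        return int(self.retained_mask.sum())

    def concatenated(self) -> np.ndarray:
        """Retained epochs joined back into a channels x samples array."""
        kept = self.epochs[self.retained_mask]
        if kept.size == 0:
            return np.empty((len(self.channels), 0))
        return np.concatenate(list(kept), axis=1)
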