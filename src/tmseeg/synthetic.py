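"""Synthetic pre/post resting-EEG cohorts with known planted structure.

The generator emulates 5-minute awake closed-eye recordings: per channel,
band-limited sinusoidal oscillations (one carrier per band, frequency drawn
uniformly inside the band and fixed per subject across sessions) ride on
1/f^alpha background noise. A cohort plants a treatment effect: each
subject's post-session amplitude of one (band, channel) is scaled by
``1 + effect_size * delta_score``, where ``delta_score`` is that subject's
(after - before) change on the target scale. Downstream correlation and
prognosis machinery can then be validated against ground truth.

The sign convention is delta = after - before everywhere; improvements on
PSQI/ISI are therefore negative deltas.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CohortIntegrityError, FixtureIntegrityError, ParameterError
from .montage import MONTAGE_16
from .preprocessing import BAND_BY_NAME
from .recording import EEGRecording

SCALE_RANGES = {"PSQI": (0, 21), "ISI": (0, 28)}

SCALE_COLUMNS = ("subject_id", "age", "psqi_before", "isi_before", "psqi_after", "isi_after")

#: Default per-band oscillation amplitudes (µV), alpha-dominant as in awake
#: closed-eye recordings.
DEFAULT_BAND_AMPLITUDES = {
    "delta": 8.0,
    "theta": 6.0,
    "alpha": 20.0,
    "beta": 5.0,
    "gamma": 2.0,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    ``effect_size`` is the fractional post-vs-pre amplitude change of
    ``effect_band`` at ``effect_channel`` per unit of score change on
    ``effect_scale``; ``score_change_mean``/``score_change_sd`` parameterize
    the normal draw of per-subject (after - before) changes, which are
    rounded to integers and clipped to the instrument range.
    """

    n_subjects: int = 15
    sampling_rate: float = 250.0
    duration: float = 300.0
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    noise_exponent: float = 1.0
    noise_scale: float = 10.0
    effect_channel: str = "P3"
    effect_band: str = "alpha"
    effect_scale: str = "PSQI"
    effect_size: float = 0.0
    score_change_mean: float = -4.0
    score_change_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate < 100:
            raise ParameterError("sampling_rate must be >= 100 Hz")
        if self.duration <= 0:
            raise ParameterError("duration must be positive")
        if self.effect_channel not in MONTAGE_16:
            raise ParameterError(f"effect_channel {self.effect_channel!r} not in montage")
        if self.effect_band not in BAND_BY_NAME:
            raise ParameterError(f"effect_band {self.effect_band!r} not a canonical band")
        if self.effect_scale not in SCALE_RANGES:
            raise ParameterError("effect_scale must be 'PSQI' or 'ISI'")
        unknown = set(self.band_amplitudes) - set(BAND_BY_NAME)
        if unknown:
            raise ParameterError(f"unknown band name(s) in band_amplitudes: {sorted(unknown)}")


def load_study_scores() -> pd.DataFrame:
    """Return the packaged 15-subject scale table (age, PSQI and ISI pre/post).

    The fixture is integrity-checked on load: 15 complete rows, integer
    scores within instrument ranges.
    """
    ref = importlib.resources.files("tmseeg.data").joinpath("table1_scores.csv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    _validate_scale_table(df, n_expected=15)
    return df


def _validate_scale_table(df: pd.DataFrame, n_expected: int | None = None) -> None:
    missing = set(SCALE_COLUMNS) - set(df.columns)
    if missing:
        raise FixtureIntegrityError(f"scale table missing columns: {sorted(missing)}")
    if df[list(SCALE_COLUMNS)].isna().any().any():
        raise FixtureIntegrityError("scale table contains missing values")
    if n_expected is not None and len(df) != n_expected:
        raise FixtureIntegrityError(f"expected {n_expected} rows, found {len(df)}")
    for scale, (lo, hi) in SCALE_RANGES.items():
        for when in ("before", "after"):
            col = f"{scale.lower()}_{when}"
            vals = df[col]
            if (vals < lo).any() or (vals > hi).any():
                raise FixtureIntegrityError(f"{col} outside instrument range [{lo}, {hi}]")


def _subject_rng(config: SyntheticConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, subject_index]))


def _session_rng(config: SyntheticConfig, subject_index: int, session: str) -> np.random.Generator:
    code = 0 if session == "pre" else 1
    return np.random.default_rng(np.random.SeedSequence([config.seed, subject_index, code]))


def _one_over_f_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, fs: float,
    exponent: float, scale: float,
) -> np.ndarray:
    """Gaussian noise spectrally shaped to S(f) ~ 1/f^exponent, RMS = scale."""
    if scale == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)  # amplitude ~ f^(-a/2) => power ~ f^-a
    shaped = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    rms = shaped.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return shaped / rms * scale


def generate_recording(
    config: SyntheticConfig,
    subject_id: str,
    session: str,
    band_amplitude_overrides: dict[str, dict[str, float]] | None = None,
    subject_index: int | None = None,
) -> EEGRecording:
    """Simulate one subject/session recording.

    Each channel is a sum over bands of ``amplitude * sin(2*pi*f*t + phi)``
    with per-channel carrier frequency and phase (fixed per subject across
    sessions) plus 1/f^alpha noise (independent per session). The optional
    ``band_amplitude_overrides`` maps band name -> {channel -> amplitude} and
    is how a cohort plants its post-treatment effect.

    Deterministic given (config.seed, subject, session).
    """
    if subject_index is None:
        # stable fallback: derive an index from the label
        subject_index = abs(hash(subject_id)) % (2**31)
    overrides = band_amplitude_overrides or {}
    unknown = set(overrides) - set(BAND_BY_NAME)
    if unknown:
        raise ParameterError(f"unknown band name(s) in overrides: {sorted(unknown)}")

    fs = config.sampling_rate
    n_samples = int(round(config.duration * fs))
    n_ch = len(MONTAGE_16)
    t = np.arange(n_samples) / fs

    subj_rng = _subject_rng(config, subject_index)
    data = np.zeros((n_ch, n_samples))
    # One draw per (band, channel), consumed in a fixed order so pre/post share
    # identical carriers and phases.
    for band in sorted(config.band_amplitudes):
        base_amp = config.band_amplitudes[band]
        b = BAND_BY_NAME[band]
        freqs = subj_rng.uniform(b.low, b.high, size=n_ch)
        phases = subj_rng.uniform(0, 2 * np.pi, size=n_ch)
        amps = np.full(n_ch, base_amp)
        for ch, amp in overrides.get(band, {}).items():
            if ch not in MONTAGE_16:
                raise ParameterError(f"override channel {ch!r} not in montage")
            amps[MONTAGE_16.index(ch)] = amp
        data += amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])

    sess_rng = _session_rng(config, subject_index, session)
    data += _one_over_f_noise(
        sess_rng, n_ch, n_samples, fs, config.noise_exponent, config.noise_scale
    )
    return EEGRecording(subject_id, session, fs, data, MONTAGE_16)


def _draw_scores(
    rng: np.random.Generator, scale: str, delta: int
) -> tuple[int, int]:
    """Draw a plausible insomnia baseline and apply the planted change."""
    lo, hi = SCALE_RANGES[scale]
    if scale == "PSQI":
        before = int(rng.integers(9, 20))
    else:
        before = int(rng.integers(8, 29))
    after = int(np.clip(before + delta, lo, hi))
    return before, after


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[tuple[EEGRecording, EEGRecording]], pd.DataFrame]:
    """Simulate a full pre/post cohort with a planted amplitude-score link.

    For each subject a score change ``delta`` is drawn (normal, rounded,
    clipped to the instrument range); the post-session amplitude of
    ``effect_band`` at ``effect_channel`` is the pre amplitude times
    ``1 + effect_size * delta``. Returns the recording pairs and the scale
    table. Deterministic given ``config.seed``.
    """
    if config.n_subjects < 3:
        raise ParameterError("n_subjects must be >= 3")
    cohort_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10**9]))
    base_amp = config.band_amplitudes.get(config.effect_band, 0.0)

    pairs: list[tuple[EEGRecording, EEGRecording]] = []
    rows = []
    for i in range(config.n_subjects):
        sid = f"S{i + 1:02d}"
        raw_delta = cohort_rng.normal(config.score_change_mean, config.score_change_sd)
        delta = int(np.rint(raw_delta))
        eff_before, eff_after = _draw_scores(cohort_rng, config.effect_scale, delta)
        delta = eff_after - eff_before  # clipping may shrink the planted change
        other = "ISI" if config.effect_scale == "PSQI" else "PSQI"
        other_delta = int(np.rint(cohort_rng.normal(config.score_change_mean, config.score_change_sd)))
        oth_before, oth_after = _draw_scores(cohort_rng, other, other_delta)
        age = int(cohort_rng.integers(18, 66))

        multiplier = 1.0 + config.effect_size * delta
        if multiplier <= 0:
            raise ParameterError(
                f"planted effect makes {config.effect_band}@{config.effect_channel} "
                f"amplitude non-positive (multiplier {multiplier:.3g} for subject {sid})"
            )
        overrides = {config.effect_band: {config.effect_channel: base_amp * multiplier}}
        pre = generate_recording(config, sid, "pre", subject_index=i)
        post = generate_recording(config, sid, "post", overrides, subject_index=i)
        pairs.append((pre, post))

        scores = {
            f"{config.effect_scale.lower()}_before": eff_before,
            f"{config.effect_scale.lower()}_after": eff_after,
            f"{other.lower()}_before": oth_before,
            f"{other.lower()}_after": oth_after,
        }
        rows.append({"subject_id": sid, "age": age, **scores})

    table = pd.DataFrame(rows)[list(SCALE_COLUMNS)]
    _validate_scale_table(table)
    if len(pairs) != len(table):
        raise CohortIntegrityError("recording pairs and scale rows disagree")
    return pairs, table


def small_test_config(**kwargs) -> SyntheticConfig:
    """A scaled-down configuration for fast simulation studies (short
    recordings, defaults otherwise). Keyword overrides are applied on top."""
    base = SyntheticConfig(duration=20.0)
    return replace(base, **kwargs)
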