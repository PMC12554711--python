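"""Band-wise EEG feature extraction: three entropies, Welch band power, and
four distribution moments, over the 8-feature x 5-band x 16-channel grid.

An *indicator* is a (feature, band) pair; with 8 features and 5 canonical
bands there are 40 indicators, each evaluated at every montage channel.

Entropy conventions
-------------------
* Approximate entropy: Pincus ApEn(m, r) = Phi_m - Phi_{m+1}, self-matches
  included, Chebyshev distance, natural log.
* Sample entropy: Richman-Moorman SampEn(m, r) = -ln(A/B), self-matches
  excluded; undefined (NaN) when no template pair matches.
* Permutation entropy: Shannon entropy of Bandt-Pompe ordinal-pattern
  frequencies, ties broken by order of appearance, normalized by ln(order!).

The tolerance r is an *absolute* amplitude for the low-level functions; the
table extractor recomputes it per (band, channel) as ``r * SD`` of that
band-limited signal, since band-limited amplitudes differ by orders of
magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .errors import CohortIntegrityError, ParameterError
from .preprocessing import CANONICAL_BANDS, BandDefinition, band_decompose
from .recording import EpochedEEG

FEATURE_NAMES = ("ApEn", "SampEn", "PE", "PSD", "median", "mean", "skewness", "kurtosis")


@dataclass(frozen=True)
class FeatureParams:
    """Tunable parameters of the feature extractor.

    ``m`` and ``r`` are the embedding dimension and tolerance fraction (of
    the signal SD) shared by ApEn and SampEn; ``pe_order``/``pe_delay`` the
    ordinal pattern length and embedding delay; ``welch_window`` (seconds)
    and ``welch_overlap`` (fraction) the Welch segmentation. Entropies are
    evaluated on at most ``entropy_max_samples`` leading samples of the
    band-limited signal (quadratic cost); band power and moments use the full
    signal. ``per_epoch_mean`` switches to computing every feature per
    retained epoch and averaging, for sensitivity analysis.
    """

    m: int = 2
    r: float = 0.2
    pe_order: int = 3
    pe_delay: int = 1
    welch_window: float = 2.0
    welch_overlap: float = 0.5
    entropy_max_samples: int = 2500
    per_epoch_mean: bool = False

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ParameterError("m must be >= 1")
        if self.r <= 0:
            raise ParameterError("r must be positive")
        if self.pe_order < 2:
            raise ParameterError("pe_order must be >= 2")
        if self.pe_delay < 1:
            raise ParameterError("pe_delay must be >= 1")
        if not 0 <= self.welch_overlap < 1:
            raise ParameterError("welch_overlap must be in [0, 1)")


@dataclass
class Spectrum:
    """A one-sided power spectral density estimate (µV²/Hz on a Hz grid)."""

    frequencies: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ParameterError("frequency grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ParameterError("spectral density must be non-negative")

    @property
    def total_power(self) -> float:
        """Average signal power (µV²): integral of the density over the grid."""
        return float(np.trapezoid(self.density, self.frequencies))


def _match_matrices(x: np.ndarray, m: int, r_abs: float) -> tuple[np.ndarray, np.ndarray]:
    """Boolean Chebyshev-match matrices at embedding dimensions m and m+1.

    ``B_k[i, j]`` is True when the k-length templates starting at i and j
    agree within r_abs in every coordinate (max-norm). B_{k} has shape
    (n-k+1, n-k+1); self-matches lie on the diagonal. Both matrices derive
    from a single n x n scalar-difference comparison, which is what makes
    the grid extraction tractable.
    """
    b1 = np.abs(x[:, None] - x[None, :]) <= r_abs
    bk = b1
    for k in range(1, m):
        bk = bk[:-1, :-1] & b1[k:, k:]
    bk1 = bk[:-1, :-1] & b1[m:, m:]
    return bk, bk1


def approximate_entropy(x: np.ndarray, m: int = 2, r_abs: float | None = None) -> float:
    """Pincus approximate entropy ApEn(m, r) with an absolute tolerance.

    Counts include the self-match, distances are Chebyshev, logs natural.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise ParameterError(f"series of length {n} too short for m={m}")
    if r_abs is None or r_abs <= 0:
        raise ParameterError("r_abs must be a positive absolute tolerance")
    bm, bm1 = _match_matrices(x, m, r_abs)
    phi_m = float(np.mean(np.log(bm.mean(axis=1))))
    phi_m1 = float(np.mean(np.log(bm1.mean(axis=1))))
    return phi_m - phi_m1


def sample_entropy(x: np.ndarray, m: int = 2, r_abs: float | None = None) -> float:
    """Richman-Moorman sample entropy -ln(A/B); NaN when undefined (B or A = 0)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise ParameterError(f"series of length {n} too short for m={m}")
    if r_abs is None or r_abs <= 0:
        raise ParameterError("r_abs must be a positive absolute tolerance")
    bm, bm1 = _match_matrices(x, m, r_abs)
    # Only the n - m templates with an (m+1)-th continuation sample count.
    # Matrices are symmetric with an all-True diagonal, so the unordered
    # off-diagonal pair count is (total - diagonal) / 2.
    bm = bm[: n - m, : n - m]
    b = (int(bm.sum()) - bm.shape[0]) // 2
    a = (int(bm1.sum()) - bm1.shape[0]) // 2
    if b == 0 or a == 0:
        return float("nan")
    return float(-np.log(a / b))


def permutation_entropy(
    x: np.ndarray, order: int = 3, delay: int = 1, normalized: bool = True
) -> float:
    """Bandt-Pompe permutation entropy of the ordinal-pattern distribution.

    Ties are broken by order of appearance (stable sort). Normalization
    divides by ln(order!) so the result lies in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    span = (order - 1) * delay
    if n < span + 2:
        raise ParameterError(f"series of length {n} too short for order={order}, delay={delay}")
    idx = np.arange(n - span)[:, None] + np.arange(order)[None, :] * delay
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    if normalized:
        h /= math.log(math.factorial(order))
    return h


def welch_spectrum(
    x: np.ndarray,
    sampling_rate: float,
    welch_window: float = 2.0,
    welch_overlap: float = 0.5,
) -> Spectrum:
    """Welch averaged modified periodogram (Hann taper, one-sided density).

    The integrated density approximates the signal variance (Parseval).
    Accepts a 1-D signal or a channels x samples array (last axis = time);
    a 2-D input yields a stacked density array in the returned Spectrum.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(welch_window * sampling_rate))
    if nperseg < 2 or x.shape[-1] < nperseg:
        raise ParameterError(
            f"signal of {x.shape[-1]} samples shorter than the {nperseg}-sample Welch window"
        )
    noverlap = int(round(welch_overlap * nperseg))
    freqs, dens = sps.welch(
        x, fs=sampling_rate, window="hann", nperseg=nperseg, noverlap=noverlap, axis=-1
    )
    return Spectrum(freqs, dens)


def band_power(spectrum: Spectrum, band: BandDefinition) -> float | np.ndarray:
    """Trapezoidal integral of the density over [low, high) (µV²)."""
    f = spectrum.frequencies
    if band.low > f[-1] or band.high < f[0]:
        raise ParameterError(f"band [{band.low}, {band.high}) outside the spectrum grid")
    mask = (f >= band.low) & (f < band.high)
    if mask.sum() < 2:
        return 0.0 if spectrum.density.ndim == 1 else np.zeros(spectrum.density.shape[0])
    out = np.trapezoid(spectrum.density[..., mask], f[mask], axis=-1)
    return float(out) if out.ndim == 0 else out


def moment_features(x: np.ndarray) -> tuple[float, float, float, float]:
    """(median, mean, skewness, excess kurtosis) of a series.

    Skewness is the biased Fisher-Pearson population moment ratio; kurtosis
    is excess kurtosis (0 for a normal distribution). Both are NaN on a
    zero-variance series.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ParameterError("need at least 4 samples for moment features")
    med = float(np.median(x))
    mean = float(np.mean(x))
    if np.std(x) == 0:
        return med, mean, float("nan"), float("nan")
    return med, mean, float(stats.skew(x, bias=True)), float(stats.kurtosis(x, fisher=True, bias=True))


def _entropy_block(x: np.ndarray, params: FeatureParams) -> tuple[float, float, float]:
    seg = x[: params.entropy_max_samples]
    sd = float(np.std(seg))
    if sd == 0 or seg.size < max(params.m + 2, (params.pe_order - 1) * params.pe_delay + 2):
        return float("nan"), float("nan"), float("nan")
    r_abs = params.r * sd
    n, m = seg.size, params.m
    bm, bm1 = _match_matrices(seg, m, r_abs)
    apen = float(np.mean(np.log(bm.mean(axis=1))) - np.mean(np.log(bm1.mean(axis=1))))
    bms = bm[: n - m, : n - m]
    b = (int(bms.sum()) - bms.shape[0]) // 2
    a = (int(bm1.sum()) - bm1.shape[0]) // 2
    sampen = float("nan") if (a == 0 or b == 0) else float(-np.log(a / b))
    pe = permutation_entropy(seg, params.pe_order, params.pe_delay)
    return apen, sampen, pe


def _moments_block(sig: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized (median, mean, skewness, excess kurtosis) per channel.

    Same biased population-moment conventions as :func:`moment_features`.
    """
    med = np.median(sig, axis=1)
    mean = sig.mean(axis=1)
    d = sig - mean[:, None]
    m2 = np.mean(d * d, axis=1)
    m3 = np.mean(d * d * d, axis=1)
    m4 = np.mean(d * d * d * d, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(m2 > 0, m3 / m2**1.5, np.nan)
        kurt = np.where(m2 > 0, m4 / m2**2 - 3.0, np.nan)
    return med, mean, skew, kurt


def _features_for_band_signal(
    sig: np.ndarray, fs: float, band: BandDefinition, params: FeatureParams
) -> dict[str, np.ndarray]:
    """Per-channel features of one band-limited channels x samples signal."""
    n_ch = sig.shape[0]
    out = {name: np.full(n_ch, np.nan) for name in FEATURE_NAMES}
    window = min(params.welch_window, sig.shape[1] / fs)
    spec = welch_spectrum(sig, fs, window, params.welch_overlap)
    out["PSD"] = np.asarray(band_power(spec, band), dtype=float)
    out["median"], out["mean"], out["skewness"], out["kurtosis"] = _moments_block(sig)
    for ch in range(n_ch):
        out["ApEn"][ch], out["SampEn"][ch], out["PE"][ch] = _entropy_block(sig[ch], params)
    return out


def extract_feature_table(
    cohort_epochs: dict[tuple[str, str], EpochedEEG],
    params: FeatureParams | None = None,
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
) -> pd.DataFrame:
    """Compute the full feature grid for a preprocessed cohort.

    ``cohort_epochs`` maps (subject_id, session) to the cleaned broadband
    EpochedEEG. Every subject must have both a ``pre`` and a ``post``
    session. Features are computed on the concatenated retained band-limited
    signal (or per epoch and averaged when ``params.per_epoch_mean``).

    Returns a long-format table with columns subject_id, session, feature,
    band, channel, value — a complete 8 x len(bands) x 16 grid per
    subject-session; entropies that are undefined on a cell are NaN and are
    excluded pairwise downstream.
    """
    params = params or FeatureParams()
    subjects = sorted({sid for sid, _ in cohort_epochs})
    for sid in subjects:
        if (sid, "pre") not in cohort_epochs or (sid, "post") not in cohort_epochs:
            raise CohortIntegrityError(f"subject {sid} is missing a session")

    rows: list[dict] = []
    for (sid, session), ep in sorted(cohort_epochs.items()):
        for band in bands:
            bd = band_decompose(ep, band)
            if params.per_epoch_mean:
                per_epoch = [
                    _features_for_band_signal(bd.epochs[i], bd.sampling_rate, band, params)
                    for i in range(bd.n_epochs)
                ]
                feats = {
                    name: np.nanmean([d[name] for d in per_epoch], axis=0)
                    for name in FEATURE_NAMES
                }
            else:
                feats = _features_for_band_signal(bd.concatenated(), bd.sampling_rate, band, params)
            for name in FEATURE_NAMES:
                for ch_i, ch in enumerate(ep.channels):
                    rows.append(
                        {
                            "subject_id": sid,
                            "session": session,
                            "feature": name,
                            "band": band.name,
                            "channel": ch,
                            "value": float(feats[name][ch_i]),
                        }
                    )
    return pd.DataFrame(rows)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Serialize a feature table as long-format TSV."""
    table.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
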