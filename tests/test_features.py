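"""Feature extractors against brute-force oracles and analytic expectations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmseeg.errors import CohortIntegrityError, ParameterError
from tmseeg.features import (
    FeatureParams,
    approximate_entropy,
    band_power,
    extract_feature_table,
    moment_features,
    permutation_entropy,
    sample_entropy,
    welch_spectrum,
)
from tmseeg.preprocessing import BAND_BY_NAME

from conftest import FAST_PARAMS, make_cohort

# ----------------------------------------------------------------- oracles


def apen_oracle(x, m, r):
    """Naive O(n^2) Pincus ApEn: self-matches included, Chebyshev, natural log."""
    x = np.asarray(x, float)
    n = len(x)

    def phi(k):
        tpl = [x[i : i + k] for i in range(n - k + 1)]
        return np.mean(
            [np.log(sum(np.max(np.abs(a - b)) <= r for b in tpl) / len(tpl)) for a in tpl]
        )

    return phi(m) - phi(m + 1)


def sampen_oracle(x, m, r):
    """Naive O(n^2) Richman-Moorman SampEn: self-matches excluded."""
    x = np.asarray(x, float)
    n = len(x)
    b = a = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if np.max(np.abs(x[i : i + m] - x[j : j + m])) <= r:
                b += 1
            if np.max(np.abs(x[i : i + m + 1] - x[j : j + m + 1])) <= r:
                a += 1
    return np.nan if (a == 0 or b == 0) else -np.log(a / b)


series_strategy = st.lists(
    st.floats(min_value=-5, max_value=5, allow_nan=False, width=32), min_size=8, max_size=30
)


class TestEntropies:
    def test_apen_matches_oracle_on_worked_series(self):
        x = [1, 2, 3, 1, 2, 3, 1, 2, 3, 1]
        assert approximate_entropy(x, 2, 0.5) == pytest.approx(apen_oracle(x, 2, 0.5), abs=1e-12)

    def test_sampen_zero_for_periodic_series(self):
        x = [1, 2, 3, 1, 2, 3, 1, 2, 3, 1]
        assert sample_entropy(x, 2, 0.5) == pytest.approx(0.0, abs=1e-12)
        assert sample_entropy(x, 2, 0.5) == pytest.approx(sampen_oracle(x, 2, 0.5), abs=1e-12)

    def test_apen_near_zero_for_constant_plus_jitter(self):
        rng = np.random.default_rng(0)
        x = 1.0 + 1e-9 * rng.standard_normal(200)
        assert approximate_entropy(x, 2, 0.5) < 1e-6

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(series_strategy, st.integers(1, 3))
    def test_match_oracles_on_random_series(self, xs, m):
        x = np.asarray(xs)
        r = 0.2 * np.std(x) + 0.05
        assert approximate_entropy(x, m, r) == pytest.approx(apen_oracle(x, m, r), abs=1e-10)
        got, want = sample_entropy(x, m, r), sampen_oracle(x, m, r)
        assert (np.isnan(got) and np.isnan(want)) or got == pytest.approx(want, abs=1e-10)

    def test_regularity_ordering(self):
        """Sinusoid < colored noise < white noise for all three entropies."""
        rng = np.random.default_rng(1)
        n = 1000
        sine = np.sin(2 * np.pi * 10 * np.arange(n) / 250)
        white = rng.standard_normal(n)
        colored = np.convolve(rng.standard_normal(n + 24), np.ones(25) / 25, mode="valid")
        for fn in (approximate_entropy, sample_entropy):
            vals = [fn(x, 2, 0.2 * np.std(x)) for x in (sine, colored, white)]
            assert vals[0] < vals[1] < vals[2], fn.__name__
        pes = [permutation_entropy(x, 3, 1) for x in (sine, colored, white)]
        assert pes[0] < pes[1] < pes[2]

    def test_too_short_series_rejected(self):
        with pytest.raises(ParameterError):
            approximate_entropy([1.0, 2.0], 2, 0.5)
        with pytest.raises(ParameterError):
            sample_entropy([1.0, 2.0, 3.0], 2, 0.5)


class TestPermutationEntropy:
    def test_monotone_series_has_zero_entropy(self):
        assert permutation_entropy(np.arange(50.0), 3, 1) == 0.0

    def test_hand_enumerated_seven_point_example(self):
        # patterns of order 2: 4 ascents, 2 descents -> H(2/3,1/3)/ln2
        x = [4, 7, 9, 10, 6, 11, 3]
        expect = -(2 / 3 * math.log(2 / 3) + 1 / 3 * math.log(1 / 3)) / math.log(2)
        assert permutation_entropy(x, 2, 1) == pytest.approx(expect, abs=1e-4)
        assert expect == pytest.approx(0.9183, abs=1e-4)

    def test_uniform_noise_approaches_max_entropy(self):
        rng = np.random.default_rng(2)
        assert permutation_entropy(rng.uniform(size=10**5), 3, 1) >= 0.99

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.floats(-100, 100, allow_nan=False, width=32), min_size=10, max_size=60))
    def test_bounded_and_monotone_invariant(self, xs):
        x = np.asarray(xs)
        pe = permutation_entropy(x, 3, 1)
        assert 0.0 <= pe <= 1.0 + 1e-12
        # strictly monotone transforms (injective at float precision)
        # preserve ordinal patterns
        assert permutation_entropy(8.0 * x, 3, 1) == pytest.approx(pe, abs=1e-12)
        assert permutation_entropy(x * x * x, 3, 1) == pytest.approx(pe, abs=1e-12)


class TestSpectrum:
    def test_tone_parseval(self):
        fs, a = 250.0, 4.0
        t = np.arange(int(fs * 30)) / fs
        spec = welch_spectrum(a * np.sin(2 * np.pi * 10 * t), fs)
        assert spec.total_power == pytest.approx(a**2 / 2, rel=0.05)

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(250 * 60)) * 3.0
        spec = welch_spectrum(x, 250.0)
        assert spec.total_power == pytest.approx(x.var(), rel=0.10)

    def test_zero_signal_zero_density(self):
        spec = welch_spectrum(np.zeros(2000), 250.0)
        assert np.all(spec.density == 0)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ParameterError):
            welch_spectrum(np.zeros(100), 250.0, welch_window=2.0)

    def test_tone_band_power_localized(self):
        fs = 250.0
        t = np.arange(int(fs * 30)) / fs
        spec = welch_spectrum(10 * np.sin(2 * np.pi * 10 * t), fs)
        alpha = band_power(spec, BAND_BY_NAME["alpha"])
        delta = band_power(spec, BAND_BY_NAME["delta"])
        assert alpha == pytest.approx(spec.total_power, rel=0.05)
        assert delta < 0.01 * alpha

    def test_two_tone_band_symmetry(self):
        fs = 250.0
        t = np.arange(int(fs * 30)) / fs
        x = 5 * np.sin(2 * np.pi * 2 * t) + 5 * np.sin(2 * np.pi * 20 * t)
        spec = welch_spectrum(x, fs)
        assert band_power(spec, BAND_BY_NAME["delta"]) == pytest.approx(
            band_power(spec, BAND_BY_NAME["beta"]), rel=0.10
        )


class TestMoments:
    def test_symmetric_small_sample(self):
        med, mean, skew, kurt = moment_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert (med, mean) == (2.5, 2.5)
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_population_formula_oracle(self):
        x = np.array([0.0, 0.0, 0.0, 1.0])
        med, mean, skew, kurt = moment_features(x)
        d = x - x.mean()
        m2, m3, m4 = (d**2).mean(), (d**3).mean(), (d**4).mean()
        assert mean == 0.25
        assert skew == pytest.approx(m3 / m2**1.5, abs=1e-12)
        assert kurt == pytest.approx(m4 / m2**2 - 3, abs=1e-12)

    def test_normal_limits(self):
        rng = np.random.default_rng(5)
        _, _, skew, kurt = moment_features(rng.standard_normal(10**5))
        assert abs(skew) < 0.1 and abs(kurt) < 0.1

    def test_zero_variance_moments_missing(self):
        med, mean, skew, kurt = moment_features(np.full(10, 2.0))
        assert (med, mean) == (2.0, 2.0)
        assert np.isnan(skew) and np.isnan(kurt)


class TestFeatureTable:
    def test_complete_grid_and_planted_effect(self, planted_features, planted_cohort):
        ft, scales = planted_features
        cfg, _, _ = planted_cohort
        assert len(ft) == 15 * 2 * 8 * 5 * 16
        counts = ft.groupby(["subject_id", "session"]).size()
        assert (counts == 640).all()
        # planted alpha@P3 amplitude shifts move PSD in the delta-score direction
        cell = ft[(ft.feature == "PSD") & (ft.band == "alpha") & (ft.channel == "P3")]
        wide = cell.pivot(index="subject_id", columns="session", values="value")
        dscore = scales.set_index("subject_id").psqi_after - scales.set_index("subject_id").psqi_before
        r = np.corrcoef(wide["post"] - wide["pre"], dscore.loc[wide.index])[0, 1]
        assert r > 0.8

    def test_band_passed_mean_is_negligible(self, planted_features):
        """High-pass filtering leaves the mean feature near zero in every band."""
        ft, _ = planted_features
        max_mean = ft[ft.feature == "mean"].groupby("band")["value"].apply(lambda v: v.abs().max())
        band_rms = ft[ft.feature == "PSD"].groupby("band")["value"].mean() ** 0.5
        assert (max_mean < 0.05 * band_rms).all()

    def test_missing_session_rejected(self):
        _, pairs, _ = make_cohort(n_subjects=3, seed=9, duration=4.0)
        epochs = {}
        from tmseeg.pipeline import preprocess_cohort

        epochs = preprocess_cohort(pairs, {})
        del epochs[("S02", "post")]
        with pytest.raises(CohortIntegrityError):
            extract_feature_table(epochs, FAST_PARAMS)

    def test_per_epoch_mean_mode_runs(self):
        _, pairs, _ = make_cohort(n_subjects=3, seed=9, duration=4.0)
        from tmseeg.pipeline import preprocess_cohort

        params = FeatureParams(entropy_max_samples=256, per_epoch_mean=True, welch_window=1.0)
        ft = extract_feature_table(preprocess_cohort(pairs, {}), params)
        assert len(ft) == 3 * 2 * 640
        psd = ft[(ft.feature == "PSD")]["value"]
        assert (psd.dropna() >= 0).all()
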