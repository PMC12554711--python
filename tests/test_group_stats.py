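"""Paired tests, outcome correlations, selection, and responder rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tmseeg.errors import DegenerateInputError, ParameterError
from tmseeg.group_stats import (
    build_diff_table,
    correlate_with_outcome,
    paired_ttest,
    responder_rate,
    scale_ttests,
    select_significant,
    ttest_all_indicators,
)
from tmseeg.synthetic import load_study_scores


class TestPairedTTest:
    def test_closed_form_example(self):
        res = paired_ttest([1, 2, 4], [2, 2, 5])
        assert res.t == pytest.approx(2.0, abs=1e-12)
        assert res.df == 2
        assert res.p == pytest.approx(0.1835, abs=2e-4)

    def test_constant_shift_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_ttest([1.0, 2.0, 5.0], [3.0, 4.0, 7.0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10**6), st.integers(3, 25))
    def test_matches_textbook_formula(self, seed, n):
        rng = np.random.default_rng(seed)
        before, after = rng.normal(size=n), rng.normal(size=n)
        d = after - before
        if np.std(d, ddof=1) == 0:
            return
        res = paired_ttest(before, after)
        t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        assert res.t == pytest.approx(t, rel=1e-10)
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), n - 1), rel=1e-10)

    def test_study_scale_scores_highly_significant(self):
        out = scale_ttests(load_study_scores())
        assert out["PSQI"].p < 0.005 and out["ISI"].p < 0.005
        assert out["PSQI"].df == 14 and out["ISI"].df == 14


def toy_feature_table(values_by_subject, feature="PSD", band="alpha", channel="P3"):
    rows = []
    for sid, (pre, post) in values_by_subject.items():
        rows.append(dict(subject_id=sid, session="pre", feature=feature, band=band,
                         channel=channel, value=pre))
        rows.append(dict(subject_id=sid, session="post", feature=feature, band=band,
                         channel=channel, value=post))
    return pd.DataFrame(rows)


class TestIndicatorGrid:
    def test_row_count_is_full_grid(self, planted_features):
        ft, _ = planted_features
        records = ttest_all_indicators(ft)
        assert len(records) == 640
        assert records.testable.all()
        assert records.n_effective.eq(15).all()

    def test_planted_effect_detected(self, planted_features):
        ft, _ = planted_features
        records = ttest_all_indicators(ft)
        cell = records[(records.feature == "PSD") & (records.band == "alpha")
                       & (records.channel == "P3")].iloc[0]
        assert cell.p < 0.05

    def test_pairwise_deletion_and_untestable_flag(self):
        vals = {f"S{i}": (1.0 + i, 2.0 + 2 * i) for i in range(5)}
        ft = toy_feature_table(vals)
        ft.loc[(ft.subject_id == "S0") & (ft.session == "post"), "value"] = np.nan
        rec = ttest_all_indicators(ft).iloc[0]
        assert rec.n_effective == 4 and rec.testable
        ft.loc[ft.session == "post", "value"] = np.nan
        rec = ttest_all_indicators(ft).iloc[0]
        assert not rec.testable and np.isnan(rec.p)


class TestOutcomeCorrelation:
    def make_diff(self, x, y_psqi):
        ft = toy_feature_table({f"S{i:02d}": (0.0, x[i]) for i in range(len(x))})
        st_rows = []
        for i in range(len(x)):
            st_rows.append(dict(subject_id=f"S{i:02d}", age=40, psqi_before=15,
                                isi_before=20, psqi_after=15 + y_psqi[i], isi_after=20))
        return build_diff_table(ft, pd.DataFrame(st_rows))

    def test_identity_gives_unit_correlation(self):
        x = np.array([1.0, -2.0, 3.0, 0.5, -1.5])
        dt = self.make_diff(x, x.astype(int))
        rec = correlate_with_outcome(dt, "PSQI").iloc[0]
        # feature delta equals the (integer) score delta where possible
        assert rec.statistic == pytest.approx(
            np.corrcoef(x, x.astype(int))[0, 1], abs=1e-12
        )

    def test_hand_computed_pearson(self):
        dt = self.make_diff(np.array([1.0, 2.0, 3.0]), np.array([3, 5, 8]))
        rec = correlate_with_outcome(dt, "PSQI").iloc[0]
        assert rec.statistic == pytest.approx(0.9934, abs=1e-4)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 10**6), st.floats(0.1, 50), st.floats(-10, 10))
    def test_pearson_symmetric_scale_invariant_bounded(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=8), rng.integers(-6, 3, size=8).astype(float)
        if np.std(y) == 0:
            return
        dt = self.make_diff(x, y.astype(int))
        r1 = correlate_with_outcome(dt, "PSQI").iloc[0].statistic
        dt2 = self.make_diff(x * scale + shift, y.astype(int))
        r2 = correlate_with_outcome(dt2, "PSQI").iloc[0].statistic
        assert abs(r1) <= 1 + 1e-12
        assert r1 == pytest.approx(r2, abs=1e-9)
        assert r1 == pytest.approx(np.corrcoef(x, y.astype(int))[0, 1], abs=1e-9)


class TestSelection:
    def records(self, ps):
        return pd.DataFrame(
            dict(scale="PSQI", feature="PSD", band="alpha",
                 channel=[f"c{i}" for i in range(len(ps))],
                 statistic=0.5, p=ps, n_effective=15, testable=True)
        )

    def test_none_pass_when_all_null(self):
        assert select_significant(self.records([0.5, 0.5, 0.5])).empty

    def test_uncorrected_threshold(self):
        sel = select_significant(self.records([0.01, 0.04, 0.2]), 0.05)
        assert list(sel.p) == [0.01, 0.04]

    def test_benjamini_hochberg_step_up(self):
        sel = select_significant(self.records([0.01, 0.04, 0.2]), 0.05, correction="bh")
        assert len(sel) == 1
        assert sel.iloc[0].p == 0.01
        assert sel.iloc[0].p_adjusted == pytest.approx(0.03, abs=1e-12)


class TestResponderRate:
    def test_unchanged_cohort_zero(self):
        st_df = load_study_scores().copy()
        st_df["psqi_after"] = st_df["psqi_before"]
        assert responder_rate(st_df, "PSQI") == 0.0

    def test_study_rates_under_quarter_reduction_rule(self):
        st_df = load_study_scores()
        assert responder_rate(st_df, "PSQI") == pytest.approx(7 / 15, abs=1e-12)
        assert responder_rate(st_df, "ISI") == pytest.approx(9 / 15, abs=1e-12)

    def test_nonpositive_baseline_rejected(self):
        st_df = load_study_scores().copy()
        st_df.loc[0, "psqi_before"] = 0
        with pytest.raises(ParameterError):
            responder_rate(st_df, "PSQI")
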