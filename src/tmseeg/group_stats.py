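"""Paired pre/post statistics, outcome correlations, significance selection,
and the treatment responder rate.

All deltas follow the convention delta = after - before, for features and
scale scores alike; an improvement on PSQI/ISI is therefore a negative
delta. Correlations are invariant to any consistent choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import CohortIntegrityError, DegenerateInputError, ParameterError

STAT_COLUMNS = ("scale", "feature", "band", "channel", "statistic", "p", "n_effective", "testable")


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    p: float
    df: int


def paired_ttest(before: np.ndarray, after: np.ndarray) -> PairedTestResult:
    """Classical paired t-test on after - before differences.

    Two-tailed p from Student's t with n-1 degrees of freedom; a positive t
    means the after values are larger.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ParameterError("before/after must be equal-length 1-D arrays")
    n = before.size
    if n < 3:
        raise ParameterError("paired t-test needs at least 3 pairs")
    d = after - before
    if np.std(d, ddof=1) == 0:
        raise DegenerateInputError("differences have zero variance")
    res = stats.ttest_rel(after, before)
    return PairedTestResult(t=float(res.statistic), p=float(res.pvalue), df=n - 1)


def build_diff_table(feature_table: pd.DataFrame, scale_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject (after - before) deltas of every feature cell plus the scales.

    Returns a wide table: one row per subject, one column per
    (feature, band, channel) cell (a pandas MultiIndex flattened to
    ``feature|band|channel``), plus ``delta_psqi`` and ``delta_isi``.
    """
    wide = feature_table.pivot(
        index="subject_id", columns=["session", "feature", "band", "channel"],
        values="value",
    )
    try:
        pre = wide["pre"]
        post = wide["post"]
    except KeyError as exc:
        raise CohortIntegrityError("feature table lacks a pre or post session") from exc
    if not pre.columns.equals(post.columns):
        raise CohortIntegrityError("pre and post feature grids differ")
    diff = post - pre
    diff.columns = ["|".join(c) for c in diff.columns]
    st = scale_table.set_index("subject_id")
    st.index = st.index.astype(str)
    diff.index = diff.index.astype(str)
    missing = set(diff.index) ^ set(st.index)
    if missing:
        raise CohortIntegrityError(f"subjects mismatch between features and scales: {sorted(missing)}")
    diff["delta_psqi"] = st["psqi_after"] - st["psqi_before"]
    diff["delta_isi"] = st["isi_after"] - st["isi_before"]
    return diff


def ttest_all_indicators(feature_table: pd.DataFrame) -> pd.DataFrame:
    """Paired pre/post t-test for every (feature, band, channel) cell.

    NaN feature values are excluded pairwise; cells with fewer than 3
    complete pairs are flagged untestable (NaN statistic and p) instead of
    raising. Returns one StatRecord row per cell.
    """
    wide = feature_table.pivot(
        index="subject_id", columns=["session", "feature", "band", "channel"],
        values="value",
    )
    if "pre" not in wide.columns.levels[0] or "post" not in wide.columns.levels[0]:
        raise CohortIntegrityError("feature table lacks a pre or post session")
    pre, post = wide["pre"], wide["post"]
    rows = []
    for col in pre.columns:
        b = pre[col].to_numpy(dtype=float)
        a = post[col].to_numpy(dtype=float)
        ok = np.isfinite(b) & np.isfinite(a)
        n_eff = int(ok.sum())
        feature, band, channel = col
        rec = {
            "scale": "none", "feature": feature, "band": band, "channel": channel,
            "statistic": np.nan, "p": np.nan, "n_effective": n_eff, "testable": False,
        }
        if n_eff >= 3 and np.std(a[ok] - b[ok], ddof=1) > 0:
            res = paired_ttest(b[ok], a[ok])
            rec.update(statistic=res.t, p=res.p, testable=True)
        rows.append(rec)
    return pd.DataFrame(rows, columns=list(STAT_COLUMNS))


def correlate_with_outcome(diff_table: pd.DataFrame, scale: str) -> pd.DataFrame:
    """Pearson correlation of every feature delta with the chosen scale delta.

    ``scale`` is ``"PSQI"`` or ``"ISI"``. NaNs excluded pairwise; cells with
    fewer than 3 complete subjects or zero variance are flagged untestable.
    """
    scale = scale.upper()
    if scale not in ("PSQI", "ISI"):
        raise ParameterError("scale must be 'PSQI' or 'ISI'")
    y_all = diff_table[f"delta_{scale.lower()}"].to_numpy(dtype=float)
    rows = []
    feature_cols = [c for c in diff_table.columns if "|" in c]
    for col in feature_cols:
        x_all = diff_table[col].to_numpy(dtype=float)
        ok = np.isfinite(x_all) & np.isfinite(y_all)
        n_eff = int(ok.sum())
        feature, band, channel = col.split("|")
        rec = {
            "scale": scale, "feature": feature, "band": band, "channel": channel,
            "statistic": np.nan, "p": np.nan, "n_effective": n_eff, "testable": False,
        }
        x, y = x_all[ok], y_all[ok]
        if n_eff >= 3 and np.std(x) > 0 and np.std(y) > 0:
            r, p = stats.pearsonr(x, y)
            rec.update(statistic=float(r), p=float(p), testable=True)
        rows.append(rec)
    return pd.DataFrame(rows, columns=list(STAT_COLUMNS))


def select_significant(
    records: pd.DataFrame, alpha: float = 0.05, correction: str | None = None
) -> pd.DataFrame:
    """Filter StatRecords to those significant at ``alpha``.

    ``correction`` is ``None`` (uncorrected, the default) or ``"bh"`` for
    Benjamini-Hochberg FDR across the testable records. Untestable records
    never pass.
    """
    testable = records[records["testable"]].copy()
    if testable.empty:
        return testable
    if correction is None:
        keep = testable["p"] < alpha
    elif correction == "bh":
        reject, p_adj, _, _ = multipletests(testable["p"].to_numpy(), alpha=alpha, method="fdr_bh")
        testable["p_adjusted"] = p_adj
        keep = reject
    else:
        raise ParameterError(f"unknown correction {correction!r}")
    return testable[keep].reset_index(drop=True)


def responder_rate(scale_table: pd.DataFrame, scale: str, threshold: float = 0.25) -> float:
    """Fraction of subjects whose score fell by at least ``threshold`` of baseline.

    Response = (before - after) / before >= threshold; baselines must be
    positive.
    """
    scale = scale.upper()
    if scale not in ("PSQI", "ISI"):
        raise ParameterError("scale must be 'PSQI' or 'ISI'")
    before = scale_table[f"{scale.lower()}_before"].to_numpy(dtype=float)
    after = scale_table[f"{scale.lower()}_after"].to_numpy(dtype=float)
    if np.any(before <= 0):
        raise ParameterError("responder rate undefined for non-positive baseline scores")
    return float(np.mean((before - after) / before >= threshold))


def scale_ttests(scale_table: pd.DataFrame) -> dict[str, PairedTestResult]:
    """Paired pre/post t-tests of the PSQI and ISI total scores."""
    out = {}
    for scale in ("PSQI", "ISI"):
        out[scale] = paired_ttest(
            scale_table[f"{scale.lower()}_before"], scale_table[f"{scale.lower()}_after"]
        )
    return out
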