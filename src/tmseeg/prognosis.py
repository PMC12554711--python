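"""Prognostic modeling: leave-one-out SVR on selected feature deltas and a
row-shuffling permutation test of its predictive correlation.

The model predicts each subject's scale-score change from the pre/post
changes of the significantly outcome-correlated indicators. Validity is
assessed by leave-one-out prediction (scaler and SVR refit without the
held-out subject) and a permutation null built by shuffling the rows of the
predictor matrix across subjects with the outcome fixed; the one-sided
percentile of the observed correlation in that null is the p-value.

Indicator selection on the full sample before LOO mirrors the original
procedure but is optimistically biased; ``mode="nested"`` repeats the
selection inside every training fold and is the leakage-free variant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR

from .errors import DegenerateInputError, ParameterError
from .group_stats import build_diff_table, correlate_with_outcome, select_significant


@dataclass(frozen=True)
class ModelConfig:
    """SVR and permutation-test settings.

    ``gamma`` follows scikit-learn semantics (``"scale"`` = 1 / (d * Var(X)),
    ``"auto"``, or a float). ``standardize`` z-scores each column using
    training-fold statistics only.
    """

    kernel: str = "rbf"
    C: float = 1.0
    epsilon: float = 0.1
    gamma: str | float = "scale"
    n_permutations: int = 5000
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ParameterError("kernel must be 'rbf' or 'linear'")
        if self.C <= 0:
            raise ParameterError("C must be positive")
        if self.epsilon < 0:
            raise ParameterError("epsilon must be non-negative")
        if self.n_permutations < 100:
            raise ParameterError("n_permutations must be >= 100")


@dataclass
class PermutationResult:
    """LOO predictions, the observed predictive correlation, and its null."""

    loo_predictions: np.ndarray
    observed_r: float
    null_rs: np.ndarray
    p: float
    seed: int

    @property
    def n_permutations(self) -> int:
        return len(self.null_rs)


@dataclass
class PrognosisResult:
    """Outcome of the full selection + LOO-SVR + permutation pipeline."""

    scale: str
    mode: str
    selected: pd.DataFrame
    permutation: PermutationResult | None
    note: str = ""

    @property
    def is_empty_model(self) -> bool:
        return self.permutation is None

    def to_dict(self, include_null: bool = False) -> dict:
        out = {
            "scale": self.scale,
            "mode": self.mode,
            "note": self.note,
            "selected_indicators": [
                {"feature": r.feature, "band": r.band, "channel": r.channel,
                 "r": float(r.statistic), "p": float(r.p)}
                for r in self.selected.itertuples()
            ],
        }
        if self.permutation is not None:
            out.update(
                observed_r=float(self.permutation.observed_r),
                p=float(self.permutation.p),
                n_permutations=int(self.permutation.n_permutations),
                seed=int(self.permutation.seed),
                loo_predictions=[float(v) for v in self.permutation.loo_predictions],
            )
            if include_null:
                out["null_rs"] = [float(v) for v in self.permutation.null_rs]
        return out

    def to_json(self, path, include_null: bool = False) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(include_null), fh, indent=2, sort_keys=True)


def _fit_predict_fold(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, cfg: ModelConfig
) -> float:
    keep = X_train.std(axis=0) > 0
    if not keep.all():
        warnings.warn("dropping constant column(s) in a training fold", stacklevel=3)
    if not keep.any():
        return float(y_train.mean())  # no informative predictors in this fold
    Xtr, Xte = X_train[:, keep], X_test[keep]
    if cfg.standardize:
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
    model = SVR(kernel=cfg.kernel, C=cfg.C, epsilon=cfg.epsilon, gamma=cfg.gamma)
    model.fit(Xtr, y_train)
    return float(model.predict(Xte[None, :])[0])


def loo_predict(X: np.ndarray, y: np.ndarray, cfg: ModelConfig | None = None) -> np.ndarray:
    """Leave-one-out SVR predictions of y from X.

    For each subject the scaler and model are fit on the remaining n-1 rows
    only, so the held-out subject never influences its own standardization.
    Constant training columns are dropped with a warning. Deterministic.
    """
    cfg = cfg or ModelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 4:
        raise ParameterError("leave-one-out needs at least 4 subjects")
    if y.shape != (n,):
        raise ParameterError("y length must match the number of rows of X")
    if not np.all(np.isfinite(X)):
        raise ParameterError("X contains missing or non-finite values")
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        preds[i] = _fit_predict_fold(X[tr], y[tr], X[i], cfg)
    return preds


def prediction_correlation(pred: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation between predicted and true score changes."""
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if pred.shape != y.shape:
        raise ParameterError("prediction and truth must have equal length")
    if np.std(y) == 0:
        raise DegenerateInputError("true score changes have zero variance")
    if np.std(pred) == 0:
        raise DegenerateInputError("predictions have zero variance")
    return float(stats.pearsonr(pred, y)[0])


def _safe_r(pred: np.ndarray, y: np.ndarray) -> float:
    # Inside the permutation loop a fold can yield constant predictions
    # (everything inside the epsilon tube); that permutation carries no
    # predictive signal and scores r = 0.
    if np.std(pred) == 0:
        return 0.0
    return float(stats.pearsonr(pred, y)[0])


def permutation_test(
    X: np.ndarray, y: np.ndarray, cfg: ModelConfig | None = None
) -> PermutationResult:
    """Permutation significance of the LOO predictive correlation.

    The rows of X are shuffled jointly across subjects (y fixed) for each of
    ``cfg.n_permutations`` draws, the whole LOO procedure is rerun, and the
    one-sided p toward positive correlation is
    ``(#{null_r >= observed_r} + 1) / (n_permutations + 1)`` — the add-one
    correction keeps p strictly positive. Deterministic given ``cfg.seed``.
    """
    cfg = cfg or ModelConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    observed_pred = loo_predict(X, y, cfg)
    observed_r = prediction_correlation(observed_pred, y)
    rng = np.random.default_rng(cfg.seed)
    null_rs = np.empty(cfg.n_permutations)
    n = X.shape[0]
    for k in range(cfg.n_permutations):
        perm = rng.permutation(n)
        null_rs[k] = _safe_r(loo_predict(X[perm], y, cfg), y)
    p = (np.count_nonzero(null_rs >= observed_r) + 1) / (cfg.n_permutations + 1)
    return PermutationResult(observed_pred, observed_r, null_rs, float(p), cfg.seed)


def _pearson_p_columns(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-column Pearson r against y and its two-tailed p."""
    n = len(y)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = xc.T @ yc / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    r[(sx == 0) | (sy == 0)] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p[np.isnan(r)] = np.nan
    p[np.abs(r) == 1.0] = 0.0
    return r, p


def _nested_loo(
    X_all: np.ndarray, y: np.ndarray, alpha: float, cfg: ModelConfig
) -> np.ndarray:
    """LOO with per-fold indicator selection (vectorized Pearson screening)."""
    n = X_all.shape[0]
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        _, p = _pearson_p_columns(X_all[tr], y[tr])
        keep = np.where(np.nan_to_num(p, nan=1.0) < alpha)[0]
        if keep.size == 0:
            preds[i] = float(y[tr].mean())
            continue
        preds[i] = _fit_predict_fold(X_all[tr][:, keep], y[tr], X_all[i, keep], cfg)
    return preds


def run_prognosis(
    feature_table: pd.DataFrame,
    scale_table: pd.DataFrame,
    scale: str,
    alpha: float = 0.05,
    cfg: ModelConfig | None = None,
    mode: str = "full-sample",
) -> PrognosisResult:
    """Selection + LOO-SVR + permutation test for one outcome scale.

    ``mode="full-sample"`` selects outcome-correlated indicators on all
    subjects before cross-validation (mirroring the original procedure, with
    its optimism); ``mode="nested"`` repeats the selection inside every
    training fold, for both the observed statistic and every permutation.
    An empty selection yields an explicit empty-model result.
    """
    cfg = cfg or ModelConfig()
    if mode not in ("full-sample", "nested"):
        raise ParameterError("mode must be 'full-sample' or 'nested'")
    scale = scale.upper()
    dt = build_diff_table(feature_table, scale_table)
    feature_cols = [c for c in dt.columns if "|" in c]
    # LOO needs complete predictors: drop all-NaN-prone columns pairwise here
    complete_cols = [c for c in feature_cols if np.all(np.isfinite(dt[c].to_numpy(dtype=float)))]
    dt_c = dt[complete_cols + ["delta_psqi", "delta_isi"]]
    y = dt_c[f"delta_{scale.lower()}"].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise DegenerateInputError(f"delta {scale} is constant across subjects")

    if mode == "full-sample":
        sel = select_significant(correlate_with_outcome(dt_c, scale), alpha=alpha)
        if sel.empty:
            return PrognosisResult(scale, mode, sel, None, note="no significant indicators")
        cols = ["|".join(t) for t in zip(sel["feature"], sel["band"], sel["channel"])]
        X = dt_c[cols].to_numpy(dtype=float)
        perm = permutation_test(X, y, cfg)
        return PrognosisResult(scale, mode, sel, perm)

    # nested: selection re-done per fold, and per permutation
    sel_full = select_significant(correlate_with_outcome(dt_c, scale), alpha=alpha)
    X_all = dt_c[complete_cols].to_numpy(dtype=float)
    observed_pred = _nested_loo(X_all, y, alpha, cfg)
    if np.std(observed_pred) == 0:
        return PrognosisResult(scale, mode, sel_full, None, note="constant nested predictions")
    observed_r = prediction_correlation(observed_pred, y)
    rng = np.random.default_rng(cfg.seed)
    null_rs = np.empty(cfg.n_permutations)
    for k in range(cfg.n_permutations):
        perm_idx = rng.permutation(len(dt_c))
        null_rs[k] = _safe_r(_nested_loo(X_all[perm_idx], y, alpha, cfg), y)
    p = (np.count_nonzero(null_rs >= observed_r) + 1) / (cfg.n_permutations + 1)
    return PrognosisResult(
        scale, mode, sel_full,
        PermutationResult(observed_pred, observed_r, null_rs, float(p), cfg.seed),
    )
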