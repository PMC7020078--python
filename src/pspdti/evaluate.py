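"""Validation battery: adjusted R², MAE / MAE%, cross-validation, blind
follow-up application and Friedman comparison of paired error sets.

Conventions
-----------
* MAE% normalises each absolute error by the scale maximum for bounded
  scales (UPDRS-III 108, PIGD 20, MHY 5) and by the per-subject observed
  value for LEDD, which has no ceiling. Either convention can be forced.
* Cross-validation refits *coefficients* only, on the term set selected
  once from the full sample; a re-selection callback is accepted for the
  unbiased (and slower) alternative in which selection and stepwise run
  inside every fold.
* "Mean adjusted R²" under cross-validation is the mean over folds of the
  training-portion adjusted R² — the only version of that statistic a
  leave-one-out scheme can report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .regression import SeverityModel, _ols
from .scales import ScaleSpec, get_scale

logger = logging.getLogger(__name__)


def adjusted_r2(observed, predicted, p_terms: int) -> float:
    """1 - (1 - R²)(n - 1)/(n - p - 1), with R² the coefficient of determination."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    n = len(obs)
    if n <= p_terms + 1:
        raise ValueError(f"adjusted R² undefined: n={n} <= p+1={p_terms + 1}")
    ss_res = np.sum((obs - pred) ** 2)
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("observed values have zero variance")
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p_terms - 1)


def mae_stats(
    observed,
    predicted,
    scale: ScaleSpec,
    percent_denominator: str | None = None,
) -> tuple[float, float, float, float]:
    """(MAE, MAE SD, MAE%, MAE% SD) over paired observations.

    ``percent_denominator`` overrides the scale's convention: ``"maximum"``
    divides by the scale ceiling, ``"observed"`` by each subject's observed
    value. SDs are sample SDs of the per-subject quantities.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) < 2:
        raise ValueError("need at least 2 paired values")
    if percent_denominator is None:
        percent_denominator = "maximum" if scale.kind == "bounded" else "observed"
    abs_err = np.abs(obs - pred)
    if percent_denominator == "maximum":
        if scale.maximum is None:
            raise ValueError(f"scale {scale.name} has no maximum to normalise by")
        pct = abs_err / scale.maximum * 100.0
    elif percent_denominator == "observed":
        if np.any(obs == 0):
            raise ValueError(f"zero observed value on {scale.name}: per-subject MAE% undefined")
        pct = abs_err / np.abs(obs) * 100.0
    else:
        raise ValueError(f"unknown percent_denominator {percent_denominator!r}")
    return (
        float(abs_err.mean()),
        float(abs_err.std(ddof=1)),
        float(pct.mean()),
        float(pct.std(ddof=1)),
    )


@dataclass
class EvaluationReport:
    """Summary plus per-subject errors for one validation scheme."""

    scheme: str  # training | loocv | fivefold | followup
    target: str
    n: int
    mean_adjusted_r2: float
    sd_adjusted_r2: float
    mae: float
    mae_sd: float
    mae_pct: float
    mae_pct_sd: float
    per_subject: pd.DataFrame  # columns: observed, predicted, error; index: record_id
    percent_denominator: str = "maximum"
    seed: int | None = None
    friedman: tuple[float, float] | None = None
    skipped_folds: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mae < 0 or self.mae_pct < 0:
            raise ValueError("MAE and MAE% must be non-negative")

    def to_dict(self) -> dict:
        return {
            "schema": "pspdti.report/1",
            "scheme": self.scheme,
            "target": self.target,
            "n": self.n,
            "mean_adjusted_r2": self.mean_adjusted_r2,
            "sd_adjusted_r2": self.sd_adjusted_r2,
            "mae": self.mae,
            "mae_sd": self.mae_sd,
            "mae_pct": self.mae_pct,
            "mae_pct_sd": self.mae_pct_sd,
            "percent_denominator": self.percent_denominator,
            "seed": self.seed,
            "friedman": list(self.friedman) if self.friedman else None,
            "skipped_folds": self.skipped_folds,
            "per_subject": {
                rid: {k: float(v) for k, v in row.items()}
                for rid, row in self.per_subject.iterrows()
            },
        }


def _summarise(
    scheme: str,
    target: str,
    per_subject: pd.DataFrame,
    fold_r2: list[float],
    scale: ScaleSpec,
    percent_denominator: str | None,
    seed: int | None = None,
    skipped: int = 0,
) -> EvaluationReport:
    mae, mae_sd, pct, pct_sd = mae_stats(
        per_subject["observed"], per_subject["predicted"], scale, percent_denominator
    )
    r2_arr = np.asarray(fold_r2, dtype=float)
    return EvaluationReport(
        scheme=scheme,
        target=target,
        n=len(per_subject),
        mean_adjusted_r2=float(r2_arr.mean()),
        sd_adjusted_r2=float(r2_arr.std(ddof=1)) if len(r2_arr) > 1 else 0.0,
        mae=mae,
        mae_sd=mae_sd,
        mae_pct=pct,
        mae_pct_sd=pct_sd,
        per_subject=per_subject,
        percent_denominator=percent_denominator
        or ("maximum" if scale.kind == "bounded" else "observed"),
        seed=seed,
        skipped_folds=skipped,
    )


def _refit_predict(
    features: list[str],
    X: pd.DataFrame,
    y: pd.Series,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> tuple[np.ndarray, float] | None:
    """OLS refit on the training rows; returns (test predictions, train adj R²)."""
    Xtr = X.iloc[train_idx][features].to_numpy(dtype=float)
    ytr = y.iloc[train_idx].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(ytr)), Xtr])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        return None
    fit = _ols(Xtr, ytr)
    Xte = X.iloc[test_idx][features].to_numpy(dtype=float)
    pred = fit.params[0] + Xte @ fit.params[1:]
    return pred, float(fit.rsquared_adj)


def _clean_xy(X: pd.DataFrame, y: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    keep = y.notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("excluding %d record(s) with missing target", dropped)
    return X.loc[keep], y.loc[keep]


def crossval(
    features: list[str],
    X: pd.DataFrame,
    y: pd.Series,
    target: str,
    folds: list[np.ndarray],
    scheme: str,
    percent_denominator: str | None = None,
    seed: int | None = None,
) -> EvaluationReport:
    """Shared engine behind LOOCV and k-fold: refit per fold, pool held-out errors."""
    scale = get_scale(target)
    n = len(y)
    records = []
    fold_r2 = []
    skipped = 0
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        out = _refit_predict(features, X, y, train_idx, test_idx)
        if out is None:
            skipped += 1
            logger.warning("%s: skipping fold with singular design", scheme)
            continue
        pred, r2 = out
        fold_r2.append(r2)
        for i, row in zip(test_idx, pred):
            obs = float(y.iloc[i])
            records.append(
                {"record_id": y.index[i], "observed": obs, "predicted": float(row),
                 "error": float(row) - obs}
            )
    if not records:
        raise ValueError(f"{scheme}: every fold had a singular design; nothing evaluated")
    per_subject = pd.DataFrame(records).set_index("record_id")
    return _summarise(scheme, target, per_subject, fold_r2, scale,
                      percent_denominator, seed=seed, skipped=skipped)


def loocv(
    features: list[str],
    X: pd.DataFrame,
    y: pd.Series,
    target: str,
    percent_denominator: str | None = None,
) -> EvaluationReport:
    """Leave-one-out: refit coefficients on n-1, predict the held-out subject."""
    X, y = _clean_xy(X, y)
    folds = [np.array([i]) for i in range(len(y))]
    return crossval(features, X, y, target, folds, "loocv", percent_denominator)


def kfold_cv(
    features: list[str],
    X: pd.DataFrame,
    y: pd.Series,
    target: str,
    k: int = 5,
    seed: int = 0,
    percent_denominator: str | None = None,
) -> EvaluationReport:
    """Seeded k-fold cross-validation (uniform random near-equal folds)."""
    X, y = _clean_xy(X, y)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available subjects")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = [np.sort(f) for f in np.array_split(perm, k)]
    scheme = "fivefold" if k == 5 else f"{k}fold"
    return crossval(features, X, y, target, folds, scheme, percent_denominator, seed=seed)


def training_report(
    model: SeverityModel,
    X: pd.DataFrame,
    y: pd.Series,
    percent_denominator: str | None = None,
) -> EvaluationReport:
    """In-sample residual report for a fitted model."""
    X, y = _clean_xy(X, y)
    scale = get_scale(model.target)
    pred = model.predict(X)
    per_subject = pd.DataFrame(
        {"observed": y.to_numpy(dtype=float), "predicted": pred,
         "error": pred - y.to_numpy(dtype=float)},
        index=y.index,
    )
    r2 = adjusted_r2(per_subject["observed"], per_subject["predicted"], len(model.terms))
    return _summarise("training", model.target, per_subject, [r2], scale, percent_denominator)


def blind_validate(
    model: SeverityModel,
    X_followup: pd.DataFrame,
    y_followup: pd.Series,
    percent_denominator: str | None = None,
) -> EvaluationReport:
    """Apply a frozen baseline model, unchanged, to follow-up records.

    Rows missing the target score or any model feature are excluded with a
    log line; no coefficients are refit.
    """
    scale = get_scale(model.target)
    X, y = _clean_xy(X_followup, y_followup)
    missing_feats = [f for f in model.feature_names if f not in X.columns]
    if missing_feats:
        raise KeyError(f"follow-up table lacks model feature(s) {missing_feats}")
    complete = X[model.feature_names].notna().all(axis=1)
    if not complete.all():
        logger.warning("excluding %d follow-up row(s) with missing features", (~complete).sum())
        X, y = X.loc[complete], y.loc[complete]
    pred = model.predict(X)
    obs = y.to_numpy(dtype=float)
    per_subject = pd.DataFrame(
        {"observed": obs, "predicted": pred, "error": pred - obs}, index=y.index
    )
    n = len(y)
    r2 = (
        adjusted_r2(obs, pred, len(model.terms))
        if n > len(model.terms) + 1
        else float("nan")
    )
    mae, mae_sd, pct, pct_sd = mae_stats(obs, pred, scale, percent_denominator)
    return EvaluationReport(
        scheme="followup",
        target=model.target,
        n=n,
        mean_adjusted_r2=r2,
        sd_adjusted_r2=0.0,
        mae=mae,
        mae_sd=mae_sd,
        mae_pct=pct,
        mae_pct_sd=pct_sd,
        per_subject=per_subject,
        percent_denominator=percent_denominator
        or ("maximum" if scale.kind == "bounded" else "observed"),
    )


# ---------------------------------------------------------------------------
# Friedman test


def _friedman_statistic(matrix: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square statistic on a subjects x schemes matrix."""
    n, k = matrix.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)  # average ranks for ties
    col_sums = ranks.sum(axis=0)
    statistic = 12.0 / (n * k * (k + 1)) * np.sum(col_sums ** 2) - 3.0 * n * (k + 1)
    # tie correction (Iman–Davenport style denominator)
    ties = 0.0
    for row in matrix:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts ** 3 - counts))
    denom = 1.0 - ties / (n * k * (k ** 2 - 1))
    if denom <= 0:
        return 0.0
    return float(statistic / denom)


def friedman_compare(
    error_matrix: pd.DataFrame | np.ndarray,
    exact: bool = False,
) -> tuple[float, float]:
    """Friedman test on paired |error| columns (one column per scheme).

    Rows are subjects (blocks), columns are validation schemes; the matrix
    must be complete. Returns ``(statistic, p)`` with p from the chi-square
    approximation, or from exhaustive within-block permutation when
    ``exact=True`` (feasible for <= 9 subjects).
    """
    matrix = np.asarray(error_matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 schemes")
    if np.isnan(matrix).any():
        raise ValueError("error matrix is incomplete; the test requires paired blocks")
    n, k = matrix.shape
    statistic = _friedman_statistic(matrix)
    if exact:
        if n > 9:
            raise ValueError(f"exact permutation over {n} blocks is infeasible; use exact=False")
        perms = list(product(*[list(_permutations(row)) for row in matrix]))
        stats_null = np.array([
            _friedman_statistic(np.vstack(rows)) for rows in perms
        ])
        p = float(np.mean(stats_null >= statistic - 1e-12))
    else:
        p = float(stats.chi2.sf(statistic, df=k - 1))
    return statistic, p


def _permutations(row: np.ndarray):
    from itertools import permutations

    return (np.asarray(p) for p in permutations(row))
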