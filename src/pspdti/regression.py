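"""Second-stage modelling: capped stepwise OLS with bootstrap coefficients.

The survivors of stability selection enter a classical bidirectional
stepwise linear regression: at each step the candidate with the smallest
partial-F p-value joins if that p-value is below ``p_enter``, then any
included term whose p-value has risen above ``p_remove`` leaves. The model
size is capped at one fifth of the number of subjects (rounded to the
nearest integer, halves away from zero) — 11 terms for a 53-subject cohort
— which bounds overfitting when candidates outnumber what the sample can
support. Final coefficients are the per-parameter means over ``B``
case-resampled OLS refits of the fixed term set, reported on the original
feature scale so exported equations read directly as
``score = intercept + sum(coef * feature)``.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

MODEL_SCHEMA = "pspdti.model/1"


def feature_cap(n_subjects: int) -> int:
    """Maximum model size: n/5, rounded half away from zero."""
    if n_subjects < 5:
        raise ValueError(f"need at least 5 subjects for the n/5 cap, got {n_subjects}")
    return math.floor(n_subjects / 5 + 0.5)


@dataclass
class SeverityModel:
    """A fitted (or bundled) linear severity equation for one clinical scale."""

    target: str
    intercept: float
    terms: list[tuple[str, float]]  # ordered (feature name, unstandardized coefficient)
    cap: int | None = None
    p_enter: float | None = None
    p_remove: float | None = None
    bootstrap_B: int | None = None
    seed: int | None = None
    training_n: int | None = None
    adjusted_r2: float | None = None
    f_statistic: float | None = None
    provenance: str = "fitted"

    def __post_init__(self) -> None:
        values = [self.intercept] + [c for _, c in self.terms]
        if not np.all(np.isfinite(values)):
            raise ValueError(f"model for {self.target} has non-finite coefficients")
        if self.cap is not None and len(self.terms) > self.cap:
            raise ValueError(f"{len(self.terms)} terms exceed the cap of {self.cap}")

    @property
    def feature_names(self) -> list[str]:
        return [name for name, _ in self.terms]

    def predict(self, features) -> float | np.ndarray:
        """Evaluate ``intercept + sum(coef * feature)``; unclipped.

        ``features`` is a mapping, Series or DataFrame providing every model
        feature by name. A DataFrame returns one prediction per row.
        """
        if isinstance(features, pd.DataFrame):
            missing = [n for n in self.feature_names if n not in features.columns]
            if missing:
                raise KeyError(f"feature row lacks model feature(s) {missing}")
            out = np.full(len(features), self.intercept)
            for name, coef in self.terms:
                out = out + coef * features[name].to_numpy(dtype=float)
            return out
        missing = [n for n in self.feature_names if n not in features]
        if missing:
            raise KeyError(f"feature row lacks model feature(s) {missing}")
        return float(self.intercept + sum(c * float(features[n]) for n, c in self.terms))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": MODEL_SCHEMA,
            "target": self.target,
            "intercept": self.intercept,
            "terms": [{"feature": n, "coefficient": c} for n, c in self.terms],
            "settings": {
                "cap": self.cap,
                "p_enter": self.p_enter,
                "p_remove": self.p_remove,
                "bootstrap_B": self.bootstrap_B,
                "seed": self.seed,
            },
            "fit": {
                "training_n": self.training_n,
                "adjusted_r2": self.adjusted_r2,
                "f_statistic": self.f_statistic,
            },
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SeverityModel":
        _check_schema(d)
        settings = d.get("settings", {})
        fit = d.get("fit", {})
        return cls(
            target=d["target"],
            intercept=float(d["intercept"]),
            terms=[(t["feature"], float(t["coefficient"])) for t in d["terms"]],
            cap=settings.get("cap"),
            p_enter=settings.get("p_enter"),
            p_remove=settings.get("p_remove"),
            bootstrap_B=settings.get("bootstrap_B"),
            seed=settings.get("seed"),
            training_n=fit.get("training_n"),
            adjusted_r2=fit.get("adjusted_r2"),
            f_statistic=fit.get("f_statistic"),
            provenance=d.get("provenance", "fitted"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SeverityModel":
        return cls.from_dict(json.loads(text))

    def to_equation(self) -> str:
        """Human-readable signed equation, one term per line."""
        lines = [f"{self.target} ="]
        lines.append(_signed(self.intercept))
        for name, coef in self.terms:
            lines.append(f"{_signed(coef)} × {name}")
        return "\n".join(lines)


def _signed(value: float) -> str:
    sign = "-" if math.copysign(1.0, value) < 0 else "+"
    return f"{sign} {abs(value):g}"


_ALLOWED_TOP = {"schema", "target", "intercept", "terms", "settings", "fit", "provenance"}
_ALLOWED_SETTINGS = {"cap", "p_enter", "p_remove", "bootstrap_B", "seed"}
_ALLOWED_FIT = {"training_n", "adjusted_r2", "f_statistic"}


def _check_schema(d: dict) -> None:
    if not isinstance(d, dict):
        raise ValueError("model JSON root must be an object")
    if d.get("schema") != MODEL_SCHEMA:
        raise ValueError(f"$.schema: expected {MODEL_SCHEMA!r}, got {d.get('schema')!r}")
    for key in ("target", "intercept", "terms"):
        if key not in d:
            raise ValueError(f"$.{key}: required field missing")
    for key in d:
        if key not in _ALLOWED_TOP:
            raise ValueError(f"$.{key}: unknown field")
    for i, t in enumerate(d["terms"]):
        extra = set(t) - {"feature", "coefficient"}
        if extra:
            raise ValueError(f"$.terms[{i}].{sorted(extra)[0]}: unknown field")
        if "feature" not in t or "coefficient" not in t:
            raise ValueError(f"$.terms[{i}]: needs 'feature' and 'coefficient'")
    for key in set(d.get("settings", {})) - _ALLOWED_SETTINGS:
        raise ValueError(f"$.settings.{key}: unknown field")
    for key in set(d.get("fit", {})) - _ALLOWED_FIT:
        raise ValueError(f"$.fit.{key}: unknown field")


# ---------------------------------------------------------------------------
# stepwise


def _ols(X: np.ndarray, y: np.ndarray):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_fit(
    X: pd.DataFrame,
    y: pd.Series,
    cap: int,
    p_enter: float = 0.15,
    p_remove: float = 0.15,
    target: str = "",
) -> SeverityModel:
    """Bidirectional stepwise OLS over the survivor pool, capped at *cap* terms.

    Entry uses the partial-F p-value of each candidate added to the current
    model (equivalently the squared-t p-value); removal drops any included
    term whose p-value exceeds ``p_remove``. Ties break on smaller p-value
    then lexicographic feature name. Perfectly collinear candidates are
    skipped with a warning.
    """
    if y.isna().any():
        raise ValueError("y contains missing values")
    if X.shape[1] == 0:
        raise ValueError("no candidate features supplied")
    if cap < 1:
        raise ValueError("cap must be >= 1")

    yv = y.loc[X.index].to_numpy(dtype=float)
    included: list[str] = []

    if np.std(yv) == 0:
        fit = _ols(np.empty((len(yv), 0)), yv)
        return _model_from_fit(target, [], fit, cap, p_enter, p_remove)

    while True:
        changed = False
        # entry
        if len(included) < cap:
            best: tuple[float, str] | None = None
            current = X[included].to_numpy(dtype=float)
            for cand in sorted(set(X.columns) - set(included)):
                trial = np.column_stack([current, X[cand].to_numpy(dtype=float)])
                if np.linalg.matrix_rank(np.column_stack([np.ones(len(yv)), trial])) < trial.shape[1] + 1:
                    logger.warning("skipping collinear candidate %s", cand)
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = _ols(trial, yv)
                p = float(fit.pvalues[-1])
                if np.isnan(p):
                    continue
                if best is None or (p, cand) < best:
                    best = (p, cand)
            if best is not None and best[0] < p_enter:
                included.append(best[1])
                changed = True
        # removal
        while len(included) > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = _ols(X[included].to_numpy(dtype=float), yv)
            pvals = pd.Series(fit.pvalues[1:], index=included)
            worst = pvals.sort_values(ascending=False)
            if worst.iloc[0] > p_remove:
                removed = worst.index[0]
                included.remove(removed)
                changed = True
            else:
                break
        if not changed:
            break

    fit = _ols(X[included].to_numpy(dtype=float), yv)
    return _model_from_fit(target, included, fit, cap, p_enter, p_remove)


def _model_from_fit(target, included, fit, cap, p_enter, p_remove) -> SeverityModel:
    params = np.asarray(fit.params, dtype=float)
    return SeverityModel(
        target=target,
        intercept=float(params[0]),
        terms=list(zip(included, params[1:])),
        cap=cap,
        p_enter=p_enter,
        p_remove=p_remove,
        training_n=int(fit.nobs),
        adjusted_r2=float(fit.rsquared_adj) if included else 0.0,
        f_statistic=float(fit.fvalue) if included else float("nan"),
    )


def best_subset_fit(X: pd.DataFrame, y: pd.Series, size: int) -> list[str]:
    """Exhaustive best subset of exactly *size* features by residual SSE.

    Brute-force reference for validating stepwise selection on small pools
    (combinatorial: keep the candidate count at 10 or below).
    """
    from itertools import combinations

    if X.shape[1] > 15:
        raise ValueError("best-subset enumeration is only sensible for small pools")
    yv = y.loc[X.index].to_numpy(dtype=float)
    best_sse, best_cols = np.inf, None
    for cols in combinations(sorted(X.columns), size):
        fit = _ols(X[list(cols)].to_numpy(dtype=float), yv)
        sse = float(np.sum(fit.resid ** 2))
        if sse < best_sse - 1e-12:
            best_sse, best_cols = sse, cols
    return list(best_cols)


# ---------------------------------------------------------------------------
# bootstrap coefficients


def bootstrap_coefficients(
    features: list[str],
    X: pd.DataFrame,
    y: pd.Series,
    B: int = 1000,
    seed: int = 0,
    aggregate: str = "mean",
    resample: bool = True,
    target: str = "",
    template: SeverityModel | None = None,
) -> SeverityModel:
    """Final coefficients: aggregate of B case-resampled OLS fits.

    The term set is fixed (taken from the stepwise stage); each replicate
    refits plain OLS on an n-of-n resample. Replicates with a singular
    design are skipped and counted; more than half singular raises (the
    term set is too rich for the sample). With ``resample=False`` every
    replicate is the full sample, so any B returns the plain OLS solution.
    """
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    if y.isna().any():
        raise ValueError("y contains missing values")
    Xv = X[list(features)].to_numpy(dtype=float)
    yv = y.loc[X.index].to_numpy(dtype=float)
    n, p = Xv.shape

    rng = np.random.default_rng(seed)
    draws = np.empty((B, p + 1))
    singular = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n) if resample else np.arange(n)
        Xb = np.column_stack([np.ones(n), Xv[idx]])
        if np.linalg.matrix_rank(Xb) < p + 1:
            singular += 1
            draws[b] = np.nan
            continue
        coef, *_ = np.linalg.lstsq(Xb, yv[idx], rcond=None)
        draws[b] = coef
    if singular > B / 2:
        raise ValueError(
            f"{singular}/{B} bootstrap designs were singular; "
            f"the {p}-term model is too rich for n={n}"
        )
    if singular:
        logger.warning("skipped %d singular bootstrap replicate(s)", singular)
    good = draws[~np.isnan(draws).any(axis=1)]
    agg = np.mean(good, axis=0) if aggregate == "mean" else np.median(good, axis=0)

    base = template.to_dict() if template is not None else {}
    fit = _ols(Xv, yv) if p else _ols(np.empty((n, 0)), yv)
    return SeverityModel(
        target=target or (template.target if template else ""),
        intercept=float(agg[0]),
        terms=list(zip(features, agg[1:])),
        cap=base.get("settings", {}).get("cap"),
        p_enter=base.get("settings", {}).get("p_enter"),
        p_remove=base.get("settings", {}).get("p_remove"),
        bootstrap_B=B,
        seed=seed,
        training_n=n,
        adjusted_r2=float(fit.rsquared_adj) if p else 0.0,
        f_statistic=float(fit.fvalue) if p else float("nan"),
    )
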