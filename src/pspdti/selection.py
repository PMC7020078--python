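"""First-stage feature reduction: bootstrap-LASSO stability selection.

For each clinical scale, an L1-penalised least-squares regression is fit on
many bootstrap resamples of the cohort (case resampling, n-of-n with
replacement). A feature *survives* when it receives a nonzero coefficient
in at least ``ceil(tau * B)`` of the ``B`` replicates — with the canonical
settings ``B = 1000`` and ``tau = 0.20``, a survival cutoff of 200
selections. Demographic covariates (age, sex, disease duration) and
imaging-protocol dummies enter the candidate pool exactly like imaging
features, so a scale genuinely driven by diffusion metrics should select
none of them. A final cap check guarantees fewer survivors than subjects.

The penalty inside each replicate is chosen by 5-fold cross-validation
over a 50-point logarithmic grid by default; a fixed-penalty rule is
available where speed matters more than per-replicate tuning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ("age", "sex_M", "disease_duration")


@dataclass
class StandardizeParams:
    """Per-column (mean, sd) of a standardization, for inverting it."""

    mean: pd.Series
    sd: pd.Series
    excluded: list[str] = field(default_factory=list)


def standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, StandardizeParams]:
    """Scale every column to zero mean, unit (sample) SD.

    Zero-variance columns cannot be scaled; they are excluded with a logged
    warning. Raises if nothing remains.
    """
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing values in columns {bad[:8]}; impute or drop first")
    mean = X.mean()
    sd = X.std(ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        logger.warning("excluding %d zero-variance column(s): %s", len(constant), constant[:8])
    keep = [c for c in X.columns if c not in constant]
    if not keep:
        raise ValueError("every column has zero variance; nothing to standardize")
    Z = (X[keep] - mean[keep]) / sd[keep]
    return Z, StandardizeParams(mean=mean[keep], sd=sd[keep], excluded=constant)


def unstandardize(Z: pd.DataFrame, params: StandardizeParams) -> pd.DataFrame:
    """Invert :func:`standardize` on the retained columns."""
    return Z * params.sd + params.mean


def augment_with_covariates(
    X: pd.DataFrame,
    subjects: pd.DataFrame,
    protocol_levels: list[str] | None = None,
) -> pd.DataFrame:
    """Append age, sex indicator, duration and protocol dummies as candidates.

    ``subjects`` rows must align with ``X`` rows (same index). Protocol
    dummies use reference coding (first protocol alphabetically dropped);
    pass ``protocol_levels`` to fix the dummy columns when augmenting a
    subset (e.g. follow-up rows) that may not exhibit every protocol.
    """
    missing_rows = X.index.difference(subjects.index)
    if len(missing_rows):
        raise ValueError(f"no clinical row for record(s) {missing_rows[:5].tolist()}")
    sub = subjects.loc[X.index]
    for col in ("age", "sex", "disease_duration", "protocol"):
        if col not in sub.columns:
            raise ValueError(f"clinical table lacks required covariate column {col!r}")
        if sub[col].isna().any():
            who = sub.index[sub[col].isna()][:5].tolist()
            raise ValueError(f"missing {col!r} for subject(s) {who}")
    out = X.copy()
    out["age"] = sub["age"].astype(float)
    out["sex_M"] = (sub["sex"] == "M").astype(float)
    out["disease_duration"] = sub["disease_duration"].astype(float)
    protocols = protocol_levels or sorted(sub["protocol"].unique())
    unknown = set(sub["protocol"]) - set(protocols)
    if unknown:
        raise ValueError(f"protocol level(s) {sorted(unknown)} missing from protocol_levels")
    for proto in list(protocols)[1:]:  # reference coding
        out[f"protocol_{proto}"] = (sub["protocol"] == proto).astype(float)
    return out


def covariate_columns(X: pd.DataFrame) -> list[str]:
    """Columns of *X* that are covariates rather than imaging features."""
    return [c for c in X.columns if c in COVARIATE_COLUMNS or c.startswith("protocol_")]


@dataclass
class StabilityResult:
    """Outcome of one bootstrap-LASSO stability-selection run."""

    target: str
    B: int
    tau: float
    counts: pd.Series  # per-feature selection counts over the B replicates
    survivors: list[str]
    penalties: np.ndarray  # penalty chosen inside each replicate
    seed: int
    tau_adjusted: float | None = None  # set by cap_check when it tightens tau

    @property
    def cutoff(self) -> int:
        return math.ceil(self.tau * self.B)

    def frequencies(self) -> pd.Series:
        return self.counts / self.B

    def to_dict(self) -> dict:
        return {
            "schema": "pspdti.stability/1",
            "target": self.target,
            "B": self.B,
            "tau": self.tau,
            "tau_adjusted": self.tau_adjusted,
            "seed": self.seed,
            "cutoff": self.cutoff,
            "counts": {k: int(v) for k, v in self.counts.items()},
            "survivors": list(self.survivors),
            "penalties": [float(p) for p in self.penalties],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StabilityResult":
        if d.get("schema") != "pspdti.stability/1":
            raise ValueError(f"unknown stability-result schema {d.get('schema')!r}")
        return cls(
            target=d["target"],
            B=int(d["B"]),
            tau=float(d["tau"]),
            counts=pd.Series(d["counts"], dtype=int),
            survivors=list(d["survivors"]),
            penalties=np.asarray(d["penalties"], dtype=float),
            seed=int(d["seed"]),
            tau_adjusted=d.get("tau_adjusted"),
        )


def _survivors_at(counts: pd.Series, cutoff: int) -> list[str]:
    surv = counts[counts >= cutoff]
    order = sorted(surv.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in order]


def _penalty_grid(Xc: np.ndarray, yc: np.ndarray, n_points: int = 50) -> np.ndarray:
    """Logarithmic grid from the smallest all-zero penalty down 3 decades."""
    n = len(yc)
    alpha_max = np.max(np.abs(Xc.T @ (yc - yc.mean()))) / n
    alpha_max = max(alpha_max, 1e-8)
    return np.logspace(np.log10(alpha_max), np.log10(alpha_max * 1e-3), n_points)


def bootstrap_select(
    X: pd.DataFrame,
    y: pd.Series,
    B: int = 1000,
    tau: float = 0.20,
    penalty_rule: str = "cv",
    fixed_penalty: float | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    target: str = "",
) -> StabilityResult:
    """Bootstrap-LASSO stability selection with the count >= ceil(tau*B) rule.

    Rows with missing ``y`` must already have been removed. ``penalty_rule``
    is ``"cv"`` (per-replicate 5-fold cross-validated penalty over a 50-point
    log grid, the default) or ``"fixed"`` (use ``fixed_penalty``; if None, a
    quarter of the full-sample all-zero penalty).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if tau <= 0:
        raise ValueError("tau must be positive")
    # tau above 1 is legal but unattainable: the survivor set is empty
    if y.isna().any():
        raise ValueError("y contains missing values; remove those rows before selection")
    if penalty_rule not in ("cv", "fixed"):
        raise ValueError(f"unknown penalty_rule {penalty_rule!r}")

    Z, _params = standardize(X)
    cols = list(Z.columns)
    Zv = Z.to_numpy()
    yv = y.loc[Z.index].to_numpy(dtype=float)
    n = len(yv)

    if penalty_rule == "fixed" and fixed_penalty is None:
        fixed_penalty = float(_penalty_grid(Zv, yv)[0]) / 4.0

    rng = np.random.default_rng(seed)
    counts = np.zeros(len(cols), dtype=int)
    penalties = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        Xb, yb = Zv[idx], yv[idx]
        sds = Xb.std(axis=0)
        live = sds > 0
        if not live.all():
            logger.debug("replicate %d: skipping %d zero-variance column(s)", b, (~live).sum())
        Xb = Xb[:, live]
        if penalty_rule == "cv":
            model = LassoCV(
                alphas=_penalty_grid(Xb, yb),
                cv=cv_folds,
                max_iter=5000,
                tol=1e-3,
            )
            with np.errstate(all="ignore"):
                model.fit(Xb, yb)
            alpha = float(model.alpha_)
            coef = model.coef_
        else:
            alpha = float(fixed_penalty)
            model = Lasso(alpha=alpha, max_iter=5000, tol=1e-3)
            model.fit(Xb, yb)
            coef = model.coef_
        penalties[b] = alpha
        nz = np.zeros(len(cols), dtype=bool)
        nz[np.flatnonzero(live)] = coef != 0
        counts += nz

    counts_s = pd.Series(counts, index=cols)
    cutoff = math.ceil(tau * B)
    return StabilityResult(
        target=target,
        B=B,
        tau=tau,
        counts=counts_s,
        survivors=_survivors_at(counts_s, cutoff),
        penalties=penalties,
        seed=seed,
    )


def cap_check(result: StabilityResult, n_subjects: int) -> list[str]:
    """Enforce fewer survivors than subjects, tightening tau if needed.

    If the survivor list already satisfies ``|survivors| < n_subjects`` it is
    returned unchanged (an empty list passes vacuously, with a warning).
    Otherwise tau is raised to the smallest value restoring the bound and
    the adjustment is recorded on the result.
    """
    if not result.survivors:
        logger.warning("stability selection for %s kept no features", result.target or "target")
        return []
    if len(result.survivors) < n_subjects:
        return list(result.survivors)
    # smallest cutoff (hence tau) with fewer survivors than subjects
    original = len(result.survivors)
    for cutoff in sorted(result.counts.unique()):
        surv = _survivors_at(result.counts, int(cutoff))
        if len(surv) < n_subjects:
            result.tau_adjusted = cutoff / result.B
            result.survivors = surv
            logger.warning(
                "survivor count %d >= n=%d; raised tau to %.3f (%d survivors)",
                original, n_subjects, result.tau_adjusted, len(surv),
            )
            return surv
    raise ValueError(
        f"{original} features tie at the maximal selection count; "
        f"no tau keeps fewer than {n_subjects} survivors"
    )
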