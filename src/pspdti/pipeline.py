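"""Staged pipeline: simulate → extract → select → fit → validate.

One master seed deterministically derives a substream per (stage, scale),
so any stage can be rerun in isolation and a manifest fully determines a
run: replaying the same configuration reproduces every output byte for
byte. Each stage writes its intermediates (feature table, stability JSON,
model JSON, evaluation reports) into the run directory.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, generate_cohort, generate_feature_table, records_to_frame
from .evaluate import blind_validate, friedman_compare, kfold_cv, loocv, training_report
from .images import build_feature_table
from .io import (
    read_clinical,
    read_feature_table,
    write_clinical,
    write_feature_table,
    write_json,
    write_model,
)
from .regression import bootstrap_coefficients, feature_cap, stepwise_fit
from .selection import augment_with_covariates, bootstrap_select, cap_check, covariate_columns
from .scales import SCALE_NAMES

logger = logging.getLogger(__name__)


def substream_seed(master: int, *keys: str) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    entropy = [int(master)] + [zlib.crc32(k.encode()) for k in keys]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """Everything a full run needs; YAML-serialisable."""

    output_dir: str = "runs/run0"
    targets: list[str] = field(default_factory=lambda: list(SCALE_NAMES))
    seed: int = 0
    # simulation (ignored when features_csv/clinical_csv are given)
    mode: str = "fast"  # "fast": closed-form features; "volumes": NIfTI extraction
    n_regions: int = 24
    cohort_overrides: dict = field(default_factory=dict)
    # real-mode inputs
    features_csv: str | None = None
    clinical_csv: str | None = None
    # selection / modelling
    B_select: int = 1000
    B_coef: int = 1000
    tau: float = 0.20
    penalty_rule: str = "cv"
    p_enter: float = 0.15
    p_remove: float = 0.15
    kfold: int = 5

    def __post_init__(self) -> None:
        unknown = [t for t in self.targets if t not in SCALE_NAMES]
        if unknown:
            raise ValueError(f"unknown target scale(s) {unknown}; known: {list(SCALE_NAMES)}")
        if (self.features_csv is None) != (self.clinical_csv is None):
            raise ValueError("features_csv and clinical_csv must be given together")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8")


def _simulate(config: PipelineConfig, out: Path):
    overrides = dict(config.cohort_overrides)
    overrides.setdefault("n_regions", config.n_regions)
    cc = CohortConfig(seed=substream_seed(config.seed, "simulate"), **overrides)
    if config.mode == "volumes":
        records, maps, atlas, mask = generate_cohort(cc)
        table = build_feature_table(maps, atlas, mask=mask)
    else:
        table, records = generate_feature_table(cc)
    clinical = records_to_frame(records)
    write_feature_table(out / "features.csv", table)
    write_clinical(out / "clinical.csv", clinical)
    return table, clinical


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the staged flow for every requested scale; returns the run dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "pspdti_version": __version__,
        "config": asdict(config),
        "stages": {},
    }

    try:
        if config.features_csv:
            table = read_feature_table(config.features_csv)
            clinical = read_clinical(config.clinical_csv)
        else:
            table, clinical = _simulate(config, out)
        manifest["stages"]["simulate"] = "ok"

        baseline = clinical[clinical["timepoint"] == "baseline"]
        followup = clinical[clinical["timepoint"] == "followup"]
        levels = sorted(clinical["protocol"].unique())
        X_all = augment_with_covariates(
            table.data.loc[baseline.index], baseline, protocol_levels=levels
        )
        covars = covariate_columns(X_all)

        for scale in config.targets:
            _run_scale(config, out, manifest, scale, table, baseline, followup, X_all, covars)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        write_json(out / "manifest.json", manifest)
        raise
    write_json(out / "manifest.json", manifest)
    return out


def _run_scale(config, out, manifest, scale, table, baseline, followup, X_all, covars):
    y_all = baseline[scale]
    keep = y_all.notna()
    if not keep.any():
        raise ValueError(f"every baseline value of scale {scale} is missing; cannot model it")
    X = X_all.loc[keep]
    y = y_all.loc[keep].astype(float)
    n = len(y)

    # stage: select
    result = bootstrap_select(
        X,
        y,
        B=config.B_select,
        tau=config.tau,
        penalty_rule=config.penalty_rule,
        seed=substream_seed(config.seed, "select", scale),
        target=scale,
    )
    survivors = cap_check(result, n)
    write_json(out / f"stability_{scale}.json", result.to_dict())
    result.frequencies().rename("frequency").to_csv(out / f"frequencies_{scale}.csv")
    manifest["stages"][f"select_{scale}"] = {"survivors": len(survivors)}

    if not survivors:
        logger.warning("%s: no survivors; skipping modelling", scale)
        manifest["stages"][f"fit_{scale}"] = "skipped (no survivors)"
        return

    # stage: fit
    cap = feature_cap(n)
    step = stepwise_fit(
        X[survivors], y, cap=cap, p_enter=config.p_enter, p_remove=config.p_remove, target=scale
    )
    model = bootstrap_coefficients(
        step.feature_names,
        X,
        y,
        B=config.B_coef,
        seed=substream_seed(config.seed, "coef", scale),
        target=scale,
        template=step,
    )
    write_model(out / f"model_{scale}.json", model)
    (out / f"model_{scale}.txt").write_text(model.to_equation() + "\n", encoding="utf-8")
    manifest["stages"][f"fit_{scale}"] = {"terms": len(model.terms)}

    # stage: validate
    reports = {"training": training_report(model, X, y)}
    reports["loocv"] = loocv(model.feature_names, X, y, scale)
    reports["fivefold"] = kfold_cv(
        model.feature_names, X, y, scale,
        k=config.kfold, seed=substream_seed(config.seed, "folds", scale),
    )
    if len(followup):
        levels = sorted(pd.concat([baseline["protocol"], followup["protocol"]]).unique())
        fu_X = augment_with_covariates(
            table.data.loc[followup.index], followup, protocol_levels=levels
        )
        fu_y = followup[scale].astype(float)
        if fu_y.notna().sum() >= 2:
            reports["followup"] = blind_validate(model, fu_X, fu_y)
            fr = _friedman_followup(reports, followup)
            if fr is not None:
                reports["followup"].friedman = fr

    payload = {name: rep.to_dict() for name, rep in reports.items()}
    write_json(out / f"reports_{scale}.json", payload)
    errors = pd.concat(
        {name: rep.per_subject for name, rep in reports.items()}, names=["scheme"]
    )
    errors.to_csv(out / f"errors_{scale}.csv", float_format="%.10g")
    manifest["stages"][f"validate_{scale}"] = {k: round(v.mae, 6) for k, v in reports.items()}


def _friedman_followup(reports, followup) -> tuple[float, float] | None:
    """Paired |error| triples (loocv, fivefold, followup) on the follow-up subjects."""
    fu = reports["followup"].per_subject
    subj = followup.loc[fu.index, "subject_id"]
    cols = {}
    for scheme in ("loocv", "fivefold"):
        per = reports[scheme].per_subject
        base_err = per["error"].abs()
        # baseline record ids are the subject ids themselves
        cols[scheme] = subj.map(base_err).to_numpy()
    cols["followup"] = fu["error"].abs().to_numpy()
    matrix = pd.DataFrame(cols, index=fu.index).dropna()
    if len(matrix) < 2:
        return None
    return friedman_compare(matrix)
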