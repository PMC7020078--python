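"""Shared fixtures: a small synthetic cohort and the 20-seed pipeline study.

The pipeline study (selection → stepwise → bootstrap → CV → blind
application on 20 independently seeded cohorts) is expensive, so it runs
once per session and several tests read off its columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pspdti as p
from pspdti.evaluate import adjusted_r2
from pspdti.regression import _ols

RECOVERY_SEEDS = range(20)
STUDY_B = 200  # bootstrap replicates per stage in the study conditions


@pytest.fixture(scope="session")
def fast_cohort():
    """One 24-region synthetic cohort with every artefact tests may need."""
    cfg = p.CohortConfig.fast(seed=7)
    table, records = p.generate_feature_table(cfg)
    clinical = p.records_to_frame(records)
    atlas, mask = p.generate_atlas(cfg)
    return {
        "config": cfg,
        "table": table,
        "records": records,
        "clinical": clinical,
        "atlas": atlas,
        "mask": mask,
    }


def _run_study_seed(seed: int) -> dict:
    cfg = p.CohortConfig.fast(seed=seed)
    table, records = p.generate_feature_table(cfg)
    clinical = p.records_to_frame(records)
    levels = sorted(clinical["protocol"].unique())
    base = clinical[clinical["timepoint"] == "baseline"]
    X = p.augment_with_covariates(table.data.loc[base.index], base, protocol_levels=levels)
    y = base["UPDRS3"].astype(float)

    atlas, _ = p.generate_atlas(cfg)
    plants = p.planted_feature_columns(cfg, atlas)
    plant_median_cols = [cols[1] for cols in plants.values()]
    oracle = float(_ols(X[plant_median_cols].to_numpy(), y.to_numpy()).rsquared_adj)

    result = p.bootstrap_select(
        X, y, B=STUDY_B, tau=0.20,
        seed=p.substream_seed(seed, "select", "UPDRS3"), target="UPDRS3",
    )
    survivors = p.cap_check(result, len(y))
    covars = p.covariate_columns(X)
    plant_cols_flat = [c for cols in plants.values() for c in cols]
    noise_cols = [c for c in X.columns if c not in plant_cols_flat and c not in covars]
    freqs = result.frequencies()

    step = p.stepwise_fit(X[survivors], y, cap=p.feature_cap(len(y)), target="UPDRS3")
    model = p.bootstrap_coefficients(
        step.feature_names, X, y, B=STUDY_B,
        seed=p.substream_seed(seed, "coef", "UPDRS3"), target="UPDRS3", template=step,
    )
    rep_train = p.training_report(model, X, y)
    rep_loo = p.loocv(model.feature_names, X, y, "UPDRS3")
    heldout = adjusted_r2(
        rep_loo.per_subject["observed"], rep_loo.per_subject["predicted"], len(model.terms)
    )

    followup = clinical[clinical["timepoint"] == "followup"]
    fu_X = p.augment_with_covariates(
        table.data.loc[followup.index], followup, protocol_levels=levels
    )
    rep_fu = p.blind_validate(model, fu_X, followup["UPDRS3"].astype(float))

    return {
        "seed": seed,
        "n_survivors": len(survivors),
        "plants_selected": sum(any(c in survivors for c in cols) for cols in plants.values()),
        "plants_in_model": sum(
            any(c in model.feature_names for c in cols) for cols in plants.values()
        ),
        "covariates_in_model": sum(1 for c in model.feature_names if c in covars),
        "covariate_freq": float(freqs[covars].mean()),
        "noise_freq": float(freqs[noise_cols].mean()),
        "oracle_adj_r2": oracle,
        "heldout_adj_r2": float(heldout),
        "training_mae": rep_train.mae,
        "loocv_mae": rep_loo.mae,
        "followup_mae": rep_fu.mae,
        "mae_ratio": rep_fu.mae / rep_loo.mae,
    }


@pytest.fixture(scope="session")
def recovery_study():
    """Select → fit → validate on 20 independently seeded default cohorts."""
    rows = [_run_study_seed(seed) for seed in RECOVERY_SEEDS]
    return pd.DataFrame(rows).set_index("seed")
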