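"""Adjusted R², MAE/MAE% conventions, CV schemes, blind application, Friedman."""

from itertools import permutations, product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pspdti as p
from pspdti.evaluate import _friedman_statistic, crossval
from pspdti.scales import get_scale


# ---------------------------------------------------------------------------
# adjusted R²


def test_adjusted_r2_examples_and_errors():
    rng = np.random.default_rng(0)
    obs = rng.normal(size=20)
    assert p.adjusted_r2(obs, obs, 5) == pytest.approx(1.0)

    # R² = 0: predicting the mean
    obs6 = np.arange(6.0)
    assert p.adjusted_r2(obs6, np.full(6, obs6.mean()), 1) == pytest.approx(-0.25)

    # scaled-residual construction with R² = 0.9054 at n=53, p=11
    obs53 = rng.normal(size=53)
    c = 1.0 - np.sqrt(1.0 - 0.9054)
    pred = obs53.mean() + c * (obs53 - obs53.mean())
    assert p.adjusted_r2(obs53, pred, 11) == pytest.approx(0.88, abs=0.005)

    with pytest.raises(ValueError, match="n=5"):
        p.adjusted_r2(np.arange(5.0), np.arange(5.0), 4)


def test_adjusted_r2_affine_invariance():
    rng = np.random.default_rng(1)
    obs = rng.normal(size=30)
    pred = obs + 0.3 * rng.normal(size=30)
    base = p.adjusted_r2(obs, pred, 3)
    assert p.adjusted_r2(5 * obs - 2, 5 * pred - 2, 3) == pytest.approx(base, abs=1e-12)


# ---------------------------------------------------------------------------
# MAE / MAE%


def test_mae_percent_conventions():
    """Printed MAEs reproduce the printed percent values under the scale-maximum
    convention: 6.1 on UPDRS-III -> 5.6%; 0.4 on MHY -> 8.0%."""
    obs = np.linspace(20, 90, 10)
    mae, _, pct, pct_sd = p.mae_stats(obs, obs + 6.1, get_scale("UPDRS3"))
    assert mae == pytest.approx(6.1)
    assert round(pct, 1) == 5.6
    assert pct_sd == pytest.approx(0.0)

    obs = np.linspace(1.5, 4.5, 8)
    mae, _, pct, _ = p.mae_stats(obs, obs - 0.4, get_scale("MHY"))
    assert (mae, round(pct, 1)) == (pytest.approx(0.4), 8.0)

    # LEDD uses per-subject observed denominators
    obs = np.array([400.0, 800.0])
    _, _, pct, _ = p.mae_stats(obs, obs + np.array([40.0, 40.0]), get_scale("LEDD"))
    assert pct == pytest.approx((10.0 + 5.0) / 2)
    with pytest.raises(ValueError, match="zero observed"):
        p.mae_stats(np.array([0.0, 5.0]), np.array([1.0, 2.0]), get_scale("LEDD"))

    mae, sd, pct, pct_sd = p.mae_stats(obs, obs, get_scale("LEDD"))
    assert (mae, sd, pct, pct_sd) == (0, 0, 0, 0)


def test_mae_percent_depends_only_on_absolute_errors():
    scale = get_scale("UPDRS3")
    errs = np.array([1.0, 4.0, 2.5, 7.0])
    obs_a = np.array([10.0, 50.0, 70.0, 90.0])
    obs_b = np.array([90.0, 20.0, 40.0, 60.0])
    _, _, pct_a, _ = p.mae_stats(obs_a, obs_a + errs, scale)
    _, _, pct_b, _ = p.mae_stats(obs_b, obs_b - errs, scale)
    assert pct_a == pytest.approx(pct_b) == pytest.approx(errs.mean() / 108 * 100)


# ---------------------------------------------------------------------------
# cross-validation


@pytest.fixture(scope="module")
def noisy_linear():
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.normal(size=(24, 3)), columns=["a", "b", "c"],
                     index=[f"r{i}" for i in range(24)])
    y = pd.Series(30 + 8 * X["a"].to_numpy() + 2 * rng.normal(size=24),
                  index=X.index, name="UPDRS3").clip(0, 108)
    return X, y


def test_loocv_exact_model_class(noisy_linear):
    X, _ = noisy_linear
    y = pd.Series(10 + 2 * X["a"] - X["b"], index=X.index)
    rep = p.loocv(["a", "b"], X, y, "UPDRS3")
    assert rep.mae == pytest.approx(0.0, abs=1e-8)
    assert rep.mean_adjusted_r2 == pytest.approx(1.0)
    assert rep.n == len(y)


def test_loocv_fold_counts_respect_missingness(fast_cohort):
    clinical = fast_cohort["clinical"]
    base = clinical[clinical["timepoint"] == "baseline"]
    X = fast_cohort["table"].data.loc[base.index]
    feats = list(X.columns[:3])
    rep_updrs = p.loocv(feats, X, base["UPDRS3"].astype(float), "UPDRS3")
    rep_pigd = p.loocv(feats, X, base["PIGD"].astype(float), "PIGD")
    assert rep_updrs.n == 53
    assert rep_pigd.n == 50  # three missing PIGD rows excluded listwise


def test_kfold_determinism_boundaries_and_loocv_equivalence(noisy_linear):
    X, y = noisy_linear
    r1 = p.kfold_cv(["a"], X, y, "UPDRS3", k=5, seed=3)
    r2 = p.kfold_cv(["a"], X, y, "UPDRS3", k=5, seed=3)
    pd.testing.assert_frame_equal(r1.per_subject, r2.per_subject)
    assert r1.to_dict() == r2.to_dict()

    loo = p.loocv(["a"], X, y, "UPDRS3")
    kn = p.kfold_cv(["a"], X, y, "UPDRS3", k=len(y), seed=0)
    pd.testing.assert_frame_equal(
        loo.per_subject.sort_index(), kn.per_subject.sort_index()
    )
    with pytest.raises(ValueError, match="exceeds"):
        p.kfold_cv(["a"], X, y, "UPDRS3", k=len(y) + 1, seed=0)
    with pytest.raises(ValueError, match="k must be"):
        p.kfold_cv(["a"], X, y, "UPDRS3", k=1, seed=0)


def test_fivefold_mae_consistent_with_loocv(noisy_linear):
    X, y = noisy_linear
    loo = p.loocv(["a"], X, y, "UPDRS3")
    five = p.kfold_cv(["a"], X, y, "UPDRS3", k=5, seed=1)
    spread = max(loo.mae_sd, five.mae_sd)
    assert abs(five.mae - loo.mae) <= 2 * spread


def test_report_summary_recomputes_from_per_subject_rows(noisy_linear):
    X, y = noisy_linear
    rep = p.loocv(["a"], X, y, "UPDRS3")
    err = rep.per_subject["error"].abs()
    assert rep.mae == pytest.approx(err.mean(), abs=1e-9)
    assert rep.mae_sd == pytest.approx(err.std(ddof=1), abs=1e-9)
    assert rep.mae_pct == pytest.approx((err / 108 * 100).mean(), abs=1e-9)
    assert np.allclose(
        rep.per_subject["error"],
        rep.per_subject["predicted"] - rep.per_subject["observed"],
    )


# ---------------------------------------------------------------------------
# blind application


def test_blind_validate_on_training_rows_equals_training_residuals(noisy_linear):
    X, y = noisy_linear
    model = p.bootstrap_coefficients(["a"], X, y, B=1, seed=0, resample=False, target="UPDRS3")
    train = p.training_report(model, X, y)
    blind = p.blind_validate(model, X, y)
    pd.testing.assert_frame_equal(train.per_subject, blind.per_subject)
    assert blind.mae == pytest.approx(train.mae)


def test_blind_validate_followup_counts(fast_cohort):
    clinical = fast_cohort["clinical"]
    followup = clinical[clinical["timepoint"] == "followup"]
    X = fast_cohort["table"].data.loc[followup.index]
    feats = list(X.columns[:2])
    model = p.SeverityModel(target="UPDRS3", intercept=0.0, terms=[(f, 1.0) for f in feats])
    rep = p.blind_validate(model, X, followup["UPDRS3"].astype(float))
    assert rep.n == 15
    model_pigd = p.SeverityModel(target="PIGD", intercept=0.0, terms=[(feats[0], 1.0)])
    rep_pigd = p.blind_validate(model_pigd, X, followup["PIGD"].astype(float))
    assert rep_pigd.n == 15 - followup["PIGD"].isna().sum()


# ---------------------------------------------------------------------------
# Friedman


def test_friedman_degenerate_and_monotone():
    identical = np.tile(np.array([[1.0, 1.0, 1.0]]), (5, 1))
    stat, pval = p.friedman_compare(identical)
    assert stat == 0.0 and pval == 1.0

    k = 3
    stats_grid = [0.5, 2.0, 5.0, 9.0]
    ps = [float(stats.chi2.sf(s, k - 1)) for s in stats_grid]
    assert all(a > b for a, b in zip(ps, ps[1:]))

    with pytest.raises(ValueError, match="incomplete"):
        p.friedman_compare(np.array([[1.0, np.nan], [2.0, 3.0]]))


def test_friedman_matches_scipy_and_exact_permutation_oracle():
    """4 subjects x 3 schemes: statistic agrees with an independent library
    computation and the exact p with a brute-force permutation enumeration."""
    matrix = np.array(
        [[1.0, 2.0, 3.0], [2.0, 6.0, 4.0], [5.0, 1.0, 9.0], [3.0, 8.0, 7.0]]
    )
    stat, p_exact = p.friedman_compare(matrix, exact=True)
    scipy_stat, _ = stats.friedmanchisquare(*matrix.T)
    assert stat == pytest.approx(scipy_stat, abs=1e-10)

    # independent enumeration: permute each block's values over schemes
    null = []
    for rows in product(*[list(permutations(row)) for row in matrix]):
        m = np.array(rows, dtype=float)
        s, _ = stats.friedmanchisquare(*m.T)
        null.append(s)
    null = np.asarray(null)
    oracle_p = float(np.mean(null >= stat - 1e-12))
    assert p_exact == pytest.approx(oracle_p, abs=1e-12)
    assert len(null) == 6**4


def test_crossval_skips_singular_folds(caplog):
    import logging

    # column "flag" is nonzero only in row 0: the fold holding out row 0
    # trains on a zero-variance column (singular design) and is skipped
    X = pd.DataFrame(
        {"a": [1.0, 2.0, 4.0, 3.0, 5.0, 2.5], "flag": [1.0, 0, 0, 0, 0, 0]},
        index=[f"r{i}" for i in range(6)],
    )
    y = pd.Series(np.arange(6.0) + 10, index=X.index, name="UPDRS3")
    with caplog.at_level(logging.WARNING):
        rep = crossval(
            ["a", "flag"], X, y, "UPDRS3",
            folds=[np.array([i]) for i in range(6)], scheme="loocv",
        )
    assert rep.skipped_folds == 1
    assert rep.n == 5
    assert "singular" in caplog.text

    X_all_dup = X.assign(dup=X["a"]).drop(columns="flag")
    with pytest.raises(ValueError, match="every fold"):
        crossval(["a", "dup"], X_all_dup, y, "UPDRS3",
                 folds=[np.array([i]) for i in range(6)], scheme="loocv")
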