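"""Feature cap, stepwise selection, bootstrap coefficients, model export."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pspdti as p
from pspdti.naming import is_feature_name
from pspdti.regression import _ols


@pytest.mark.parametrize("n,expected", [(53, 11), (50, 10), (47, 9), (55, 11), (5, 1)])
def test_feature_cap_rounds_half_away_from_zero(n, expected):
    assert p.feature_cap(n) == expected


def test_feature_cap_needs_five_subjects():
    with pytest.raises(ValueError, match="at least 5"):
        p.feature_cap(4)


def _orthonormal_design(n, k, seed):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(n, k)))
    return pd.DataFrame(q, columns=[f"x{i}" for i in range(k)])


def test_stepwise_zero_variance_y_gives_intercept_only():
    X = _orthonormal_design(20, 4, 0)
    model = p.stepwise_fit(X, pd.Series(np.full(20, 7.0), index=X.index), cap=3)
    assert model.terms == []
    assert model.intercept == pytest.approx(7.0)


def test_stepwise_enters_dominant_feature_first_and_matches_best_subset():
    """Orthonormal design, y = 3*x7 + tiny noise: x7 enters first and the
    final term set equals the exhaustive best subset of the same size."""
    X = _orthonormal_design(40, 10, 1)
    rng = np.random.default_rng(2)
    y = pd.Series(3.0 * X["x7"].to_numpy() + 0.01 * rng.normal(size=40), index=X.index)
    model = p.stepwise_fit(X, y, cap=5, p_enter=0.01, p_remove=0.01)
    assert model.terms[0][0] == "x7"
    assert set(model.feature_names) == set(p.best_subset_fit(X, y, len(model.terms)))


def test_stepwise_equals_best_subset_over_random_orthogonal_trials():
    """50 random orthogonal designs with sparse truth: stepwise = best subset."""
    matches = 0
    for trial in range(50):
        rng = np.random.default_rng(100 + trial)
        n, k = 40, 8
        X = _orthonormal_design(n, k, 200 + trial)
        truth = rng.choice(k, size=2, replace=False)
        beta = np.zeros(k)
        beta[truth] = rng.uniform(1.0, 3.0, size=2) * rng.choice([-1, 1], size=2)
        y = pd.Series(X.to_numpy() @ beta + 0.05 * rng.normal(size=n), index=X.index)
        model = p.stepwise_fit(X, y, cap=4, p_enter=0.05, p_remove=0.05)
        best = p.best_subset_fit(X, y, len(model.terms)) if model.terms else []
        assert set(model.feature_names) == set(best)
        matches += 1
    assert matches == 50


def test_collinear_candidate_skipped(caplog):
    X = _orthonormal_design(30, 4, 3)
    X["x0_dup"] = X["x0"]
    rng = np.random.default_rng(4)
    y = pd.Series(2.0 * X["x0"].to_numpy() + 0.01 * rng.normal(size=30), index=X.index)
    with caplog.at_level(logging.WARNING):
        model = p.stepwise_fit(X, y, cap=3, p_enter=0.01, p_remove=0.01)
    assert "collinear" in caplog.text
    assert ("x0" in model.feature_names) != ("x0_dup" in model.feature_names)


def test_stepwise_respects_cap(fast_cohort):
    clinical = fast_cohort["clinical"]
    base = clinical[clinical["timepoint"] == "baseline"]
    X = fast_cohort["table"].data.loc[base.index]
    y = base["UPDRS3"].astype(float)
    model = p.stepwise_fit(X.iloc[:, :40], y, cap=11)
    assert len(model.terms) <= 11


def test_bootstrap_coefficients_degenerate_and_exact():
    rng = np.random.default_rng(5)
    X = pd.DataFrame({"x1": rng.normal(size=30)})
    y_exact = pd.Series(2.0 + 3.0 * X["x1"].to_numpy(), index=X.index)

    # full-sample "resample": equals plain OLS for any B
    ols = _ols(X.to_numpy(), y_exact.to_numpy())
    m = p.bootstrap_coefficients(["x1"], X, y_exact, B=1, seed=0, resample=False)
    assert m.intercept == pytest.approx(ols.params[0], abs=1e-10)
    assert m.terms[0][1] == pytest.approx(ols.params[1], abs=1e-10)

    # noise-free linear truth: every resample reproduces it exactly
    m2 = p.bootstrap_coefficients(["x1"], X, y_exact, B=50, seed=1)
    assert m2.intercept == pytest.approx(2.0, abs=1e-8)
    assert m2.terms[0][1] == pytest.approx(3.0, abs=1e-8)


def test_bootstrap_coefficients_singular_designs_raise():
    X = pd.DataFrame({"a": np.ones(10), "b": np.ones(10)})
    y = pd.Series(np.arange(10.0))
    with pytest.raises(ValueError, match="singular"):
        p.bootstrap_coefficients(["a", "b"], X, y, B=20, seed=0)


def test_bootstrap_coefficient_bias_is_negligible():
    """Known slopes, B=200, 20 seeds: mean bias within 2 Monte-Carlo SEs of 0."""
    true = np.array([1.0, 2.0, -1.0])
    est = []
    for seed in range(20):
        rng = np.random.default_rng(300 + seed)
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        y = pd.Series(
            true[0] + X.to_numpy() @ true[1:] + 0.5 * rng.normal(size=50), index=X.index
        )
        m = p.bootstrap_coefficients(["a", "b"], X, y, B=200, seed=seed)
        est.append([m.intercept, m.terms[0][1], m.terms[1][1]])
    est = np.asarray(est)
    bias = est.mean(axis=0) - true
    se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
    assert np.all(np.abs(bias) <= 2 * se + 1e-12)


def test_predict_examples_and_errors():
    toy = p.SeverityModel(target="toy", intercept=1.0, terms=[("a", 2.0), ("b", -0.5)])
    assert toy.predict({"a": 3.0, "b": 4.0}) == pytest.approx(5.0)
    empty = p.SeverityModel(target="toy", intercept=-2.5, terms=[])
    assert empty.predict({"anything": 9.9}) == pytest.approx(-2.5)
    with pytest.raises(KeyError, match="'b'"):
        toy.predict({"a": 1.0})


@settings(max_examples=50, derandomize=True)
@given(data=st.data())
def test_predict_is_affine(data):
    names = ["f1", "f2", "f3"]
    coefs = [data.draw(st.floats(-10, 10)) for _ in names]
    model = p.SeverityModel(target="t", intercept=data.draw(st.floats(-5, 5)),
                            terms=list(zip(names, coefs)))
    x = {n: data.draw(st.floats(-100, 100)) for n in names}
    y = {n: data.draw(st.floats(-100, 100)) for n in names}
    zero = {n: 0.0 for n in names}
    lhs = model.predict(x) + model.predict(y) - model.predict(zero)
    rhs = model.predict({n: x[n] + y[n] for n in names})
    assert lhs == pytest.approx(rhs, abs=1e-9 * max(1.0, abs(rhs)))


def test_model_json_round_trip_and_schema_errors():
    models = p.bundled_reference_models()
    m = models["PIGD"]
    assert p.SeverityModel.from_json(m.to_json()).to_dict() == m.to_dict()

    payload = m.to_dict()
    payload["bogus"] = 1
    with pytest.raises(ValueError, match=r"\$\.bogus"):
        p.SeverityModel.from_dict(payload)
    payload = m.to_dict()
    payload["settings"]["bogus"] = 1
    with pytest.raises(ValueError, match=r"\$\.settings\.bogus"):
        p.SeverityModel.from_dict(payload)


def test_equation_rendering():
    m = p.SeverityModel(target="toy", intercept=-0.0, terms=[("a", -0.0), ("b", 1.5)])
    lines = m.to_equation().splitlines()
    assert lines[0] == "toy ="
    assert lines[1] == "- 0"  # negative zero keeps its sign
    assert lines[2].startswith("- 0 ×")
    assert lines[3] == "+ 1.5 × b"


def test_bundled_reference_models_shape_and_values():
    models = p.bundled_reference_models()
    assert set(models) == {"UPDRS3", "PIGD", "MHY", "LEDD"}
    for m in models.values():
        assert len(m.terms) == 11
        assert all(is_feature_name(name) for name in m.feature_names)
    updrs = dict(models["UPDRS3"].terms)
    assert updrs["FA90_GP_L"] == 28.3
    ledd = models["LEDD"]
    assert len(ledd.to_equation().splitlines()) == 1 + 1 + 11  # header, intercept, terms
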