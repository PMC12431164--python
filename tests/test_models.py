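"""Logistic and forest model machinery."""

import numpy as np
import pandas as pd
import pytest

from psyreadmit import ReadmissionForest, ReadmissionLogit, site_defaults, simulate_instances
from psyreadmit.design import build_design

from conftest import random_instance_table


def test_intercept_only_fit_recovers_logit_of_prevalence(fh_instances):
    """With 25% positive labels and no informative predictors, the fitted
    intercept of an intercept-only model is ln(1/3)."""
    df = fh_instances.head(400).copy()
    df["readmitted"] = [i % 4 == 0 for i in range(400)]
    # neutralise all predictors by making them constant
    for col in ("age", "los"):
        df[col] = 10
    for col in ("psychosis", "mood", "anxiety", "sud"):
        df[col] = False
    df["sex"] = "female"
    df["race"] = "White"
    res = ReadmissionLogit(df).fit()
    assert res.params["const"] == pytest.approx(np.log(1 / 3), abs=1e-6)


def test_logistic_matches_independent_reference():
    """Agreement with an independently optimised logistic fit to 1e-6 in the
    coefficients on 50 random small datasets."""
    from sklearn.linear_model import LogisticRegression

    rng = np.random.default_rng(17)
    for _ in range(50):
        df = random_instance_table(200, rng, prevalence=0.4)
        res = ReadmissionLogit(df).fit()
        X = build_design(df).to_numpy()
        y = df["readmitted"].astype(int).to_numpy()
        ref = LogisticRegression(
            C=np.inf, max_iter=10_000, tol=1e-12, solver="newton-cholesky"
        ).fit(X, y)
        ours = res.params.drop("const").to_numpy()
        np.testing.assert_allclose(ours, ref.coef_[0], atol=1e-6)
        np.testing.assert_allclose(res.params["const"], ref.intercept_[0], atol=1e-6)


def test_integer_weights_equal_replication():
    rng = np.random.default_rng(23)
    df = random_instance_table(150, rng, prevalence=0.35)
    w = rng.integers(1, 4, size=len(df)).astype(float)
    weighted = ReadmissionLogit(df, weights=w).fit()
    replicated = df.loc[df.index.repeat(w.astype(int))].reset_index(drop=True)
    repfit = ReadmissionLogit(replicated).fit()
    np.testing.assert_allclose(
        weighted.params.to_numpy(), repfit.params.to_numpy(), atol=1e-8
    )


def test_uniform_weight_scaling_leaves_coefficients_unchanged():
    rng = np.random.default_rng(29)
    df = random_instance_table(200, rng)
    a = ReadmissionLogit(df, weights=np.full(len(df), 1.0)).fit()
    b = ReadmissionLogit(df, weights=np.full(len(df), 2.0)).fit()
    c = ReadmissionLogit(df).fit()
    np.testing.assert_allclose(a.params.to_numpy(), b.params.to_numpy(), atol=1e-12)
    np.testing.assert_allclose(a.params.to_numpy(), c.params.to_numpy(), atol=1e-12)


def test_one_class_labels_error():
    rng = np.random.default_rng(31)
    df = random_instance_table(50, rng)
    df["readmitted"] = True
    with pytest.raises(ValueError, match="single class"):
        ReadmissionLogit(df)


def test_perfect_separation_flagged():
    rng = np.random.default_rng(37)
    df = random_instance_table(120, rng)
    df["readmitted"] = df["los"] > df["los"].median()
    res = ReadmissionLogit(df).fit()
    assert res.separation
    assert len(res.params) == 11  # still returned


def test_odds_ratio_table_shape_and_consistency():
    rng = np.random.default_rng(41)
    df = random_instance_table(400, rng)
    res = ReadmissionLogit(df).fit()
    tab = res.odds_ratio_table()
    assert list(tab["predictor"]) == list(build_design(df).columns)
    assert (tab["ci_low"] <= tab["odds_ratio"]).all()
    assert (tab["odds_ratio"] <= tab["ci_high"]).all()
    np.testing.assert_allclose(
        tab["odds_ratio"], np.exp(res.params.drop("const")), rtol=1e-12
    )
    assert "Logistic readmission model" in res.summary()


def test_logistic_predict_schema_mismatch_names_column():
    rng = np.random.default_rng(43)
    df = random_instance_table(100, rng)
    res = ReadmissionLogit(df).fit()
    with pytest.raises(KeyError, match="los"):
        res.predict(df.drop(columns=["los"]))


def test_logit_score_half_at_zero_linear_predictor():
    rng = np.random.default_rng(47)
    df = random_instance_table(100, rng)
    res = ReadmissionLogit(df).fit()
    res.params[:] = 0.0
    assert np.allclose(res.predict(df), 0.5)


# ---------------------------------------------------------------------------
# forest
# ---------------------------------------------------------------------------


def _threshold_labeled(n, seed):
    rng = np.random.default_rng(seed)
    df = random_instance_table(n, rng)
    df["readmitted"] = df["los"] > 7
    if df["readmitted"].nunique() < 2:  # pragma: no cover
        df.loc[df.index[0], "readmitted"] = ~df["readmitted"].iloc[0]
    return df


def test_forest_learns_single_split_rule():
    df = _threshold_labeled(2000, 53)
    res = ReadmissionForest(df, n_trees=200, seed=1).fit()
    assert res.oob_accuracy > 0.95
    from psyreadmit.metrics import compute_auc

    scores = res.predict(df)
    assert compute_auc(scores, df["readmitted"].astype(int).to_numpy()) > 0.99


def test_forest_oob_matches_majority_baseline_on_noise():
    rng = np.random.default_rng(59)
    df = random_instance_table(2000, rng, prevalence=0.3)
    res = ReadmissionForest(df, n_trees=200, seed=2).fit()
    majority = max(df["readmitted"].mean(), 1 - df["readmitted"].mean())
    assert res.oob_accuracy == pytest.approx(majority, abs=0.03)


def test_forest_deterministic_given_seed():
    df = _threshold_labeled(300, 61)
    a = ReadmissionForest(df, n_trees=50, seed=9).fit()
    b = ReadmissionForest(df, n_trees=50, seed=9).fit()
    np.testing.assert_array_equal(a.predict(df), b.predict(df))
    assert a.oob_accuracy == b.oob_accuracy


def test_forest_small_n_rejected():
    df = _threshold_labeled(300, 67).head(8)
    with pytest.raises(ValueError, match="at least 10"):
        ReadmissionForest(df)


def test_constant_weights_match_unweighted_forest():
    df = _threshold_labeled(300, 71)
    a = ReadmissionForest(df, n_trees=50, seed=3).fit()
    b = ReadmissionForest(df, weights=np.full(len(df), 2.5), n_trees=50, seed=3).fit()
    np.testing.assert_array_equal(a.predict(df), b.predict(df))


def test_permutation_importance_dominant_and_noise():
    """The sole predictive variable shows a substantial (>0.1) accuracy drop;
    untouched noise variables stay within +-0.01 of zero."""
    df = _threshold_labeled(2000, 73)
    res = ReadmissionForest(df, n_trees=300, seed=4).fit()
    imp = res.permutation_importance(n_permutations=5, seed=4).set_index("predictor")
    assert imp.loc["los", "importance"] > 0.1
    for noise_var in ("age", "sex", "race", "psychosis", "mood", "anxiety", "sud"):
        assert abs(imp.loc[noise_var, "importance"]) < 0.01, noise_var


def test_permutation_importance_constant_column_zero():
    df = _threshold_labeled(500, 79)
    df["anxiety"] = False  # constant column
    res = ReadmissionForest(df, n_trees=100, seed=5).fit()
    imp = res.permutation_importance(n_permutations=3, seed=5).set_index("predictor")
    assert imp.loc["anxiety", "importance"] == 0.0


def test_missing_sex_rows_dropped_from_modeling():
    rng = np.random.default_rng(83)
    df = random_instance_table(200, rng)
    df.loc[df.index[:20], "sex"] = "missing"
    res = ReadmissionLogit(df).fit()
    assert res.nobs == 180
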