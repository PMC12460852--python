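"""LASSO logistic path, forward stepwise selection, comparison classifiers."""

import numpy as np
import pandas as pd
import pytest

from edemarec.models import (SeparationWarning, comparison_classifiers,
                             fit_lasso_logistic, forward_stepwise_logistic,
                             irls_logistic, kkt_residual, lasso_logistic_path,
                             select_features_chain, stratified_folds,
                             validate_cohort_table)
from edemarec.phantom import FEATURE_NAMES, simulate_feature_cohort


def _standardize(X):
    return (X - X.mean(axis=0)) / X.std(axis=0)


def test_cohort_table_pairing_validated():
    df = simulate_feature_cohort(5, seed=0)
    validate_cohort_table(df)
    with pytest.raises(ValueError, match="exactly one rec"):
        validate_cohort_table(df.iloc[:-1])


def test_all_zero_solution_at_lambda_max():
    df = simulate_feature_cohort(20, seed=1)
    res = lasso_logistic_path(df, list(FEATURE_NAMES), folds=5, seed=0)
    assert np.all(res.coef_path[0] == 0.0)
    assert res.lambda_grid[0] > res.lambda_grid[-1]
    # and just above lambda_max everything stays zero too
    y = df["label"].to_numpy(float)
    X = _standardize(df[list(FEATURE_NAMES)].to_numpy(float))
    _, beta, _ = fit_lasso_logistic(X, y, res.lambda_grid[0] * 1.01)
    assert np.all(beta == 0.0)


def test_kkt_conditions_along_path():
    df = simulate_feature_cohort(24, seed=2)
    res = lasso_logistic_path(df, list(FEATURE_NAMES), folds=5, seed=3)
    assert res.kkt_max_residual < 1e-6
    # independent spot check on a middle lambda
    y = df["label"].to_numpy(float)
    X = _standardize(df[list(FEATURE_NAMES)].to_numpy(float))
    i = 50
    assert kkt_residual(X, y, res.intercept_path[i], res.coef_path[i],
                        res.lambda_grid[i]) < 1e-6


def test_lambda_to_zero_matches_unpenalized_irls(rng):
    n = 60
    x = _standardize(rng.normal(size=(n, 1)))
    eta = 0.9 * x[:, 0]
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
    b0, b, ok = fit_lasso_logistic(x, y, 1e-10)
    beta, _, _, conv = irls_logistic(x, y)
    assert ok and conv
    assert abs(b[0] - beta[1]) < 1e-4
    assert abs(b0 - beta[0]) < 1e-4


def test_duplicated_features_share_the_coefficient():
    """Two identical columns: their L1 coefficients sum to roughly the
    single-feature coefficient, and the selected set is nonempty."""
    rng = np.random.default_rng(4)
    n = 80
    z = rng.normal(size=n)
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-1.5 * z))).astype(float)
    df = pd.DataFrame({"case_id": np.repeat(np.arange(n // 2), 2),
                       "subvolume": ["rec", "no_rec"] * (n // 2),
                       "label": y, "f1": z, "f2": z,
                       "noise": rng.normal(size=n)})
    res = lasso_logistic_path(df, ["f1", "f2", "noise"], folds=5, seed=1)
    assert res.selected_features
    dup_sum = res.coef_at_min[0] + res.coef_at_min[1]
    single = lasso_logistic_path(df, ["f1", "noise"], folds=5, seed=1)
    assert dup_sum == pytest.approx(single.coef_at_min[0], rel=0.15)


def test_lasso_input_validation():
    df = simulate_feature_cohort(10, seed=5)
    with pytest.raises(ValueError, match="at least 2"):
        lasso_logistic_path(df, ["meanADC"])
    bad = df.copy()
    bad["label"] = 2
    with pytest.raises(ValueError, match="binary"):
        lasso_logistic_path(bad, ["meanADC", "maxiADC"])
    const = df.copy()
    const["meanADC"] = 1.0
    with pytest.raises(ValueError, match="constant"):
        lasso_logistic_path(const, ["meanADC", "maxiADC"])


def test_cv_is_deterministic_given_seed():
    df = simulate_feature_cohort(16, seed=6)
    a = lasso_logistic_path(df, list(FEATURE_NAMES), folds=5, seed=42)
    b = lasso_logistic_path(df, list(FEATURE_NAMES), folds=5, seed=42)
    assert a.lambda_min == b.lambda_min
    assert np.array_equal(a.cv_mean, b.cv_mean)
    c = lasso_logistic_path(df, list(FEATURE_NAMES), folds=5, seed=43)
    assert not np.array_equal(a.cv_mean, c.cv_mean)


def test_stratified_folds_balance():
    y = np.r_[np.zeros(30, int), np.ones(30, int)]
    folds = stratified_folds(y, 10, seed=0)
    for f in range(10):
        sel = folds == f
        assert sel.sum() == 6
        assert y[sel].sum() == 3


def test_lasso_agrees_with_sklearn_at_fixed_lambda(rng):
    from sklearn.linear_model import LogisticRegression

    n, p = 100, 4
    X = _standardize(rng.normal(size=(n, p)))
    eta = X @ np.array([1.0, -0.5, 0.0, 0.0])
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
    lam = 0.02
    b0, b, _ = fit_lasso_logistic(X, y, lam)
    sk = LogisticRegression(penalty="l1", C=1.0 / (n * lam), solver="liblinear",
                            tol=1e-10, max_iter=10000).fit(X, y)
    assert np.allclose(b, sk.coef_[0], atol=2e-4)
    assert b0 == pytest.approx(sk.intercept_[0], abs=2e-3)


# ---------------------------------------------------------------------------
# Forward stepwise


def test_stepwise_prefers_planted_signal_over_noise():
    hits = 0
    for rep in range(40):
        rngr = np.random.default_rng(100 + rep)
        n = 64
        sig = rngr.normal(size=n)
        noise = rngr.normal(size=n)
        y = (rngr.uniform(size=n) < 1 / (1 + np.exp(-1.5 * sig))).astype(float)
        df = pd.DataFrame({"label": y, "signal": sig, "noise": noise})
        model = forward_stepwise_logistic(df, ["signal", "noise"])
        hits += model.included_features == ["signal"]
    assert hits >= 36   # >= 95% in expectation with one noise candidate


def test_stepwise_degenerate_inputs():
    df = simulate_feature_cohort(12, seed=7)
    m0 = forward_stepwise_logistic(df, list(FEATURE_NAMES), alpha_entry=0.0)
    assert m0.intercept_only and m0.included_features == []
    m1 = forward_stepwise_logistic(df, [])
    assert m1.intercept_only


def test_stepwise_odds_ratio_identity_and_wald():
    df = simulate_feature_cohort(32, seed=8, effect_size=1.5)
    model = forward_stepwise_logistic(df, ["ratio_maxi_mean", "meanADC"])
    assert "ratio_maxi_mean" in model.included_features
    assert np.allclose(model.odds_ratios, np.exp(model.coefficients),
                       rtol=1e-9)
    i = model.included_features.index("ratio_maxi_mean")
    assert model.p_values[i] < 0.01
    assert model.coefficients[i] < 0    # no_rec carries the higher ratio


def test_stepwise_wald_matches_statsmodels():
    import statsmodels.api as sm

    df = simulate_feature_cohort(32, seed=9, effect_size=1.2)
    model = forward_stepwise_logistic(df, ["ratio_maxi_mean"])
    X = sm.add_constant(df[["ratio_maxi_mean"]].to_numpy(float))
    fit = sm.Logit(df["label"].to_numpy(float), X).fit(disp=0)
    assert model.intercept == pytest.approx(fit.params[0], abs=1e-6)
    assert model.coefficients[0] == pytest.approx(fit.params[1], abs=1e-6)
    assert model.p_values[0] == pytest.approx(fit.pvalues[1], rel=1e-4)


def test_stepwise_flags_separation():
    n = 40
    x = np.r_[np.zeros(20), np.ones(20)] + np.linspace(0, 0.1, 40)
    y = (np.arange(n) >= 20).astype(float)
    df = pd.DataFrame({"label": y, "x": x})
    with pytest.warns(SeparationWarning):
        model = forward_stepwise_logistic(df, ["x"])
    assert model.separation_flag


def test_selection_chain_recovers_planted_ratio_effect():
    hits = 0
    for rep in range(25):
        df = simulate_feature_cohort(32, seed=3000 + rep, effect_size=1.2)
        _, sm_model = select_features_chain(df, list(FEATURE_NAMES),
                                            folds=10, seed=3000 + rep)
        hits += sm_model.included_features == ["ratio_maxi_mean"]
    assert hits >= 20


# ---------------------------------------------------------------------------
# Comparison classifiers


def test_classifiers_detect_planted_signal_and_are_deterministic():
    df = simulate_feature_cohort(32, seed=10, effect_size=1.5)
    aucs = comparison_classifiers(df, list(FEATURE_NAMES), folds=5, seed=0)
    again = comparison_classifiers(df, list(FEATURE_NAMES), folds=5, seed=0)
    assert aucs == again
    se = np.sqrt(0.25 / 12)   # loose guard for per-fold AUC of ~6+6
    assert aucs["svm_rbf"] > 0.5 + 2 * se / np.sqrt(5)
    assert aucs["random_forest"] > 0.5 + 2 * se / np.sqrt(5)


def test_classifiers_near_chance_on_permuted_labels():
    df = simulate_feature_cohort(32, seed=11, effect_size=1.5)
    rngp = np.random.default_rng(0)
    df = df.copy()
    df["label"] = rngp.permutation(df["label"].to_numpy())
    if df["label"].min() == df["label"].max():  # pragma: no cover
        pytest.skip("degenerate permutation")
    aucs = comparison_classifiers(df, list(FEATURE_NAMES), folds=5, seed=1)
    for v in aucs.values():
        assert 0.2 < v < 0.8
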