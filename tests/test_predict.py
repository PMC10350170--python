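"""Penalized-path behavior, bootstrap stability selection, repeated-split
evaluation, and the rank-based AUC against a brute-force concordance oracle."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import alloatlas as aa
from alloatlas import ConfigurationError, DataError
from alloatlas.predict import (
    _l1_logistic_path,
    _standardize_train,
    default_lambda_grid,
    lambda_max,
)


@pytest.fixture(scope="module")
def signal_cohort():
    return aa.generate_feature_cohort(100, 8, informative=[0], effect_size=3.0, seed=42)


# ---------------------------------------------------------------------------
# path solver and lambda selection


def test_penalty_above_lambda_max_shrinks_everything_to_zero(signal_cohort):
    X, y = signal_cohort
    Z, _, _ = _standardize_train(X.to_numpy())
    lmax = lambda_max(X.to_numpy(), y.to_numpy())
    coefs, b0s = _l1_logistic_path(Z, y.to_numpy(dtype=float), np.array([lmax * 1.1]))
    assert np.all(coefs == 0.0)
    # unpenalized intercept converges to the log-odds of the base rate
    assert b0s[0] == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-6)


def test_path_matches_reference_l1_solver(signal_cohort):
    """Dual-route check: coordinate-descent path vs liblinear at matched
    penalties (sklearn's C = 1 / (n * lambda))."""
    from sklearn.linear_model import LogisticRegression

    X, y = signal_cohort
    Z, _, _ = _standardize_train(X.to_numpy())
    grid = default_lambda_grid(X.to_numpy(), y.to_numpy(), 20)
    coefs, b0s = _l1_logistic_path(Z, y.to_numpy(dtype=float), grid)
    # compare on the working range of the path; at the extreme tail the fit
    # saturates (near-separation) and both solvers become ill-conditioned
    for i in (5, 10, 15):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = LogisticRegression(
                penalty="l1", C=1 / (len(y) * grid[i]), solver="liblinear", max_iter=5000, tol=1e-9
            ).fit(Z, y)
        # small residual disagreement is expected: liblinear penalizes the
        # intercept, this solver does not
        rel = np.abs(coefs[i] - ref.coef_[0]) / np.maximum(1.0, np.abs(ref.coef_[0]))
        assert np.max(rel) < 1e-2


def test_cv_selects_separating_feature_and_is_deterministic(signal_cohort):
    X, y = signal_cohort
    lam1 = aa.cv_select_lambda(X, y, seed=7)
    lam2 = aa.cv_select_lambda(X, y, seed=7)
    assert lam1 == lam2
    Z, _, _ = _standardize_train(X.to_numpy())
    coef, _ = aa.predict._fit_l1(Z, y.to_numpy(dtype=float), lam1)
    assert abs(coef[0]) > 0  # the informative feature survives the penalty


def test_cv_raises_when_class_cannot_stratify():
    X = pd.DataFrame(np.random.default_rng(0).standard_normal((6, 3)))
    y = pd.Series([1, 0, 0, 0, 0, 0])
    with pytest.raises(DataError):
        aa.cv_select_lambda(X, y, folds=5)


# ---------------------------------------------------------------------------
# bootstrap selection


def test_bootstrap_single_iteration_gives_binary_frequencies(signal_cohort):
    X, y = signal_cohort
    sel = aa.bootstrap_feature_frequency(X, y, n_boot=1, seed=0)
    assert set(np.unique(sel.frequencies)) <= {0.0, 1.0}
    assert sel.n_iterations == 1


def test_informative_feature_selected_noise_frequency_lower():
    Xs, ys = aa.generate_feature_cohort(100, 8, informative=[0], effect_size=3.0, seed=5)
    sig = aa.bootstrap_feature_frequency(Xs, ys, n_boot=100, seed=1)
    assert sig.frequencies.iloc[0] >= 0.5
    assert "feature_00" in sig.selected
    Xn, yn = aa.generate_feature_cohort(100, 8, effect_size=0.0, seed=5)  # paired seed
    noise = aa.bootstrap_feature_frequency(Xn, yn, n_boot=100, seed=1)
    assert noise.frequencies.mean() < 0.5
    assert noise.frequencies.mean() < sig.frequencies.iloc[0]


def test_selection_frequency_nondecreasing_in_effect_size():
    """Mean selection frequency of the informative feature grows with its
    effect size (averaged over paired-seed cohorts: any single noise draw
    can carry a chance association that masks a small true effect)."""
    means = []
    for effect in (0.0, 1.0, 3.0):
        freqs = []
        for seed in (9, 10, 11, 12):
            X, y = aa.generate_feature_cohort(80, 6, informative=[2], effect_size=effect, seed=seed)
            sel = aa.bootstrap_feature_frequency(X, y, n_boot=40, seed=3)
            freqs.append(sel.frequencies.iloc[2])
        means.append(np.mean(freqs))
    assert means[0] < means[2] and means[1] < means[2]
    assert means[2] >= 0.9  # a 3-SD effect is essentially always selected


def test_constant_features_warn_and_select_nothing():
    X = pd.DataFrame(np.ones((20, 3)), columns=list("abc"))
    y = pd.Series([0, 1] * 10)
    with pytest.warns(UserWarning, match="constant"):
        sel = aa.bootstrap_feature_frequency(X, y, n_boot=5, seed=0)
    assert sel.selected == [] and (sel.frequencies == 0).all()


# ---------------------------------------------------------------------------
# AUC / ROC


def test_auc_worked_examples():
    auc, _ = aa.compute_roc_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])
    assert auc == pytest.approx(0.75)  # 3 of 4 concordant pairs
    assert aa.compute_roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])[0] == 1.0
    assert aa.compute_roc_auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1])[0] == 0.5  # all ties
    with pytest.raises(DataError):
        aa.compute_roc_auc([0.1, 0.9], [1, 1])


def _auc_oracle(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


@settings(max_examples=100, deadline=None)
@given(
    st.integers(min_value=2, max_value=30).flatmap(
        lambda n: st.tuples(
            st.lists(st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.5, 0.75, 1.0]), min_size=n, max_size=n),
            st.lists(st.integers(min_value=0, max_value=1), min_size=n, max_size=n),
        )
    )
)
def test_auc_matches_pairwise_concordance_oracle(case):
    scores, labels = case
    if len(set(labels)) < 2:
        labels = labels[:-1] + [1 - labels[-1]]
    auc, _ = aa.compute_roc_auc(scores, labels)
    assert auc == pytest.approx(_auc_oracle(scores, labels), abs=1e-12)


def test_roc_curve_endpoints_monotone():
    rng = np.random.default_rng(1)
    scores = rng.uniform(0, 1, 25)
    labels = (rng.uniform(0, 1, 25) < scores).astype(int)
    _, roc = aa.compute_roc_auc(scores, labels)
    assert roc["tpr"].iloc[0] == 0.0 and roc["fpr"].iloc[0] == 0.0
    assert roc["tpr"].iloc[-1] == 1.0 and roc["fpr"].iloc[-1] == 1.0
    assert (np.diff(roc["tpr"]) >= 0).all() and (np.diff(roc["fpr"]) >= 0).all()


# ---------------------------------------------------------------------------
# evaluation


def test_perfect_feature_gives_perfect_metrics():
    rng = np.random.default_rng(0)
    y = pd.Series([0, 1] * 20, index=[f"P{i}" for i in range(40)])
    X = pd.DataFrame({"oracle": y.to_numpy(dtype=float), "noise": rng.standard_normal(40)}, index=y.index)
    rep = aa.evaluate_model(X, y, features=["oracle"], n_iter=40, seed=1)
    means = rep.metric_summary["mean"]
    assert means["sensitivity"] == 1.0 and means["specificity"] == 1.0
    assert means["accuracy"] == 1.0 and means["auc"] == 1.0
    assert rep.auc_median_pred == 1.0


def test_metric_record_count_and_split_validity(signal_cohort):
    X, y = signal_cohort
    ev = aa.RepeatedSplitEvaluator(n_iter=25, seed=2)
    ev.fit(X, y, features=["feature_00"])
    assert len(ev.report_.metrics) == 25
    # stratification: re-derive the splits and check both classes on each side
    yv = y.to_numpy()
    rng = aa.predict.derived_rng(2, 29)
    for _ in range(25):
        train, val = ev._stratified_split(yv, rng)
        assert {0, 1} <= set(yv[train]) and {0, 1} <= set(yv[val])
        assert len(np.intersect1d(train, val)) == 0


def test_permuted_outcome_null_auc_near_half():
    X, y = aa.generate_feature_cohort(80, 5, informative=[0], effect_size=3.0, seed=3)
    y_perm = pd.Series(np.random.default_rng(10).permutation(y.to_numpy()), index=y.index)
    rep = aa.evaluate_model(X, y_perm, features=list(X.columns), n_iter=60, seed=4)
    assert 0.4 <= rep.metric_summary["mean"]["auc"] <= 0.6


def test_evaluation_deterministic_under_seed(signal_cohort):
    X, y = signal_cohort
    r1 = aa.evaluate_model(X, y, features=["feature_00"], n_iter=10, seed=5)
    r2 = aa.evaluate_model(X, y, features=["feature_00"], n_iter=10, seed=5)
    pd.testing.assert_frame_equal(r1.metrics, r2.metrics)
    pd.testing.assert_series_equal(r1.median_predictions, r2.median_predictions)


def test_coefficient_sign_recovery(signal_cohort):
    X, y = signal_cohort
    rep = aa.evaluate_model(X, y, features=["feature_00"], n_iter=30, seed=6)
    assert rep.coefficients["feature_00"] > 0


def test_empty_feature_set_raises(signal_cohort):
    X, y = signal_cohort
    with pytest.raises(ConfigurationError):
        aa.evaluate_model(X, y, features=[], n_iter=5, seed=0)


# ---------------------------------------------------------------------------
# Spearman association


def test_spearman_sign_and_exact_extreme_p():
    # predictions strictly higher for every positive: maximal rho for this
    # class balance, and the rank-sum p equals the extreme-arrangement
    # probability 2 / C(6,3) = 0.1
    preds = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]
    y = [1, 1, 1, 0, 0, 0]
    rho, p = aa.spearman_association(preds, y)
    # maximum attainable rho: Pearson correlation of the rank vectors
    # (prediction ranks 6..1 against tied outcome ranks 5,5,5,2,2,2)
    rho_max = np.corrcoef([6, 5, 4, 3, 2, 1], [5, 5, 5, 2, 2, 2])[0, 1]
    assert rho == pytest.approx(rho_max, abs=1e-12)
    assert p == pytest.approx(0.1, abs=1e-12)
    rho_neg, _ = aa.spearman_association(preds[::-1], y)
    assert rho_neg < 0


def test_spearman_null_mean_near_zero():
    rng = np.random.default_rng(7)
    rhos = []
    for _ in range(200):
        preds = rng.uniform(0, 1, 20)
        y = rng.integers(0, 2, 20)
        if len(np.unique(y)) < 2:
            continue
        rhos.append(aa.spearman_association(preds, y)[0])
    assert abs(np.mean(rhos)) < 0.05


def test_constant_predictions_give_missing_rho():
    rho, p = aa.spearman_association([0.5] * 6, [0, 1, 0, 1, 0, 1])
    assert np.isnan(rho)
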