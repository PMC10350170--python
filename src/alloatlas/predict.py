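"""Bootstrap-stabilized logistic LASSO and repeated-split evaluation.

The recipe, on a per-patient feature matrix (cell-type proportions that
differed significantly in the pairwise group comparisons) with a binary
clinical contrast (e.g. NR vs TCMR):

1. regularization path: an L1-penalized logistic model fit over a grid of
   100 log-spaced penalties from the analytic lambda_max (the smallest
   penalty shrinking every coefficient to zero) down to lambda_max * 1e-4;
   the working penalty is chosen by 5-fold stratified cross-validated
   binomial deviance;
2. stability selection: 5,000 bootstrap resamples of patients (with
   replacement; single-class resamples are redrawn so the iteration count
   stays exact), each refit with its own internally cross-validated penalty;
   a feature's importance is the fraction of iterations in which its
   coefficient is non-zero, and features at >= 50% frequency form the final
   model;
3. evaluation: 1,000 random stratified 75/25 train/validation splits; per
   split the selected-feature model is refit and sensitivity, specificity,
   accuracy (probability cut-off 0.5) and AUC are recorded; the report
   carries the metric means +/- SD, averaged coefficients, each patient's
   median validation prediction, the ROC built from those medians, and the
   Spearman correlation (with a rank-sum p) between median prediction and
   outcome.

Features are standardized inside each training set before penalization and
the intercept is unpenalized. The model is penalized *binomial deviance*
(logistic loss), the likelihood matching a binary outcome, rather than a
squared-error loss.

AUC uses the Mann-Whitney identity (probability that a random positive
outscores a random negative, ties counting 1/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

from ._utils import ConfigurationError, DataError, derived_int_seed, derived_rng

_NONZERO_TOL = 1e-8


def _check_xy(X: pd.DataFrame, y: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=int)
    if np.isnan(Xv).any() or np.isnan(yv).any():
        raise DataError("missing values in the feature matrix or outcome")
    if set(np.unique(yv)) - {0, 1} or len(np.unique(yv)) < 2:
        raise DataError("outcome must be binary with both classes present")
    return Xv, yv


def _standardize_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every coefficient of the standardized
    L1-logistic model is zero: max_j |x_j . (y - ybar)| / n."""
    Z, _, _ = _standardize_train(np.asarray(X, dtype=float))
    r = y - y.mean()
    return float(np.max(np.abs(Z.T @ r)) / len(y))


def default_lambda_grid(X: np.ndarray, y: np.ndarray, n_lambdas: int = 100) -> np.ndarray:
    lmax = max(lambda_max(X, y), 1e-12)
    return np.geomspace(lmax, lmax * 1e-4, n_lambdas)


@numba.njit(cache=False)
def _cd_path(Z, y, lambdas, tol, max_outer):  # pragma: no cover - jitted
    n, p = Z.shape
    L = lambdas.shape[0]
    beta = np.zeros(p)
    ybar = y.mean()
    b0 = np.log(max(ybar, 1e-12) / max(1.0 - ybar, 1e-12))
    coefs = np.zeros((L, p))
    b0s = np.zeros(L)
    eta = np.empty(n)
    for li in range(L):
        lam = lambdas[li]
        for _outer in range(max_outer):
            for i in range(n):
                s = b0
                for j in range(p):
                    s += Z[i, j] * beta[j]
                eta[i] = s
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            for i in range(n):
                if w[i] < 1e-5:
                    w[i] = 1e-5
            r = (y - mu) / w  # working residual z - eta
            wsum = w.sum()
            xwx = np.zeros(p)
            for j in range(p):
                acc = 0.0
                for i in range(n):
                    acc += w[i] * Z[i, j] * Z[i, j]
                xwx[j] = acc / n
            max_step = 0.0
            for _sweep in range(100):
                delta = 0.0
                for j in range(p):
                    if xwx[j] <= 0.0:
                        continue
                    rho = 0.0
                    for i in range(n):
                        rho += w[i] * Z[i, j] * r[i]
                    rho = rho / n + xwx[j] * beta[j]
                    if rho > lam:
                        new = (rho - lam) / xwx[j]
                    elif rho < -lam:
                        new = (rho + lam) / xwx[j]
                    else:
                        new = 0.0
                    if new != beta[j]:
                        step = new - beta[j]
                        for i in range(n):
                            r[i] -= Z[i, j] * step
                        if abs(step) > delta:
                            delta = abs(step)
                        beta[j] = new
                shift = 0.0
                for i in range(n):
                    shift += w[i] * r[i]
                shift /= wsum
                if shift != 0.0:
                    b0 += shift
                    for i in range(n):
                        r[i] -= shift
                    if abs(shift) > delta:
                        delta = abs(shift)
                if _sweep == 0:
                    max_step = delta
                if delta < tol:
                    break
            if max_step < 10.0 * tol:
                break
        for j in range(p):
            coefs[li, j] = beta[j]
        b0s[li] = b0
        # saturation: the fit is (near-)perfect, smaller penalties change
        # nothing scientifically -> propagate and stop early
        dev = 0.0
        for i in range(n):
            e = b0
            for j in range(p):
                e += Z[i, j] * beta[j]
            m = 1.0 / (1.0 + np.exp(-e))
            if m < 1e-12:
                m = 1e-12
            if m > 1.0 - 1e-12:
                m = 1.0 - 1e-12
            dev += -2.0 * (y[i] * np.log(m) + (1.0 - y[i]) * np.log(1.0 - m))
        if dev / n < 0.02:
            for lk in range(li + 1, L):
                for j in range(p):
                    coefs[lk, j] = beta[j]
                b0s[lk] = b0
            break
    return coefs, b0s


def _l1_logistic_path(
    Z: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-7,
    max_outer: int = 25,
) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started coordinate-descent path for the L1-penalized logistic
    model, glmnet-style: an outer quadratic (IRLS) approximation around the
    current estimate, inner cyclic coordinate descent with soft-thresholding
    on the penalized weighted least-squares problem, intercept unpenalized.
    ``lambdas`` must be descending; returns (coefs[len(lambdas), p], intercepts).

    Objective per penalty: (1/n) mean binomial deviance / 2 + lam ||beta||_1.
    Once a fit saturates (mean deviance < 0.02) the remaining, smaller
    penalties inherit it unchanged.
    """
    Z = np.ascontiguousarray(Z, dtype=np.float64)
    yv = np.ascontiguousarray(y, dtype=np.float64)
    lams = np.ascontiguousarray(lambdas, dtype=np.float64)
    return _cd_path(Z, yv, lams, tol, max_outer)


def _fit_l1(Z: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """L1 logistic fit at mean-deviance penalty lam on standardized Z,
    warm-started along a short descending path for stability."""
    lmax = max(float(np.max(np.abs(Z.T @ (y - y.mean()))) / len(y)), lam)
    path = np.geomspace(lmax, lam, 5) if lmax > lam else np.array([lam])
    coefs, b0s = _l1_logistic_path(Z, y, path)
    return coefs[-1], float(b0s[-1])


def _predict_proba(Z: np.ndarray, coef: np.ndarray, intercept: float) -> np.ndarray:
    eta = Z @ coef + intercept
    return 1.0 / (1.0 + np.exp(-eta))


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def cv_select_lambda(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    folds: int = 5,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    rule: str = "min",
) -> float:
    """Cross-validated penalty choice on stratified folds.

    rule "min": penalty minimizing mean CV binomial deviance (ties resolved
    toward the larger penalty). rule "1se": the largest penalty whose mean
    deviance is within one standard error of that minimum — the usual
    parsimony rule when the penalty drives feature selection.
    """
    Xv, yv = _check_xy(pd.DataFrame(X), pd.Series(np.asarray(y)))
    n_min = int(min((yv == 0).sum(), (yv == 1).sum()))
    folds = min(folds, n_min)
    if folds < 2:
        raise DataError("a class is too small to stratify cross-validation folds")
    if rule not in ("min", "1se"):
        raise ConfigurationError(f"unknown lambda rule {rule!r}")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(Xv, yv)
    lambda_grid = np.asarray(sorted(lambda_grid, reverse=True), dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    dev = np.zeros((folds, len(lambda_grid)))
    for fi, (train, test) in enumerate(skf.split(Xv, yv)):
        Z, mu, sd = _standardize_train(Xv[train])
        Zt = (Xv[test] - mu) / sd
        coefs, b0s = _l1_logistic_path(Z, yv[train], lambda_grid)
        for i in range(len(lambda_grid)):
            dev[fi, i] = _deviance(yv[test], _predict_proba(Zt, coefs[i], b0s[i]))
    mean_dev = dev.mean(axis=0)
    best = int(np.argmin(mean_dev))  # first = largest penalty on ties
    if rule == "min":
        return float(lambda_grid[best])
    se = dev[:, best].std(ddof=1) / np.sqrt(folds)
    within = np.flatnonzero(mean_dev <= mean_dev[best] + se)
    return float(lambda_grid[int(within[0])])


@dataclass
class BootstrapSelection:
    frequencies: pd.Series  # feature -> selection frequency in [0, 1]
    n_iterations: int
    threshold: float
    selected: list[str] = field(default_factory=list)


class BootstrapLassoSelector(BaseEstimator):
    """Stability selection: refit the internally cross-validated L1 logistic
    model on bootstrap resamples and keep features whose coefficients are
    non-zero in at least ``threshold`` of the iterations."""

    def __init__(self, n_boot: int = 5000, threshold: float = 0.5, folds: int = 5, n_lambdas: int = 100,
                 seed: int = 0, rule: str = "1se"):
        self.n_boot = n_boot
        self.threshold = threshold
        self.folds = folds
        self.n_lambdas = n_lambdas
        self.seed = seed
        self.rule = rule  # parsimonious penalty: selection, not prediction

    def fit(self, X: pd.DataFrame, y: pd.Series):
        if self.n_boot < 1:
            raise ConfigurationError("n_boot must be >= 1")
        Xv, yv = _check_xy(X, y)
        features = list(X.columns)
        if np.all(Xv.std(axis=0) == 0):
            warnings.warn("all features are constant; empty selection")
            self.frequencies_ = pd.Series(0.0, index=features)
            self.selected_features_ = []
            return self
        if min((yv == 0).sum(), (yv == 1).sum()) < 2:
            raise DataError("each class needs >= 2 patients for bootstrap selection")
        rng = derived_rng(self.seed, 19)
        n = len(yv)
        hits = np.zeros(Xv.shape[1])
        for it in range(self.n_boot):
            # redraw degenerate resamples so the iteration count stays exact;
            # internal CV needs at least 2 patients of each class
            while True:
                idx = rng.integers(0, n, n)
                counts = np.bincount(yv[idx], minlength=2)
                if counts.min() >= 2:
                    break
            Xb, yb = Xv[idx], yv[idx]
            lam = cv_select_lambda(
                Xb, yb, folds=self.folds,
                lambda_grid=default_lambda_grid(Xb, yb, self.n_lambdas),
                seed=derived_int_seed(self.seed, 23, it), rule=self.rule,
            )
            Z, _, _ = _standardize_train(Xb)
            coef, _ = _fit_l1(Z, yb, lam)
            hits += np.abs(coef) > _NONZERO_TOL
        self.frequencies_ = pd.Series(hits / self.n_boot, index=features)
        self.selected_features_ = [f for f in features if self.frequencies_[f] >= self.threshold]
        return self


def bootstrap_feature_frequency(
    X: pd.DataFrame, y: pd.Series, n_boot: int = 5000, threshold: float = 0.5, seed: int = 0, **kwargs
) -> BootstrapSelection:
    sel = BootstrapLassoSelector(n_boot=n_boot, threshold=threshold, seed=seed, **kwargs).fit(X, y)
    return BootstrapSelection(
        frequencies=sel.frequencies_, n_iterations=n_boot, threshold=threshold, selected=sel.selected_features_
    )


# ---------------------------------------------------------------------------
# evaluation


def compute_roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC via the Mann-Whitney identity (ties count 1/2) plus the ROC
    threshold sweep. Raises on single-class labels."""
    s = np.asarray(scores, dtype=float)
    yv = np.asarray(labels, dtype=int)
    n_pos, n_neg = int((yv == 1).sum()), int((yv == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("both classes are required to compute an ROC")
    ranks = sps.rankdata(s)
    auc = (ranks[yv == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-s, kind="stable")
    tps = np.cumsum(yv[order] == 1)
    fps = np.cumsum(yv[order] == 0)
    distinct = np.r_[np.flatnonzero(np.diff(s[order])), len(s) - 1]
    roc = pd.DataFrame(
        {
            "threshold": np.r_[np.inf, s[order][distinct]],
            "tpr": np.r_[0.0, tps[distinct] / n_pos],
            "fpr": np.r_[0.0, fps[distinct] / n_neg],
        }
    )
    return float(auc), roc


def _binary_metrics(y_true: np.ndarray, proba: np.ndarray, cutoff: float = 0.5) -> dict[str, float]:
    pred = (proba >= cutoff).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    auc, _ = compute_roc_auc(proba, y_true)
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "accuracy": (tp + tn) / len(y_true),
        "auc": auc,
    }


def spearman_association(predictions, outcomes) -> tuple[float, float]:
    """Spearman rho between median predictions and the binary outcome, with a
    two-sided rank-sum p comparing predictions between outcome classes.
    Constant predictions give a missing rho."""
    p = np.asarray(predictions, dtype=float)
    yv = np.asarray(outcomes, dtype=int)
    keep = ~np.isnan(p)
    p, yv = p[keep], yv[keep]
    if len(p) < 3 or len(np.unique(yv)) < 2:
        raise DataError("need >= 3 patients with both classes")
    if np.ptp(p) == 0:
        return np.nan, 1.0
    rho = float(sps.spearmanr(p, yv).statistic)
    pw = float(sps.mannwhitneyu(p[yv == 1], p[yv == 0], alternative="two-sided", method="auto").pvalue)
    return rho, pw


@dataclass
class ModelReport:
    metrics: pd.DataFrame  # one row per evaluation iteration
    metric_summary: pd.DataFrame  # mean/sd per metric
    coefficients: pd.Series  # averaged standardized-scale coefficients (+ intercept)
    median_predictions: pd.Series  # patient -> median validation probability
    roc: pd.DataFrame  # from median predictions
    auc_median_pred: float
    spearman_rho: float
    spearman_p: float
    selected_features: list[str]


class RepeatedSplitEvaluator(BaseEstimator):
    """Repeated stratified 75/25 split evaluation of the selected-feature
    L1-logistic model."""

    def __init__(self, n_iter: int = 1000, train_frac: float = 0.75, folds: int = 5, n_lambdas: int = 100,
                 cutoff: float = 0.5, seed: int = 0):
        self.n_iter = n_iter
        self.train_frac = train_frac
        self.folds = folds
        self.n_lambdas = n_lambdas
        self.cutoff = cutoff
        self.seed = seed

    def _stratified_split(self, yv: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
        train_idx, val_idx = [], []
        for cls in (0, 1):
            idx = np.flatnonzero(yv == cls)
            idx = idx[rng.permutation(len(idx))]
            n_train = int(round(self.train_frac * len(idx)))
            n_train = min(max(n_train, 1), len(idx) - 1)  # both sides keep the class
            train_idx.append(idx[:n_train])
            val_idx.append(idx[n_train:])
        return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))

    def fit(self, X: pd.DataFrame, y: pd.Series, features: list[str] | None = None):
        features = list(features) if features is not None else list(X.columns)
        if not features:
            raise ConfigurationError("the selected feature set is empty")
        Xv, yv = _check_xy(X[features], y)
        if min((yv == 0).sum(), (yv == 1).sum()) < 2:
            raise DataError("each class needs >= 2 patients to stratify the splits")
        patients = list(X.index)
        rng = derived_rng(self.seed, 29)
        metric_rows = []
        coef_sum = np.zeros(len(features))
        intercept_sum = 0.0
        preds: dict[int, list[float]] = {i: [] for i in range(len(patients))}
        for it in range(self.n_iter):
            train, val = self._stratified_split(yv, rng)
            lam = cv_select_lambda(
                Xv[train], yv[train], folds=self.folds,
                lambda_grid=default_lambda_grid(Xv[train], yv[train], self.n_lambdas),
                seed=derived_int_seed(self.seed, 31, it),
            )
            Z, mu, sd = _standardize_train(Xv[train])
            coef, b0 = _fit_l1(Z, yv[train], lam)
            proba = _predict_proba((Xv[val] - mu) / sd, coef, b0)
            metric_rows.append(_binary_metrics(yv[val], proba, self.cutoff))
            coef_sum += coef
            intercept_sum += b0
            for pos, pr in zip(val, proba):
                preds[pos].append(float(pr))
        metrics = pd.DataFrame(metric_rows)
        never_val = [patients[i] for i, v in preds.items() if not v]
        if never_val:
            warnings.warn(f"{len(never_val)} patient(s) never entered a validation split; median prediction missing")
        median_pred = pd.Series(
            {patients[i]: (float(np.median(v)) if v else np.nan) for i, v in preds.items()}, name="median_prediction"
        ).reindex(patients)
        ok = median_pred.notna().to_numpy()
        auc_med, roc = compute_roc_auc(median_pred.to_numpy()[ok], yv[ok])
        rho, pw = spearman_association(median_pred.to_numpy()[ok], yv[ok])
        self.report_ = ModelReport(
            metrics=metrics,
            metric_summary=metrics.agg(["mean", "std"]).T.rename(columns={"std": "sd"}),
            coefficients=pd.Series(
                np.r_[coef_sum / self.n_iter, intercept_sum / self.n_iter], index=features + ["(intercept)"]
            ),
            median_predictions=median_pred,
            roc=roc,
            auc_median_pred=auc_med,
            spearman_rho=rho,
            spearman_p=pw,
            selected_features=features,
        )
        return self


def evaluate_model(
    X: pd.DataFrame,
    y: pd.Series,
    features: list[str] | None = None,
    n_iter: int = 1000,
    train_frac: float = 0.75,
    seed: int = 0,
    **kwargs,
) -> ModelReport:
    ev = RepeatedSplitEvaluator(n_iter=n_iter, train_frac=train_frac, seed=seed, **kwargs)
    return ev.fit(X, y, features=features).report_
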