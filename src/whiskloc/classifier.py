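"""L1-regularized logistic classification with repeated stratified CV.

This is the statistical core of the analysis, written from scratch: a
logistic model ``h_theta(x) = g(theta^T x)`` with mean cross-entropy cost

    J(theta) = (1/m) sum_i [ -y_i log h - (1-y_i) log(1-h) ] + lambda sum_j |theta_j|

penalizing every coefficient except the intercept. The cost is minimized by
proximal gradient descent with Nesterov acceleration (FISTA); the L1 term is
handled by soft-thresholding, so exact zeros are reachable. Model selection
runs 20 iterations of 5-fold stratified cross-validation over a logarithmic
lambda grid; the operating lambda is the mean of the lowest-error lambda and
the first lambda whose error is one SEM above the minimum. Performance is
scored with the Matthews correlation coefficient (MCC), which stays honest
under class imbalance, and coefficients are summarized as sign-carrying
min-max-normalized odds ratios averaged across folds.

The two-stage choice model routes trials without touch to the count-only
stage — which invariably predicts "no lick" — and trials with touch to a
kinematic-feature + touch-count model.

scikit-learn is deliberately not used anywhere in this module; it serves
only as an independent oracle in the test suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.special import expit

from .session import GO, LICK

DEFAULT_LAMBDA_GRID = np.logspace(-4, 1, 20)
DEFAULT_ITERATIONS = 20
DEFAULT_FOLDS = 5
PROB_CLIP_EPS = 1e-12

#: positive class per target label
POSITIVE = {"trial_type": GO, "choice": LICK}


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def sigmoid(z):
    """Overflow-safe logistic link g(z) = 1 / (1 + exp(-z))."""
    return expit(z)


def cost_and_gradient(
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
) -> Tuple[float, np.ndarray]:
    """Cost J(theta) and its (sub)gradient.

    ``X`` carries the intercept in column 0; the intercept is never
    penalized. Probabilities are clipped at 1e-12 inside the logs. At
    theta_j = 0 the subgradient term lambda*sign(0) = 0 is reported; the
    optimizer itself uses the proximal (soft-threshold) treatment instead.
    """
    theta = np.asarray(theta, dtype=float)
    m = X.shape[0]
    if m == 0:
        raise ValueError("empty design matrix")
    h = expit(X @ theta)
    hc = np.clip(h, PROB_CLIP_EPS, 1.0 - PROB_CLIP_EPS)
    J = float(-np.mean(y * np.log(hc) + (1.0 - y) * np.log(1.0 - hc)))
    J += lam * float(np.sum(np.abs(theta[1:])))
    grad = X.T @ (h - y) / m
    grad[1:] += lam * np.sign(theta[1:])
    return J, grad


def _smooth_cost(theta, X, y):
    h = expit(X @ theta)
    hc = np.clip(h, PROB_CLIP_EPS, 1.0 - PROB_CLIP_EPS)
    return float(-np.mean(y * np.log(hc) + (1.0 - y) * np.log(1.0 - hc)))


@dataclass
class ClassifierModel:
    """A fitted logistic model with its normalization frozen at train time."""

    theta: np.ndarray                    # intercept first
    lam: float
    predictor_names: List[str]
    normalization_stats: Dict[str, Tuple[float, float, float]]  # mean, min, max
    converged: bool = True
    n_iter: int = 0

    def design(self, table: pd.DataFrame) -> np.ndarray:
        """Normalized design matrix (with intercept) for new data, using the
        training normalization statistics."""
        cols = []
        for name in self.predictor_names:
            mean, lo, hi = self.normalization_stats[name]
            rng = hi - lo
            x = np.asarray(table[name], dtype=float)
            cols.append((x - mean) / (rng if rng > 0 else 1.0))
        X = np.column_stack([np.ones(len(table))] + cols)
        return X

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return expit(self.design(table) @ self.theta)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(table) >= 0.5).astype(int)


def fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    theta0: Optional[np.ndarray] = None,
    max_iter: int = 1000,
    tol: float = 1e-10,
    predictor_names: Optional[List[str]] = None,
    normalization_stats: Optional[dict] = None,
) -> ClassifierModel:
    """Minimize J(theta) by FISTA with soft-thresholding on the penalized
    coordinates (all but the intercept).

    Convergence is declared when the cost change drops below ``tol``
    (relative); otherwise the returned model is flagged ``converged=False``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m, p = X.shape
    # Lipschitz constant of the smooth part: ||X||_2^2 / (4m)
    L = float(np.linalg.norm(X, 2)) ** 2 / (4.0 * m)
    L = max(L, 1e-12)
    step = 1.0 / L
    theta = np.zeros(p) if theta0 is None else np.asarray(theta0, dtype=float).copy()
    z = theta.copy()
    t_acc = 1.0
    J_prev = _smooth_cost(theta, X, y) + lam * np.sum(np.abs(theta[1:]))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        h = expit(X @ z)
        grad = X.T @ (h - y) / m
        theta_new = z - step * grad
        theta_new[1:] = np.sign(theta_new[1:]) * np.maximum(
            np.abs(theta_new[1:]) - step * lam, 0.0)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc ** 2))
        z = theta_new + ((t_acc - 1.0) / t_new) * (theta_new - theta)
        theta, t_acc = theta_new, t_new
        J = _smooth_cost(theta, X, y) + lam * np.sum(np.abs(theta[1:]))
        if abs(J_prev - J) <= tol * max(1.0, abs(J)):
            converged = True
            break
        J_prev = J
    if not converged:
        warnings.warn(f"fit did not converge in {max_iter} iterations (lambda={lam:g})")
    names = predictor_names or [f"x{j}" for j in range(p - 1)]
    stats = normalization_stats or {n: (0.0, 0.0, 1.0) for n in names}
    return ClassifierModel(theta=theta, lam=float(lam), predictor_names=names,
                           normalization_stats=stats, converged=converged,
                           n_iter=it)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            TN=int(np.sum((y_true == 0) & (y_pred == 0))),
            FP=int(np.sum((y_true == 0) & (y_pred == 1))),
            FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        )

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def mcc(confusion: ConfusionMatrix) -> float:
    """Matthews correlation coefficient in [-1, 1].

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); any zero
    factor in the denominator makes the coefficient undefined and is mapped
    to 0 with a warning.
    """
    tp, tn, fp, fn = (float(confusion.TP), float(confusion.TN),
                      float(confusion.FP), float(confusion.FN))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0.0:
        warnings.warn("degenerate confusion matrix: MCC defined as 0")
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def accuracy(confusion: ConfusionMatrix) -> float:
    return (confusion.TP + confusion.TN) / confusion.total


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def labels_from(table: pd.DataFrame, target_label: str) -> np.ndarray:
    """Binary labels for a target column ('trial_type' -> go=1, 'choice' -> lick=1)."""
    if target_label not in POSITIVE:
        raise ValueError(f"unknown target label {target_label!r}")
    return (table[target_label].to_numpy() == POSITIVE[target_label]).astype(int)


def stratified_folds(
    y: np.ndarray,
    folds: int,
    rng: np.random.Generator,
) -> List[np.ndarray]:
    """Class-stratified fold assignment; remainder trials go to the earliest
    folds. Raises if any class has fewer members than folds."""
    y = np.asarray(y)
    test_sets: List[List[int]] = [[] for _ in range(folds)]
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        if idx.size < folds:
            counts = {int(c): int(np.sum(y == c)) for c in np.unique(y)}
            raise ValueError(
                f"class {cls!r} has fewer members than folds={folds}; class "
                f"counts: {counts}")
        perm = rng.permutation(idx)
        base, rem = divmod(idx.size, folds)
        start = 0
        for f in range(folds):
            size = base + (1 if f < rem else 0)
            test_sets[f].extend(perm[start:start + size].tolist())
            start += size
    return [np.sort(np.asarray(s, dtype=int)) for s in test_sets]


def _norm_stats(X: np.ndarray, names: Sequence[str]) -> dict:
    return {n: (float(X[:, j].mean()), float(X[:, j].min()), float(X[:, j].max()))
            for j, n in enumerate(names)}


def _apply_norm(X: np.ndarray, names: Sequence[str], stats: dict) -> np.ndarray:
    cols = []
    for j, n in enumerate(names):
        mean, lo, hi = stats[n]
        rng = hi - lo
        cols.append((X[:, j] - mean) / (rng if rng > 0 else 1.0))
    return np.column_stack([np.ones(X.shape[0])] + cols)


@dataclass
class FitResult:
    model: ClassifierModel
    chosen_lambda: float
    per_fold_mcc: List[float]
    per_fold_accuracy: List[float]
    per_fold_theta: List[np.ndarray]
    normalized_weights: np.ndarray
    predictor_names: List[str]
    target_label: str
    lambda_grid: np.ndarray
    error_by_lambda: np.ndarray
    error_sem: np.ndarray

    @property
    def mean_mcc(self) -> float:
        return float(np.mean(self.per_fold_mcc))

    @property
    def sem_mcc(self) -> float:
        k = len(self.per_fold_mcc)
        return float(np.std(self.per_fold_mcc, ddof=1) / np.sqrt(k)) if k > 1 else 0.0

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_fold_accuracy))

    def to_dict(self) -> dict:
        return {
            "target_label": self.target_label,
            "predictor_names": list(self.predictor_names),
            "chosen_lambda": self.chosen_lambda,
            "theta": self.model.theta.tolist(),
            "normalization_stats": {k: list(v) for k, v in
                                    self.model.normalization_stats.items()},
            "per_fold_mcc": list(map(float, self.per_fold_mcc)),
            "per_fold_accuracy": list(map(float, self.per_fold_accuracy)),
            "normalized_weights": self.normalized_weights.tolist(),
            "lambda_grid": self.lambda_grid.tolist(),
            "error_by_lambda": self.error_by_lambda.tolist(),
            "error_sem": self.error_sem.tolist(),
            "mean_mcc": self.mean_mcc,
            "sem_mcc": self.sem_mcc,
            "mean_accuracy": self.mean_accuracy,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def cross_validate(
    feature_table: pd.DataFrame,
    predictors: Sequence[str],
    target_label: str,
    lambda_grid: Optional[np.ndarray] = None,
    iterations: int = DEFAULT_ITERATIONS,
    folds: int = DEFAULT_FOLDS,
    rng: Optional[np.random.Generator] = None,
    max_iter: int = 400,
    tol: float = 1e-9,
) -> FitResult:
    """Repeated stratified cross-validation with lambda selection.

    Normalization statistics are computed on the training folds only and
    applied to the held-out fold. Held-out misclassification ("error") is
    averaged per lambda across all folds x iterations; the chosen lambda is
    the mean of the minimum-error lambda and the first larger lambda whose
    error is one SEM above the minimum. Per-fold MCC/accuracy and
    coefficients are recorded at the chosen lambda, and the returned model
    is refit at that lambda on all data.
    """
    predictors = list(predictors)
    if rng is None:
        rng = np.random.default_rng(0)
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid,
                                                                      dtype=float)
    Xraw = feature_table[predictors].to_numpy(dtype=float)
    if not np.all(np.isfinite(Xraw)):
        raise ValueError(
            "feature table contains missing values in the requested "
            "predictors; resolve missing markers before fitting")
    y = labels_from(feature_table, target_label)

    fold_assignments = []
    for _ in range(iterations):
        fold_assignments.append(stratified_folds(y, folds, rng))

    n_cells = iterations * folds
    errors = np.empty((n_cells, grid.size))
    cell = 0
    cell_data = []  # (train_idx, test_idx, stats, theta_path_last)
    for it_folds in fold_assignments:
        for test_idx in it_folds:
            train_mask = np.ones(len(y), dtype=bool)
            train_mask[test_idx] = False
            train_idx = np.nonzero(train_mask)[0]
            stats = _norm_stats(Xraw[train_idx], predictors)
            Xtr = _apply_norm(Xraw[train_idx], predictors, stats)
            Xte = _apply_norm(Xraw[test_idx], predictors, stats)
            ytr, yte = y[train_idx], y[test_idx]
            theta = np.zeros(Xtr.shape[1])
            with warnings.catch_warnings():
                # path fits are warm starts; only the refits must be converged
                warnings.filterwarnings("ignore", message=".*did not converge.*")
                for g, lam in enumerate(grid):
                    model = fit(Xtr, ytr, lam, theta0=theta, max_iter=max_iter,
                                tol=tol)
                    theta = model.theta
                    pred = (expit(Xte @ theta) >= 0.5).astype(int)
                    errors[cell, g] = float(np.mean(pred != yte))
            cell_data.append((train_idx, test_idx, stats))
            cell += 1

    error_by_lambda = errors.mean(axis=0)
    error_sem = errors.std(axis=0, ddof=1) / np.sqrt(n_cells)
    i_min = int(np.argmin(error_by_lambda))
    threshold = error_by_lambda[i_min] + error_sem[i_min]
    i_1se = i_min
    for g in range(i_min + 1, grid.size):
        if error_by_lambda[g] >= threshold:
            i_1se = g
            break
    chosen = float((grid[i_min] + grid[i_1se]) / 2.0)

    per_fold_mcc, per_fold_acc, per_fold_theta = [], [], []
    for train_idx, test_idx, stats in cell_data:
        Xtr = _apply_norm(Xraw[train_idx], predictors, stats)
        Xte = _apply_norm(Xraw[test_idx], predictors, stats)
        model = fit(Xtr, y[train_idx], chosen, max_iter=4 * max_iter, tol=tol)
        pred = (expit(Xte @ model.theta) >= 0.5).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = ConfusionMatrix.from_predictions(y[test_idx], pred)
            per_fold_mcc.append(mcc(cm))
            per_fold_acc.append(accuracy(cm))
        per_fold_theta.append(model.theta.copy())

    full_stats = _norm_stats(Xraw, predictors)
    Xfull = _apply_norm(Xraw, predictors, full_stats)
    final = fit(Xfull, y, chosen, max_iter=4 * max_iter, tol=tol,
                predictor_names=predictors, normalization_stats=full_stats)
    weights = normalized_odds_weights(per_fold_theta)
    return FitResult(
        model=final, chosen_lambda=chosen, per_fold_mcc=per_fold_mcc,
        per_fold_accuracy=per_fold_acc, per_fold_theta=per_fold_theta,
        normalized_weights=weights, predictor_names=predictors,
        target_label=target_label, lambda_grid=grid,
        error_by_lambda=error_by_lambda, error_sem=error_sem,
    )


def normalized_odds_weights(per_fold_theta: Sequence[np.ndarray]) -> np.ndarray:
    """Sign-carrying normalized odds-ratio weights, averaged across folds.

    Per fold, each coefficient's effect magnitude e^|theta_j| is min-max
    normalized to [0, 1] across predictors and multiplied by sign(theta_j);
    intercepts are excluded. A single-predictor model is degenerate under
    min-max normalization and returns sign(theta) * 1 with a warning; a fold
    with zero spread returns equal unit magnitudes.
    """
    per_fold = [np.asarray(th, dtype=float)[1:] for th in per_fold_theta]
    p = per_fold[0].size
    if p == 1:
        warnings.warn("single-predictor model: odds-ratio normalization is "
                      "degenerate; returning sign(theta)")
        return np.array([float(np.mean([np.sign(th[0]) for th in per_fold]))])
    acc = np.zeros(p)
    for th in per_fold:
        odds = np.exp(np.abs(th))
        spread = odds.max() - odds.min()
        mag = np.ones(p) if spread == 0 else (odds - odds.min()) / spread
        acc += mag * np.sign(th)
    return acc / len(per_fold)


# ---------------------------------------------------------------------------
# shuffle control
# ---------------------------------------------------------------------------

@dataclass
class ShuffleResult:
    real: FitResult
    null_mcc: np.ndarray            # mean CV MCC per shuffle
    null_per_fold_mcc: np.ndarray   # (n_shuffles, folds*iterations)
    statistic: float
    pvalue: float

    @property
    def percentile_95(self) -> float:
        return float(np.percentile(self.null_mcc, 95))


def shuffle_control(
    feature_table: pd.DataFrame,
    predictors: Sequence[str],
    target_label: str,
    n_shuffles: int,
    rng: np.random.Generator,
    **cv_kwargs,
) -> ShuffleResult:
    """Null MCC distribution from label-permuted refits of the full CV.

    The fold structure is held identical between the real fit and every
    shuffle (same fold seed), so the per-fold scores pair up; the paired
    comparison is a Wilcoxon signed-rank test of the real per-fold MCCs
    against the across-shuffle mean per fold.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    fold_seed = int(rng.integers(2 ** 31))
    real = cross_validate(feature_table, predictors, target_label,
                          rng=np.random.default_rng(fold_seed), **cv_kwargs)
    null_rows = []
    null_means = []
    for _ in range(n_shuffles):
        shuffled = feature_table.copy()
        perm = rng.permutation(len(shuffled))
        shuffled[target_label] = shuffled[target_label].to_numpy()[perm]
        res = cross_validate(shuffled, predictors, target_label,
                             rng=np.random.default_rng(fold_seed), **cv_kwargs)
        null_rows.append(res.per_fold_mcc)
        null_means.append(res.mean_mcc)
    null_per_fold = np.asarray(null_rows)
    diffs = np.asarray(real.per_fold_mcc) - null_per_fold.mean(axis=0)
    if np.allclose(diffs, 0):
        statistic, pvalue = 0.0, 1.0
    else:
        statistic, pvalue = sstats.wilcoxon(diffs)
    return ShuffleResult(real=real, null_mcc=np.asarray(null_means),
                         null_per_fold_mcc=null_per_fold,
                         statistic=float(statistic), pvalue=float(pvalue))


# ---------------------------------------------------------------------------
# two-stage choice model
# ---------------------------------------------------------------------------

def two_stage_predict(
    feature_table: pd.DataFrame,
    touch_model: ClassifierModel,
    touch_trial_model: ClassifierModel,
) -> np.ndarray:
    """Two-stage choice prediction aligned to the table's row order.

    Trials without touch are handled by the count-only stage, which — with a
    touch count of zero — invariably predicts "no lick"; that invariant is
    enforced structurally here. Trials with touch are scored by the
    kinematic-feature + touch-count model; touch trials whose kinematic
    feature is missing (exclusively retraction touches) fall back to the
    count-only model.
    """
    n = len(feature_table)
    pred = np.zeros(n, dtype=int)
    counts = feature_table["touch_count"].to_numpy(dtype=float)
    kin_cols = [c for c in touch_trial_model.predictor_names if c != "touch_count"]
    kin = feature_table[kin_cols].to_numpy(dtype=float) if kin_cols else \
        np.zeros((n, 0))
    has_touch = counts > 0
    kin_ok = np.all(np.isfinite(kin), axis=1) if kin.shape[1] else np.ones(n, bool)

    stage2 = has_touch & kin_ok
    fallback = has_touch & ~kin_ok
    if stage2.any():
        pred[stage2] = touch_trial_model.predict(feature_table.loc[stage2])
    if fallback.any():
        pred[fallback] = touch_model.predict(feature_table.loc[fallback])
    # zero-touch trials: count-only stage, invariably "no lick"
    pred[~has_touch] = 0
    return pred


def fit_two_stage(
    feature_table: pd.DataFrame,
    kinematic_feature: str,
    target_label: str = "choice",
    rng: Optional[np.random.Generator] = None,
    count_fit: Optional[FitResult] = None,
    **cv_kwargs,
) -> Tuple[FitResult, FitResult, np.ndarray]:
    """Fit both stages and return (count_fit, touch_fit, predictions).

    The count-only stage is trained on all trials; the touch stage on trials
    with a finite kinematic feature (touch trials, protraction-touch trials
    for Hilbert features). A pre-fitted count stage can be reused across
    kinematic variants.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    seeds = rng.integers(2 ** 31, size=2)
    if count_fit is None:
        count_fit = cross_validate(feature_table, ["touch_count"], target_label,
                                   rng=np.random.default_rng(int(seeds[0])),
                                   **cv_kwargs)
    touch_rows = feature_table[np.isfinite(
        feature_table[kinematic_feature].to_numpy(dtype=float))]
    touch_fit = cross_validate(touch_rows, [kinematic_feature, "touch_count"],
                               target_label,
                               rng=np.random.default_rng(int(seeds[1])), **cv_kwargs)
    pred = two_stage_predict(feature_table, count_fit.model, touch_fit.model)
    return count_fit, touch_fit, pred
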