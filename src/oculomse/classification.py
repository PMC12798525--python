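"""Class-weighted L1 logistic regression with leakage-safe nested LOOCV.

The classifier protocol for the biomarker evaluation: an L1-penalized
(lasso) logistic regression with per-sample weights inversely proportional
to class frequency, evaluated by nested cross-validation — an outer
leave-one-out loop for the generalization estimate, and within every outer
training fold an inner stratified 5-fold loop that picks the penalty
strength.  Feature standardization constants and the chosen penalty are
computed from the training fold only, so the held-out participant never
leaks into its own fold's model.  Pooled out-of-fold probabilities yield
one ROC and one precision-recall curve per feature set; the operating
threshold is the probability cut maximizing F1 on the PR operating points.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "CvConfig",
    "EvaluationReport",
    "class_weights",
    "fit_lasso_logistic",
    "nested_loocv_evaluate",
    "roc_pr_metrics",
    "optimal_f1_threshold",
    "feature_combination_sweep",
    "DEFAULT_LAMBDA_GRID",
]

#: deterministic log-spaced penalty grid searched by the inner loop
DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(
    float(x) for x in np.logspace(-4, 2, 50)
)


@dataclass(frozen=True)
class CvConfig:
    """Nested cross-validation settings (outer loop is leave-one-out)."""

    inner_folds: int = 5
    lambda_grid: tuple[float, ...] = tuple(DEFAULT_LAMBDA_GRID)
    inner_criterion: str = "weighted_log_loss"  # or "auc_roc"
    seed: int = 0


@dataclass
class EvaluationReport:
    """Out-of-fold predictions and derived metrics for one feature set."""

    feature_set: tuple[str, ...]
    participant_ids: list[str]
    labels: np.ndarray
    probabilities: np.ndarray
    lambdas: np.ndarray  # chosen penalty per outer fold
    auc_roc: float = field(init=False)
    auc_pr: float = field(init=False)
    roc: tuple[np.ndarray, np.ndarray] = field(init=False)
    pr: tuple[np.ndarray, np.ndarray] = field(init=False)
    threshold: float = field(init=False)
    f1: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    confusion: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        metrics = roc_pr_metrics(self.probabilities, self.labels)
        self.auc_roc = metrics["auc_roc"]
        self.auc_pr = metrics["auc_pr"]
        self.roc = metrics["roc"]
        self.pr = metrics["pr"]
        opt = optimal_f1_threshold(self.probabilities, self.labels)
        self.threshold = opt["threshold"]
        self.f1 = opt["f1"]
        self.sensitivity = opt["sensitivity"]
        self.specificity = opt["specificity"]
        self.confusion = opt["confusion"]

    def to_dict(self) -> dict:
        return {
            "feature_set": list(self.feature_set),
            "auc_roc": self.auc_roc,
            "auc_pr": self.auc_pr,
            "threshold": self.threshold,
            "f1": self.f1,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion": self.confusion,
            "participant_ids": self.participant_ids,
            "labels": self.labels.astype(int).tolist(),
            "probabilities": self.probabilities.tolist(),
            "lambdas": self.lambdas.tolist(),
        }


def class_weights(labels: np.ndarray) -> np.ndarray:
    """Per-sample weights inversely proportional to class frequency.

    Normalized so the weights sum to n; each class then carries equal
    total weight n/2, preventing majority-class bias.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"expected two classes, got {classes.size}")
    n = y.size
    w = np.empty(n, dtype=float)
    for cls, cnt in zip(classes, counts):
        w[y == cls] = n / (2.0 * cnt)
    return w


def fit_lasso_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    sample_weight: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Weighted L1 logistic regression: minimize sum_i w_i * NLL_i + lam * ||beta||_1.

    The intercept is unpenalized.  ``lam = 0`` gives the unpenalized
    maximum-likelihood fit.  Zero-variance columns are dropped (their
    coefficient is reported as exactly 0) with a warning.

    Returns ``(coefficients, intercept)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance feature column(s)"
        )
    Xk = X[:, keep]
    coef = np.zeros(X.shape[1])
    if Xk.shape[1] == 0:
        # intercept-only weighted MLE
        w = np.ones(y.size) if sample_weight is None else np.asarray(sample_weight)
        p = np.average(y.astype(float), weights=w)
        p = min(max(p, 1e-12), 1 - 1e-12)
        return coef, float(np.log(p / (1 - p)))
    if lam == 0:
        model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=10000, tol=1e-10)
    else:
        # liblinear: min ||beta||_1 + C * sum_i w_i NLL_i  =>  C = 1 / lam.
        # The large intercept_scaling makes the intercept penalty negligible.
        # the iteration cap bounds runtime on (near-)separable folds, where
        # the weakly-penalized optimum has very large coefficients; the
        # decision function is converged far earlier
        model = LogisticRegression(
            l1_ratio=1.0, C=1.0 / lam, solver="liblinear",
            intercept_scaling=1000.0, max_iter=3000, tol=1e-9,
            random_state=0,
        )
    model.fit(Xk, y, sample_weight=sample_weight)
    coef[keep] = model.coef_.ravel()
    return coef, float(model.intercept_[0])


def _predict_proba(X: np.ndarray, coef: np.ndarray, intercept: float) -> np.ndarray:
    z = X @ coef + intercept
    return 1.0 / (1.0 + np.exp(-z))


def _weighted_log_loss(y: np.ndarray, p: np.ndarray, w: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    ll = -(y * np.log(p) + (1 - y) * np.log(1 - p))
    return float(np.average(ll, weights=w))


def _inner_select_lambda(
    X: np.ndarray, y: np.ndarray, config: CvConfig, rng_seed: int
) -> float:
    """Pick the penalty by inner stratified k-fold CV on the training fold.

    Criterion: class-weighted cross-entropy on the validation folds
    (smooth and defined for tiny folds) or pooled AUC-ROC.  Ties favour
    the largest penalty (the more parsimonious model).
    """
    grid = np.asarray(config.lambda_grid, dtype=float)
    n_splits = min(config.inner_folds, int(np.bincount(y.astype(int)).min()))
    n_splits = max(n_splits, 2)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=rng_seed)
    scores = np.zeros(grid.size)
    for train_idx, val_idx in skf.split(X, y):
        X_tr, y_tr = X[train_idx], y[train_idx]
        X_va, y_va = X[val_idx], y[val_idx]
        if np.unique(y_tr).size < 2:
            continue
        mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        X_tr_s, X_va_s = (X_tr - mu) / sd, (X_va - mu) / sd
        w_tr = class_weights(y_tr)
        w_va = np.where(y_va == 1, y_va.size / (2.0 * max(y_va.sum(), 1)),
                        y_va.size / (2.0 * max((1 - y_va).sum(), 1)))
        for i, lam in enumerate(grid):
            coef, b = fit_lasso_logistic(X_tr_s, y_tr, lam, w_tr)
            p = _predict_proba(X_va_s, coef, b)
            if config.inner_criterion == "auc_roc":
                score = 0.5 if np.unique(y_va).size < 2 else roc_auc_score(y_va, p)
                scores[i] += -score  # lower is better
            else:
                scores[i] += _weighted_log_loss(y_va.astype(float), p, w_va)
    # ties -> largest penalty
    best = np.flatnonzero(scores <= scores.min() + 1e-12)[-1]
    return float(grid[best])


def nested_loocv_evaluate(
    feature_table: pd.DataFrame,
    feature_set: tuple[str, ...],
    config: CvConfig = CvConfig(),
    label_column: str = "group",
    positive_label: str = "ADHD",
    id_column: str = "participant_id",
) -> EvaluationReport:
    """Nested leave-one-out evaluation of one feature set.

    Rows with missing feature values are dropped (reported via the
    returned participant list).  For each outer fold: standardize from the
    training fold, choose the penalty by inner stratified CV, refit on the
    whole training fold, and record the held-out participant's predicted
    probability of the positive class.
    """
    cols = list(feature_set)
    df = feature_table.dropna(subset=cols)
    if len(df) < len(feature_table):
        warnings.warn(
            f"dropped {len(feature_table) - len(df)} participant(s) with missing features"
        )
    X = df[cols].to_numpy(dtype=float)
    y = (df[label_column] == positive_label).to_numpy().astype(int)
    ids = df[id_column].astype(str).tolist() if id_column in df else [str(i) for i in df.index]
    if np.unique(y).size < 2 or min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 participants in each class")

    n = y.size
    probs = np.empty(n)
    lambdas = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr = X[mask], y[mask]
        mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        X_tr_s = (X_tr - mu) / sd
        lam = _inner_select_lambda(X_tr_s, y_tr, config, rng_seed=config.seed)
        coef, b = fit_lasso_logistic(X_tr_s, y_tr, lam, class_weights(y_tr))
        probs[i] = _predict_proba(((X[i] - mu) / sd)[None, :], coef, b)[0]
        lambdas[i] = lam
    return EvaluationReport(
        feature_set=tuple(feature_set),
        participant_ids=ids,
        labels=y,
        probabilities=probs,
        lambdas=lambdas,
    )


def roc_pr_metrics(probabilities: np.ndarray, labels: np.ndarray) -> dict:
    """ROC and PR curves with their areas, from pooled probabilities.

    AUC-ROC by trapezoidal integration of the threshold sweep (ties split,
    so constant scores give exactly 0.5); AUC-PR by step integration over
    achievable recall points (average precision).
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, p)
    precision, recall, _ = precision_recall_curve(y, p)
    return {
        "auc_roc": float(roc_auc_score(y, p)),
        "auc_pr": float(average_precision_score(y, p)),
        "roc": (fpr, tpr),
        "pr": (recall, precision),
    }


def optimal_f1_threshold(probabilities: np.ndarray, labels: np.ndarray) -> dict:
    """Operating point maximizing F1 over all achievable probability cuts.

    Candidates are the distinct predicted probabilities (predict positive
    when p >= threshold); ties in F1 resolve to the lowest threshold
    (favouring sensitivity).  Returns the threshold, F1, sensitivity,
    specificity and confusion counts.
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    best = None
    for thr in np.unique(p):
        pred = (p >= thr).astype(int)
        tp = int(np.sum((pred == 1) & (y == 1)))
        fp = int(np.sum((pred == 1) & (y == 0)))
        fn = int(np.sum((pred == 0) & (y == 1)))
        tn = int(np.sum((pred == 0) & (y == 0)))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if best is None or f1 > best[0] + 1e-15:
            best = (f1, thr, tp, fp, fn, tn)
    f1, thr, tp, fp, fn, tn = best
    return {
        "threshold": float(thr),
        "f1": float(f1),
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
        "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    }


def feature_combination_sweep(
    feature_table: pd.DataFrame,
    features: tuple[str, ...] = ("pupil_size", "hor_fuzzyen", "vert_fuzzyen"),
    config: CvConfig = CvConfig(),
    **kwargs,
) -> dict[tuple[str, ...], EvaluationReport]:
    """Evaluate every non-empty feature subset with the identical CV protocol.

    Three candidate features yield exactly 7 reports, keyed by subset and
    ordered by descending AUC-ROC in the returned dict.
    """
    reports = {}
    for size in range(1, len(features) + 1):
        for subset in itertools.combinations(features, size):
            reports[subset] = nested_loocv_evaluate(
                feature_table, subset, config, **kwargs
            )
    return dict(
        sorted(reports.items(), key=lambda kv: kv[1].auc_roc, reverse=True)
    )
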