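"""RBF-SVM classification with leave-one-subject-out evaluation.

The outer loop is leave-one-subject-out; inside every training fold the
features are z-scored with training statistics only, and (c, g) are chosen
by exhaustive grid search (default 2^-8..2^8, step 1 in the exponent)
under stratified K-fold cross-validation.  The held-out subject never
influences standardization or model selection.  Patients are the positive
class: sensitivity is the proportion of patients correctly identified,
specificity the proportion of controls, and balanced accuracy their mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .stats import FeatureTable

__all__ = [
    "ClassifierConfig",
    "EvalResult",
    "NestedSVC",
    "standardize_features",
    "grid_search_cv",
    "loocv_evaluate",
    "compute_bac",
]

DEFAULT_EXP_GRID = tuple(float(2.0**e) for e in range(-8, 9))

POSITIVE = "patient"
NEGATIVE = "control"


@dataclass
class ClassifierConfig:
    """SVM hyper-parameter grids and inner-CV settings."""

    c_grid: tuple[float, ...] = DEFAULT_EXP_GRID
    g_grid: tuple[float, ...] = DEFAULT_EXP_GRID
    inner_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_grid or not self.g_grid:
            raise ValueError("parameter grids must be nonempty")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")


@dataclass
class EvalResult:
    """Outer-loop classification outcome (percentages)."""

    accuracy: float
    sensitivity: float
    specificity: float
    bac: float
    predictions: np.ndarray
    chosen_params: list[tuple[float, float]]
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0


def standardize_features(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score features with *training* mean/sd; constant features map to 0."""
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1) if train.shape[0] > 1 else np.zeros(train.shape[1])
    safe = np.where(sd > 0, sd, 1.0)
    z_train = (train - mean) / safe
    z_test = (test - mean) / safe
    z_train[:, sd == 0] = 0.0
    z_test[:, sd == 0] = 0.0
    return z_train, z_test


class NestedSVC(BaseEstimator, ClassifierMixin):
    """RBF-SVM with internal standardization and (C, gamma) grid search.

    ``fit`` z-scores the training features, evaluates every (C, gamma)
    pair by stratified K-fold CV accuracy (ties broken toward smaller C,
    then smaller gamma), and refits on the full training set with the
    winning pair.  The fold count adapts downward when a class is smaller
    than ``inner_folds``.
    """

    def __init__(
        self,
        c_grid: tuple[float, ...] = DEFAULT_EXP_GRID,
        g_grid: tuple[float, ...] = DEFAULT_EXP_GRID,
        inner_folds: int = 10,
        random_state: int = 0,
    ):
        self.c_grid = c_grid
        self.g_grid = g_grid
        self.inner_folds = inner_folds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        if self.classes_.size != 2:
            raise ValueError("NestedSVC requires exactly two classes in training data")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        self.scale_ = np.where(sd > 0, sd, 1.0)
        self.constant_ = sd == 0
        z = self._transform(X)

        n_splits = int(min(self.inner_folds, counts.min()))
        if n_splits >= 2 and len(self.c_grid) * len(self.g_grid) > 1:
            cv = StratifiedKFold(
                n_splits=n_splits, shuffle=True, random_state=self.random_state
            )
            folds = list(cv.split(z, y))
            best = None
            for c in sorted(self.c_grid):
                for g in sorted(self.g_grid):
                    correct = 0
                    for tr, va in folds:
                        clf = SVC(C=c, gamma=g, kernel="rbf")
                        clf.fit(z[tr], y[tr])
                        correct += int((clf.predict(z[va]) == y[va]).sum())
                    if best is None or correct > best[0]:
                        best = (correct, c, g)
            _, self.c_, self.gamma_ = best
        else:
            self.c_, self.gamma_ = sorted(self.c_grid)[0], sorted(self.g_grid)[0]
        self.cv_folds_ = n_splits
        self.svc_ = SVC(C=self.c_, gamma=self.gamma_, kernel="rbf")
        self.svc_.fit(z, y)
        return self

    def _transform(self, X):
        z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        z[:, self.constant_] = 0.0
        return z

    def predict(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.predict(self._transform(X))


def grid_search_cv(train: FeatureTable, config: ClassifierConfig) -> tuple[float, float]:
    """Best (c, g) on a training table by stratified K-fold CV accuracy."""
    model = NestedSVC(
        c_grid=config.c_grid,
        g_grid=config.g_grid,
        inner_folds=config.inner_folds,
        random_state=config.seed,
    ).fit(train.values, train.labels)
    return model.c_, model.gamma_


def loocv_evaluate(table: FeatureTable, config: ClassifierConfig) -> EvalResult:
    """Leave-one-subject-out evaluation with fully nested model selection."""
    x, y = table.values, table.labels
    n = x.shape[0]
    for g, cnt in zip(*np.unique(y, return_counts=True)):
        if cnt < 2:
            raise ValueError(f"class {g!r} needs at least 2 subjects for LOOCV")
    preds = np.empty(n, dtype=object)
    chosen = []
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        model = NestedSVC(
            c_grid=config.c_grid,
            g_grid=config.g_grid,
            inner_folds=config.inner_folds,
            random_state=config.seed,
        ).fit(x[tr], y[tr])
        preds[i] = model.predict(x[i : i + 1])[0]
        chosen.append((model.c_, model.gamma_))
    preds = preds.astype(y.dtype)

    pos, neg = POSITIVE, NEGATIVE
    tp = int(np.sum((preds == pos) & (y == pos)))
    tn = int(np.sum((preds == neg) & (y == neg)))
    fp = int(np.sum((preds == pos) & (y == neg)))
    fn = int(np.sum((preds == neg) & (y == pos)))
    acc = 100.0 * (tp + tn) / n
    sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    spec = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    return EvalResult(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        bac=compute_bac(sens, spec),
        predictions=preds,
        chosen_params=chosen,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
    )


def compute_bac(sensitivity: float, specificity: float) -> float:
    """Balanced accuracy: arithmetic mean of sensitivity and specificity (%)."""
    for v in (sensitivity, specificity):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"percentage out of range: {v}")
    return (sensitivity + specificity) / 2.0
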