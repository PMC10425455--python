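"""Maturity-stage classification: PLS-DA, SKNN and SVM.

PLS-DA regresses a one-hot stage indicator matrix by PLS and classifies by
argmax of the predicted scores; SKNN (simplified K nearest neighbour) is
interpreted as nearest class centroid — each class collapses to its mean
spectrum; SVM is an RBF-kernel one-vs-one machine with (C, gamma) chosen by
5-fold grid search.  Ties are broken toward the earlier stage (I < II <
III).  Classification operates on full-spectrum (typically SNV-treated)
spectra.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .errors import ContractError, DomainError

STAGE_ORDER = ("I", "II", "III")


def _check_labels(y) -> np.ndarray:
    y = np.asarray([str(v) for v in y])
    unknown = set(y) - set(STAGE_ORDER)
    if unknown:
        raise ContractError(f"unknown stage labels: {sorted(unknown)}")
    return y


def _check_training(X, y):
    X = np.asarray(X, float)
    y = _check_labels(y)
    present, counts = np.unique(y, return_counts=True)
    if present.size < 2:
        raise DomainError("need at least 2 classes to fit a classifier")
    if counts.min() < 2:
        raise DomainError("every class needs at least 2 training samples")
    return X, y


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """PLS discriminant analysis with CV-selected latent variables."""

    def __init__(self, n_components=None, max_components: int = 10,
                 cv_folds: int = 5, random_state: int = 0):
        self.n_components = n_components
        self.max_components = max_components
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _check_training(X, y)
        self.classes_ = np.array([c for c in STAGE_ORDER if c in set(y)])
        Y = (y[:, None] == self.classes_[None, :]).astype(float)
        cap = max(1, min(self.max_components, X.shape[1], X.shape[0] - 2))
        if self.n_components is not None:
            k = int(self.n_components)
        else:
            min_class = np.bincount(
                np.searchsorted(self.classes_, y)
            ).min()
            folds = min(self.cv_folds, int(min_class))
            k = self._choose_components(X, y, Y, cap, max(folds, 2))
        self.n_components_ = k
        self.pls_ = PLSRegression(n_components=k, scale=False).fit(X, Y)
        return self

    def _choose_components(self, X, y, Y, cap, folds):
        skf = StratifiedKFold(n_splits=folds)
        accs = []
        for k in range(1, cap + 1):
            correct = 0
            for tr, te in skf.split(X, y):
                pls = PLSRegression(
                    n_components=min(k, len(tr) - 1), scale=False
                ).fit(X[tr], Y[tr])
                pred = self.classes_[np.argmax(pls.predict(X[te]), axis=1)]
                correct += int((pred == y[te]).sum())
            accs.append(correct)
        return int(np.argmax(accs)) + 1  # argmax is first-max: fewest LVs on ties

    def predict(self, X):
        scores = np.asarray(self.pls_.predict(np.asarray(X, float)))
        return self.classes_[np.argmax(scores, axis=1)]  # ties -> earlier stage


class SKNNClassifier(ClassifierMixin, BaseEstimator):
    """Simplified K nearest neighbour: nearest class-centroid spectrum.

    Each stage is represented by its mean training spectrum; a sample is
    assigned to the class whose centroid is nearest in Euclidean distance,
    ties going to the earlier stage.
    """

    def fit(self, X, y):
        X, y = _check_training(X, y)
        self.classes_ = np.array([c for c in STAGE_ORDER if c in set(y)])
        self.centroids_ = np.stack([X[y == c].mean(axis=0) for c in self.classes_])
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        d = np.linalg.norm(X[:, None, :] - self.centroids_[None, :, :], axis=2)
        return self.classes_[np.argmin(d, axis=1)]  # argmin first-min: earlier stage


class SVMStageClassifier(ClassifierMixin, BaseEstimator):
    """RBF-kernel SVM, one-vs-one, with (C, gamma) by 5-fold grid search.

    The default grid is C in 2^-5..2^10 and gamma in 2^-10..2^3 (powers of
    two).  Deterministic: the grid search uses unshuffled stratified folds.
    """

    def __init__(self, c_grid=None, gamma_grid=None, cv_folds: int = 5,
                 random_state: int = 0):
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _check_training(X, y)
        self.classes_ = np.array([c for c in STAGE_ORDER if c in set(y)])
        c_grid = (self.c_grid if self.c_grid is not None
                  else 2.0 ** np.arange(-5, 11))
        gamma_grid = (self.gamma_grid if self.gamma_grid is not None
                      else 2.0 ** np.arange(-10, 4))
        folds = min(self.cv_folds, int(np.unique(y, return_counts=True)[1].min()))
        search = GridSearchCV(
            SVC(kernel="rbf", decision_function_shape="ovo"),
            {"C": list(c_grid), "gamma": list(gamma_grid)},
            cv=StratifiedKFold(n_splits=max(folds, 2)),
            n_jobs=None,
        )
        search.fit(X, y)
        self.best_params_ = search.best_params_
        self.svc_ = search.best_estimator_
        return self

    def predict(self, X):
        return self.svc_.predict(np.asarray(X, float))


CLASSIFIER_FAMILIES = {
    "PLSDA": PLSDAClassifier,
    "SKNN": SKNNClassifier,
    "SVM": SVMStageClassifier,
}


def fit_classifier(family: str, X_cal, labels, hyperparams: dict | None = None,
                   seed: int = 0):
    """Fit one classifier family on calibration spectra and stage labels."""
    if family not in CLASSIFIER_FAMILIES:
        raise ContractError(
            f"unknown classifier family {family!r}; expected {list(CLASSIFIER_FAMILIES)}"
        )
    params = dict(hyperparams or {})
    cls = CLASSIFIER_FAMILIES[family]
    if family != "SKNN":
        params.setdefault("random_state", seed)
    return cls(**params).fit(X_cal, labels)


def classify(model, X) -> np.ndarray:
    return model.predict(X)


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 stage confusion counts (rows true, columns predicted)."""

    counts: np.ndarray
    set_name: str = "pred"  # {"cal", "pred"}

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (len(STAGE_ORDER), len(STAGE_ORDER)) or np.any(c < 0):
            raise ContractError("confusion matrix must be 3x3 with counts >= 0")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_errors(self) -> int:
        return int(self.counts.sum() - np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(STAGE_ORDER),
                            columns=list(STAGE_ORDER))


def confusion(true_labels, predicted, set_name: str = "pred") -> ConfusionMatrix:
    """Stage confusion matrix (rows true, columns predicted, order I/II/III)."""
    t = _check_labels(true_labels)
    p = _check_labels(predicted)
    if t.size != p.size:
        raise ContractError("true/predicted length mismatch")
    return ConfusionMatrix(
        _sk_confusion(t, p, labels=list(STAGE_ORDER)), set_name=set_name
    )


@dataclass(frozen=True)
class AccuracyReport:
    """Calibration/prediction/pooled accuracies, percentages to 2 decimals."""

    n_cal: int
    err_cal: int
    acc_cal: float
    n_pred: int
    err_pred: int
    acc_pred: float
    acc_total: float

    def to_row(self) -> dict:
        return {
            "Num_cal": self.n_cal, "Error_cal": self.err_cal,
            "Accuracy_cal_pct": self.acc_cal,
            "Num_pred": self.n_pred, "Error_pred": self.err_pred,
            "Accuracy_pred_pct": self.acc_pred,
            "Total_accuracy_pct": self.acc_total,
        }


def accuracy_report(cm_cal: ConfusionMatrix, cm_pred: ConfusionMatrix) -> AccuracyReport:
    """Accuracy arithmetic: acc = 100 (n - err) / n per set and pooled."""
    if cm_cal.n == 0 or cm_pred.n == 0:
        raise DomainError("empty calibration or prediction set")
    n_c, e_c = cm_cal.n, cm_cal.n_errors
    n_p, e_p = cm_pred.n, cm_pred.n_errors
    return AccuracyReport(
        n_cal=n_c, err_cal=e_c, acc_cal=round(100.0 * (n_c - e_c) / n_c, 2),
        n_pred=n_p, err_pred=e_p, acc_pred=round(100.0 * (n_p - e_p) / n_p, 2),
        acc_total=round(100.0 * (n_c + n_p - e_c - e_p) / (n_c + n_p), 2),
    )
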