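"""One-against-all SVM classification and confusion-matrix evaluation.

The base classifier trains one binary linear SVM (C = 1) per lesion class
on z-scored features and predicts the class with the maximum decision
value, ties broken toward the earlier class in label order.

:class:`LesionClassifier` is the end-of-pipeline composite estimator: it
takes the *raw* per-sample feature rows (3780 HOG + 42 texture + 36 color
= 3858 columns), fits the PCA-weighted entropy HOG reduction (-> 200),
applies zero-padded parallel fusion (-> 200), fits the entropy-variance
selector (-> 172) and the one-vs-all SVM — so cross-validation through it
refits every data-dependent stage on the training folds only, with no
leakage into the test folds.

Evaluation metrics follow confusion-matrix arithmetic: per-class
sensitivity = diag / row sum, accuracy = trace / total, specificity and
precision macro-averaged, FNR = 100 - sensitivity (percent) and
FPR = 1 - specificity/100 (fraction), plus macro one-vs-rest ROC AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .features import (
    COLOR_LENGTH,
    FUSED_LENGTH,
    HOG_LENGTH,
    TEXTURE_LENGTH,
    HogEntropyReducer,
    zero_pad,
)
from .select import EntropyVarianceSelector

__all__ = [
    "EvalReport",
    "EvalResult",
    "OneVsAllSVM",
    "LesionClassifier",
    "metrics_from_confusion",
    "auc_ovr",
    "evaluate_protocol",
]

logger = logging.getLogger(__name__)

RAW_LENGTH = HOG_LENGTH + TEXTURE_LENGTH + COLOR_LENGTH


@dataclass
class EvalReport:
    """Macro-averaged confusion-matrix measures.

    Percent scales for sensitivity/specificity/precision/accuracy/FNR;
    FPR is a fraction in [0, 1]; AUC in [0, 1] when scores were available.
    """

    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    fnr: float
    fpr: float
    auc: float | None = None
    per_class_sensitivity: dict = field(default_factory=dict)


@dataclass
class EvalResult:
    report: EvalReport
    confusion: np.ndarray
    classes: list


class OneVsAllSVM(BaseEstimator, ClassifierMixin):
    """One-against-all multi-class linear SVM on z-scored features.

    One binary SVC (linear kernel, C = 1 by default) is trained per class
    against the rest; prediction takes the argmax of the per-class decision
    values, ties resolved toward the earlier class in sorted label order.
    """

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        if counts.min() < 2:
            raise ValueError("need at least 2 samples per class")
        self.classes_ = classes
        self.scaler_ = StandardScaler().fit(X)
        Z = self.scaler_.transform(X)
        self.estimators_ = []
        for c in classes:
            clf = SVC(kernel="linear", C=self.C)
            clf.fit(Z, (y == c).astype(int))
            self.estimators_.append(clf)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "estimators_")
        Z = self.scaler_.transform(np.asarray(X, dtype=float))
        return np.column_stack([est.decision_function(Z) for est in self.estimators_])

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]  # first max wins ties


class LesionClassifier(BaseEstimator, ClassifierMixin):
    """Raw-features-to-label composite: HOG reduction, parallel fusion,
    entropy-variance selection, one-vs-all SVM.

    ``X`` rows are the concatenation [hog(3780) | texture(42) | color(36)].
    All data-dependent stages are fitted inside :meth:`fit`, so the whole
    chain is leakage-free under cross-validation.
    """

    def __init__(self, n_hog_keep: int = FUSED_LENGTH, n_select: int = 172,
                 C: float = 1.0):
        self.n_hog_keep = n_hog_keep
        self.n_select = n_select
        self.C = C

    @staticmethod
    def _split(X: np.ndarray):
        if X.shape[1] != RAW_LENGTH:
            raise ValueError(
                f"expected {RAW_LENGTH} raw feature columns, got {X.shape[1]}"
            )
        return (
            X[:, :HOG_LENGTH],
            X[:, HOG_LENGTH:HOG_LENGTH + TEXTURE_LENGTH],
            X[:, HOG_LENGTH + TEXTURE_LENGTH:],
        )

    @staticmethod
    def _fuse(hog200: np.ndarray, tex: np.ndarray, col: np.ndarray) -> np.ndarray:
        tp = np.stack([zero_pad(row, FUSED_LENGTH) for row in tex])
        cp = np.stack([zero_pad(row, FUSED_LENGTH) for row in col])
        return np.hypot(hog200, tp) + np.hypot(hog200, cp)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        hog, tex, col = self._split(X)
        self.reducer_ = HogEntropyReducer(n_keep=self.n_hog_keep).fit(hog)
        fused = self._fuse(self.reducer_.transform(hog), tex, col)
        self.selector_ = EntropyVarianceSelector(n_keep=self.n_select).fit(fused)
        self.svm_ = OneVsAllSVM(C=self.C).fit(self.selector_.transform(fused), y)
        self.classes_ = self.svm_.classes_
        return self

    def _transform(self, X):
        check_is_fitted(self, "svm_")
        X = np.asarray(X, dtype=float)
        hog, tex, col = self._split(X)
        fused = self._fuse(self.reducer_.transform(hog), tex, col)
        return self.selector_.transform(fused)

    def decision_function(self, X):
        return self.svm_.decision_function(self._transform(X))

    def predict(self, X):
        return self.svm_.predict(self._transform(X))


def metrics_from_confusion(cm: np.ndarray, classes=None) -> EvalReport:
    """Macro-averaged measures from a K x K confusion matrix (rows = true).

    Classes with a zero row (or column, for precision) are excluded from
    the macro averages with a warning.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    total = cm.sum()
    diag = np.diag(cm)
    row = cm.sum(axis=1)
    colsum = cm.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(row > 0, 100.0 * diag / row, np.nan)
        prec = np.where(colsum > 0, 100.0 * diag / colsum, np.nan)
        tn = total - row - colsum + diag
        fp = colsum - diag
        spec = np.where(tn + fp > 0, 100.0 * tn / (tn + fp), np.nan)
    if np.any(np.isnan(sens)):
        logger.warning("classes with zero row sum excluded from macro averages")
    if np.any(np.isnan(prec)):
        logger.warning("classes with zero column sum excluded from macro precision")

    sensitivity = float(np.nanmean(sens))
    specificity = float(np.nanmean(spec))
    precision = float(np.nanmean(prec))
    accuracy = float(100.0 * diag.sum() / total)
    names = list(classes) if classes is not None else list(range(cm.shape[0]))
    return EvalReport(
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        accuracy=accuracy,
        fnr=100.0 - sensitivity,
        fpr=1.0 - specificity / 100.0,
        per_class_sensitivity={n: float(s) for n, s in zip(names, sens)},
    )


def auc_ovr(scores: np.ndarray, labels, classes=None) -> float:
    """Macro one-vs-rest ROC AUC from per-class decision scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels) if classes is None else np.asarray(classes)
    if classes.size < 2:
        raise ValueError("AUC undefined for a single class")
    if scores.ndim != 2 or scores.shape[1] != classes.size:
        raise ValueError("scores must be (n_samples, n_classes)")
    aucs = [
        roc_auc_score((labels == c).astype(int), scores[:, k])
        for k, c in enumerate(classes)
    ]
    return float(np.mean(aucs))


def evaluate_protocol(
    X,
    y,
    protocol: str = "holdout_50_50",
    seed: int = 0,
    estimator: BaseEstimator | None = None,
) -> EvalResult:
    """Evaluate a classifier under the stated validation protocol.

    ``holdout_50_50``: stratified 50:50 train/test split. ``cv_10fold``:
    stratified 10-fold cross-validation where every sample is predicted
    exactly once and the fold confusions are aggregated. The estimator
    (default :class:`LesionClassifier`) is cloned and refitted per fold, so
    feature reduction, selection and scaling see training data only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    base = estimator if estimator is not None else LesionClassifier()

    if protocol == "holdout_50_50":
        idx_tr, idx_te = train_test_split(
            np.arange(len(y)), test_size=0.5, stratify=y, random_state=seed
        )
        model = clone(base).fit(X[idx_tr], y[idx_tr])
        y_pred = model.predict(X[idx_te])
        y_true = y[idx_te]
        scores = (
            model.decision_function(X[idx_te])
            if hasattr(model, "decision_function")
            else None
        )
    elif protocol == "cv_10fold":
        counts = np.array([(y == c).sum() for c in classes])
        if counts.min() < 10:
            raise ValueError("every class needs at least 10 samples for 10-fold CV")
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
        y_pred = np.empty_like(y)
        has_scores = hasattr(base, "decision_function")
        scores = np.empty((len(y), classes.size)) if has_scores else None
        for tr, te in skf.split(X, y):
            model = clone(base).fit(X[tr], y[tr])
            y_pred[te] = model.predict(X[te])
            if has_scores:
                scores[te] = model.decision_function(X[te])
        y_true = y
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    cm = _sk_confusion(y_true, y_pred, labels=classes)
    report = metrics_from_confusion(cm, classes=classes)
    if scores is not None:
        try:
            report.auc = auc_ovr(scores, y_true, classes=classes)
        except ValueError:
            report.auc = None
    return EvalResult(report=report, confusion=cm, classes=list(classes))
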