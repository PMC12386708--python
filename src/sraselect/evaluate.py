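"""Stratified cross-validated training and evaluation of the CNN classifier."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .metrics import confusion_matrix, macro_auc, macro_f1
from .nn import FocalCNNClassifier

__all__ = ["MetricsReport", "train_cv", "evaluate_on"]


@dataclass
class MetricsReport:
    """Validation (per-fold) and optional held-out-test classification metrics."""

    per_fold: list  # [(macro_f1_pct, macro_auc), ...]
    macro_f1: float  # mean validation macro F1, percent
    macro_f1_sd: float
    macro_auc: float  # mean validation macro AUC
    macro_auc_sd: float
    confusion: np.ndarray  # summed over validation folds
    test_macro_f1: float | None = None
    test_macro_auc: float | None = None
    test_confusion: np.ndarray | None = None

    def summary(self) -> str:
        s = (
            f"validation macro F1 {self.macro_f1:.2f}% +/- {self.macro_f1_sd:.2f}, "
            f"macro AUC {self.macro_auc:.4f} +/- {self.macro_auc_sd:.4f} "
            f"({len(self.per_fold)} folds)"
        )
        if self.test_macro_f1 is not None:
            s += f"; test macro F1 {self.test_macro_f1:.2f}%, AUC {self.test_macro_auc:.4f}"
        return s


def evaluate_on(model, X, y, classes) -> tuple[float, float, np.ndarray]:
    """(macro F1 %, macro AUC, confusion) of a fitted classifier on (X, y)."""
    probs = model.predict_proba(X)
    pred = model.classes_[np.argmax(probs, axis=1)]
    conf = confusion_matrix(y, pred, classes=classes)
    return macro_f1(conf), macro_auc(probs, y, classes=classes), conf


def train_cv(
    X,
    y,
    classifier: FocalCNNClassifier | None = None,
    n_folds: int = 5,
    seed: int = 0,
    X_test=None,
    y_test=None,
) -> MetricsReport:
    """Stratified k-fold CV of the focal-loss CNN on a selected SNP panel.

    Each fold trains a fresh clone of ``classifier`` on the in-fold 80% (for
    5 folds) and evaluates macro F1 / macro AUC on the held-out fold. When a
    test set is supplied, a final model trained on all of (X, y) is evaluated
    on it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    classes = np.unique(y)
    base = classifier if classifier is not None else FocalCNNClassifier()
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    per_fold = []
    conf_total = np.zeros((len(classes), len(classes)), dtype=int)
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        if len(np.unique(y[va])) < len(classes) or len(np.unique(y[tr])) < len(classes):
            raise ValueError(f"fold {fold} lacks at least one class")
        model = clone(base)
        model.set_params(random_state=base.random_state + fold)
        model.fit(X[tr], y[tr])
        f1, auc, conf = evaluate_on(model, X[va], y[va], classes)
        per_fold.append((f1, auc))
        conf_total += conf
    f1s = np.array([f for f, _ in per_fold])
    aucs = np.array([a for _, a in per_fold])
    report = MetricsReport(
        per_fold=per_fold,
        macro_f1=float(f1s.mean()),
        macro_f1_sd=float(f1s.std(ddof=1)) if len(f1s) > 1 else 0.0,
        macro_auc=float(aucs.mean()),
        macro_auc_sd=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        confusion=conf_total,
    )
    if X_test is not None:
        final = clone(base).fit(X, y)
        f1, auc, conf = evaluate_on(final, np.asarray(X_test, dtype=float), y_test, classes)
        report.test_macro_f1 = f1
        report.test_macro_auc = auc
        report.test_confusion = conf
    return report
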