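"""Classification losses and multi-class evaluation metrics.

Macro F1 here is the harmonic mean of macro-averaged precision and
macro-averaged recall (not the mean of per-class F1 scores), and macro AUC is
the unweighted mean of one-vs-rest AUCs computed by the rank-sum
(Mann-Whitney) formulation, so tied scores earn half credit.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "reduction_rate",
    "cross_entropy",
    "focal_alpha",
    "focal_loss",
    "macro_f1",
    "macro_auc",
    "confusion_matrix",
]

_EPS = 1e-15


def reduction_rate(n_selected: int, n_total: int) -> float:
    """Percentage of features removed by a selection: 100 * (1 - kept/total)."""
    if not 0 <= n_selected <= n_total or n_total == 0:
        raise ValueError("need 0 <= n_selected <= n_total, n_total > 0")
    return 100.0 * (1.0 - n_selected / n_total)


def _true_class_probs(probs: np.ndarray, true_labels: np.ndarray, classes=None):
    probs = np.asarray(probs, dtype=float)
    true_labels = np.asarray(true_labels)
    if probs.ndim != 2 or len(true_labels) != probs.shape[0]:
        raise ValueError(
            f"shape mismatch: probs {probs.shape} vs {len(true_labels)} labels"
        )
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    if classes is None:
        classes = np.unique(true_labels)
    idx = np.searchsorted(classes, true_labels)
    if (np.asarray(classes)[idx] != true_labels).any():
        raise ValueError("true_labels contain classes absent from `classes`")
    return np.clip(probs[np.arange(len(true_labels)), idx], _EPS, 1.0), idx


def cross_entropy(true_labels, probs, classes=None) -> float:
    """Mean negative log-probability of the true class.

    ``probs`` rows are softmax probabilities over the (sorted) class set;
    probabilities are clamped at 1e-15 before the log.
    """
    p_true, _ = _true_class_probs(np.asarray(probs), true_labels, classes)
    return float(-np.mean(np.log(p_true)))


def focal_alpha(n: int, class_counts) -> np.ndarray:
    """Class-balancing weights alpha_b = N / (B * g_b).

    Balanced classes give alpha = 1; rarer classes get proportionally larger
    weight.
    """
    g = np.asarray(class_counts, dtype=float)
    if (g <= 0).any():
        raise ValueError("class counts must be positive")
    if int(g.sum()) != n:
        raise ValueError(f"class counts sum to {int(g.sum())}, expected {n}")
    return n / (len(g) * g)


def focal_loss(probs, true_labels, alphas, gamma: float = 2.0, classes=None) -> float:
    """Mean focal loss: alpha_b * (1 - p_true)^gamma * (-log p_true).

    The (1-p)^gamma factor down-weights well-classified examples; alpha_b
    rebalances class frequencies (see :func:`focal_alpha`).
    """
    probs = np.asarray(probs, dtype=float)
    alphas = np.asarray(alphas, dtype=float)
    if alphas.shape[0] != probs.shape[1]:
        raise ValueError("alphas length must equal the number of classes")
    p_true, idx = _true_class_probs(probs, true_labels, classes)
    return float(
        np.mean(alphas[idx] * (1.0 - p_true) ** gamma * (-np.log(p_true)))
    )


def confusion_matrix(true_labels, pred_labels, classes=None) -> np.ndarray:
    """B x B confusion matrix; rows = true class, columns = predicted."""
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if classes is None:
        classes = np.unique(np.concatenate([true_labels, pred_labels]))
    classes = np.asarray(classes)
    t = np.searchsorted(classes, true_labels)
    p = np.searchsorted(classes, pred_labels)
    b = len(classes)
    return np.bincount(t * b + p, minlength=b * b).reshape(b, b)


def macro_f1(confusion: np.ndarray) -> float:
    """Macro F1 in percent from a confusion matrix.

    Precision and recall are macro-averaged over classes first; F1 is their
    harmonic mean. A class with zero predicted (or zero actual) individuals
    contributes 0 to the corresponding average.
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    tp = np.diag(c)
    pred_tot = c.sum(axis=0)
    true_tot = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        rec = np.where(true_tot > 0, tp / true_tot, 0.0)
    precision = prec.mean()
    recall = rec.mean()
    if precision + recall == 0:
        return 0.0
    return float(100.0 * 2.0 * precision * recall / (precision + recall))


def macro_auc(scores: np.ndarray, true_labels, classes=None) -> float:
    """Mean one-vs-rest AUC over classes, by the rank-sum formulation.

    Classes without both a positive and a negative individual are skipped
    (with a warning); if every class is skipped an error is raised.
    """
    scores = np.asarray(scores, dtype=float)
    true_labels = np.asarray(true_labels)
    if scores.ndim != 2 or scores.shape[0] != len(true_labels):
        raise ValueError("scores must be N x B with one row per labelled individual")
    if classes is None:
        classes = np.unique(true_labels)
    classes = np.asarray(classes)
    aucs = []
    for b, cls in enumerate(classes):
        pos = true_labels == cls
        n_pos = int(pos.sum())
        n_neg = len(true_labels) - n_pos
        if n_pos == 0 or n_neg == 0:
            warnings.warn(f"class {cls!r} lacks positives or negatives; skipped")
            continue
        ranks = rankdata(scores[:, b])  # average ranks -> ties get 0.5 credit
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
        aucs.append(auc)
    if not aucs:
        raise ValueError("no class had both positives and negatives")
    return float(np.mean(aucs))
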