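"""Independent brute-force oracles used by unit and acceptance tests.

Each function recomputes a quantity by enumeration or a direct dense formula,
deliberately avoiding the implementation path it checks.
"""

from itertools import combinations

import numpy as np


def dense_mme_solve(z: np.ndarray, y: np.ndarray, lam: float, intercept=True):
    """Direct dense solve of the mixed model equations."""
    z = np.asarray(z, dtype=float)
    k, p = z.shape
    if intercept:
        a = np.zeros((p + 1, p + 1))
        a[0, 0] = k
        a[0, 1:] = z.sum(axis=0)
        a[1:, 0] = z.sum(axis=0)
        a[1:, 1:] = z.T @ z + lam * np.eye(p)
        rhs = np.concatenate([[y.sum()], z.T @ y])
    else:
        a = z.T @ z + lam * np.eye(p)
        rhs = z.T @ y
    return np.linalg.solve(a, rhs)


def cross_entropy_brute(true_idx, probs):
    """Plain per-sample loop of the mean negative log true-class probability."""
    total = 0.0
    for i, t in enumerate(true_idx):
        total += -np.log(max(probs[i][t], 1e-15))
    return total / len(true_idx)


def macro_f1_brute(confusion):
    """Per-class precision/recall loops, macro averages, harmonic mean."""
    c = np.asarray(confusion, dtype=float)
    b = c.shape[0]
    precs, recs = [], []
    for j in range(b):
        tp = c[j, j]
        fp = sum(c[i, j] for i in range(b)) - tp
        fn = sum(c[j, i] for i in range(b)) - tp
        precs.append(tp / (tp + fp) if tp + fp > 0 else 0.0)
        recs.append(tp / (tp + fn) if tp + fn > 0 else 0.0)
    p, r = np.mean(precs), np.mean(recs)
    return 0.0 if p + r == 0 else 100.0 * 2 * p * r / (p + r)


def auc_concordance(scores, positives):
    """One-vs-rest AUC by counting concordant pairs (ties half credit)."""
    pos = np.flatnonzero(positives)
    neg = np.flatnonzero(~np.asarray(positives, dtype=bool))
    total = 0.0
    for i in pos:
        for j in neg:
            if scores[i] > scores[j]:
                total += 1.0
            elif scores[i] == scores[j]:
                total += 0.5
    return total / (len(pos) * len(neg))


def best_two_partition(points):
    """Minimum within-cluster sum of squares over all 2-partitions (<= ~15 rows).

    Returns (best_assignment, best_wss); assignment is a boolean array.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < len(points):  # 1-D input
        pts = np.asarray(points, dtype=float)[:, None]
    n = pts.shape[0]
    best, best_wss = None, np.inf
    for r in range(1, n // 2 + 1):
        for subset in combinations(range(n), r):
            mask = np.zeros(n, dtype=bool)
            mask[list(subset)] = True
            wss = 0.0
            for m in (mask, ~mask):
                c = pts[m].mean(axis=0)
                wss += ((pts[m] - c) ** 2).sum()
            if wss < best_wss:
                best, best_wss = mask.copy(), wss
    return best, best_wss


def greedy_tagging_dense(r2: np.ndarray, pos, window_bp, r2_max):
    """Reference greedy scan over a precomputed dense r² matrix."""
    kept = []
    for j in range(len(pos)):
        ok = True
        for t in kept:
            if pos[j] - pos[t] <= window_bp and r2[j, t] > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return kept
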