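"""Independent brute-force oracles used to validate the fast implementations.

Everything here deliberately avoids the code paths it checks: metrics are
computed by explicit pair/threshold enumeration, the simplex QP by
exhaustive grid evaluation, and propagation by partial geometric sums.
"""

from __future__ import annotations

import numpy as np


def simplex_grid(K: int, step: float = 1e-3) -> np.ndarray:
    """All points of the probability simplex on a regular grid (K <= 3)."""
    n = int(round(1.0 / step))
    if K == 1:
        return np.array([[1.0]])
    if K == 2:
        w1 = np.arange(n + 1) / n
        return np.column_stack([w1, 1.0 - w1])
    if K == 3:
        i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
        keep = i + j <= n
        w1 = i[keep] / n
        w2 = j[keep] / n
        return np.column_stack([w1, w2, 1.0 - w1 - w2])
    raise ValueError("grid oracle only supports K <= 3")


def grid_search_qp(A: np.ndarray, step: float = 1e-3) -> tuple[np.ndarray, float]:
    """Minimize w'Aw over the gridded simplex by exhaustive evaluation."""
    W = simplex_grid(A.shape[0], step)
    vals = np.einsum("ij,jk,ik->i", W, A, W)
    best = int(np.argmin(vals))
    return W[best], float(vals[best])


def auc_bruteforce(scores, labels) -> float:
    """Mann-Whitney AUC by explicit enumeration of all (pos, neg) pairs."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, float)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def aupr_bruteforce(scores, labels) -> float:
    """Step-integral AUPR by looping over distinct thresholds descending."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, float)
    n_pos = y.sum()
    thresholds = sorted(set(s), reverse=True)
    area = 0.0
    recall_prev = 0.0
    for t in thresholds:
        called = s >= t
        tp = float(y[called].sum())
        precision = tp / called.sum()
        recall = tp / n_pos
        area += (recall - recall_prev) * precision
        recall_prev = recall
    return area


def propagate_partial_sums(W, Y, alpha, n_terms=2000) -> np.ndarray:
    """Geometric-series view of propagation: (1-a) * sum_k (aW)^k Y."""
    W = np.asarray(W, float)
    Y = np.asarray(Y, float)
    term = Y.copy()
    acc = Y.copy()
    for _ in range(n_terms - 1):
        term = alpha * (W @ term)
        acc += term
    return (1.0 - alpha) * acc
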