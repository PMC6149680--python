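"""Leave-one-out cross-validation over drug-target pairs, AUC and AUPR.

Every known interaction is masked in turn, the model is retrained on the
remaining pairs, and the masked pair's score is recorded; pairs that are
already 0 keep their score from the unmasked model (their training label is
unchanged by masking, so re-running the fit for them would reproduce it).
AUC is the Mann-Whitney statistic, AUPR the step-wise (average-precision)
integral of the precision-recall curve — negatives vastly outnumber
positives in interaction networks, which is why AUPR is the primary metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import rankdata

from .datamodel import FeatureMatrix, InteractionMatrix, interaction_profiles
from .errors import ParameterError, UndefinedMetricError, ValidationError
from .propagation import PropagationParams, ScoreMatrix, propagate_closed_form
from .similarity import (
    BASELINE_METHODS,
    LnsHyperParams,
    SimilarityMatrix,
    baseline_similarity,
    lns_similarity,
    row_normalize,
)

__all__ = [
    "CVResult",
    "GridSearchResult",
    "auc",
    "aupr",
    "loocv",
    "held_out_scores",
    "grid_search",
    "build_similarity",
    "build_scores",
]


def _as_1d(x) -> np.ndarray:
    return np.asarray(x, dtype=float).ravel()


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Fraction of (positive, negative) pairs ranked correctly, ties counted
    one half; identical to trapezoidal integration of the ROC curve.
    """
    s, y = _as_1d(scores), _as_1d(labels)
    if s.shape != y.shape:
        raise ValidationError("scores and labels differ in length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("labels must be binary")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"AUC undefined: {n_pos} positives, {n_neg} negatives"
        )
    ranks = rankdata(s, method="average")
    return float(
        (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve, step convention.

    Thresholds sweep the distinct scores descending with ties grouped at a
    single threshold; the area is sum over thresholds of
    (recall_i - recall_{i-1}) * precision_i, i.e. average precision with no
    linear interpolation between points.
    """
    s, y = _as_1d(scores), _as_1d(labels)
    if s.shape != y.shape:
        raise ValidationError("scores and labels differ in length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("labels must be binary")
    n_pos = int(y.sum())
    if n_pos == 0:
        raise UndefinedMetricError("AUPR undefined without positives")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # last index of each tied-score group
    boundaries = np.flatnonzero(np.diff(s_sorted) != 0)
    last = np.append(boundaries, s_sorted.size - 1)
    tp = np.cumsum(y_sorted)[last]
    pred_pos = last + 1.0
    precision = tp / pred_pos
    recall = tp / n_pos
    recall_prev = np.concatenate(([0.0], recall[:-1]))
    return float(np.sum((recall - recall_prev) * precision))


def build_similarity(
    X: FeatureMatrix,
    method: str,
    lns_params: LnsHyperParams | None = None,
    gauss_bandwidth: str = "squared_norm",
) -> SimilarityMatrix:
    """Similarity matrix ready for propagation (row-stochastic, zero diagonal)."""
    if method == "lns":
        if lns_params is None:
            raise ParameterError("lns similarity requires LnsHyperParams")
        return lns_similarity(X, lns_params)
    if method in BASELINE_METHODS:
        S = baseline_similarity(X, method, gauss_bandwidth=gauss_bandwidth)
        return row_normalize(S)
    raise ParameterError(f"unknown similarity method {method!r}")


def _resolve_view(
    Y: InteractionMatrix, view: FeatureMatrix | str
) -> FeatureMatrix:
    if isinstance(view, str):
        if view != "profile":
            raise ParameterError(f"unknown feature view {view!r}")
        return interaction_profiles(Y)
    if view.nd != Y.nd:
        raise ValidationError(
            f"feature view covers {view.nd} drugs, interactions {Y.nd}"
        )
    if list(view.drug_ids) != list(Y.drug_ids):
        raise ValidationError(
            "feature view drug IDs do not match the interaction matrix"
        )
    return view


def build_scores(
    Y: InteractionMatrix,
    view: FeatureMatrix | str = "profile",
    lns_params: LnsHyperParams | None = None,
    prop_params: PropagationParams | None = None,
    similarity: str = "lns",
) -> ScoreMatrix:
    """Full pipeline on the unmasked data: features -> W -> propagation."""
    if prop_params is None:
        raise ParameterError("propagation parameters are required")
    X = _resolve_view(Y, view)
    W = build_similarity(X, similarity, lns_params)
    return propagate_closed_form(W, Y, prop_params.alpha)


@dataclass
class CVResult:
    """Per-pair held-out records plus the two summary ranking metrics."""

    records: pd.DataFrame
    auc: float
    aupr: float
    params_used: dict = field(default_factory=dict)


def _held_out_fixed_w(
    W: SimilarityMatrix, Y: InteractionMatrix, alpha: float
) -> np.ndarray:
    """Held-out scores when W does not depend on the masked label.

    With M = (I - alpha W)^-1, masking the single entry (i, j) of Y is a
    rank-one perturbation, so the masked model's score of the held-out pair
    is F[i, j] - (1 - alpha) * M[i, i] exactly.
    """
    Wv = W.values
    nd = Wv.shape[0]
    A = np.eye(nd) - alpha * Wv
    lu, piv = scipy.linalg.lu_factor(A)
    M = scipy.linalg.lu_solve((lu, piv), np.eye(nd))
    F = (1.0 - alpha) * (M @ Y.values)
    scores = F.copy()
    pos = Y.values == 1
    diag = np.diag(M)
    scores[pos] = (F - (1.0 - alpha) * diag[:, None])[pos]
    return scores


def held_out_scores(
    Y: InteractionMatrix,
    view: FeatureMatrix | str = "profile",
    lns_params: LnsHyperParams | None = None,
    prop_params: PropagationParams | None = None,
    similarity: str = "lns",
    refit: str = "full",
) -> np.ndarray:
    """LOOCV score matrix: entry (i, j) is pair (i, j)'s held-out score.

    refit="full" recomputes features (for the profile view), neighborhoods
    and W from the masked interaction matrix for every held-out known pair —
    the only reading in which the masked label cannot leak through the
    similarity.  refit="fixed_w" keeps W from the unmasked data and masks
    only the label, a fast approximation that is *exact* whenever the
    feature view does not depend on the labels (fingerprints).
    """
    if refit not in ("full", "fixed_w"):
        raise ParameterError(f"unknown refit mode {refit!r}")
    if prop_params is None:
        raise ParameterError("propagation parameters are required")
    X = _resolve_view(Y, view)
    label_dependent = X.feature_kind == "interaction_profile" and isinstance(
        view, str
    )
    if refit == "fixed_w" or not label_dependent:
        W = build_similarity(X, similarity, lns_params)
        return _held_out_fixed_w(W, Y, prop_params.alpha)
    # full refit: every positive pair gets its own masked model
    F_full = build_scores(Y, view, lns_params, prop_params, similarity).values
    scores = F_full.copy()
    for i, j in zip(*np.where(Y.values == 1)):
        Ym = Y.masked(int(i), int(j))
        Fm = build_scores(Ym, "profile", lns_params, prop_params, similarity)
        scores[i, j] = Fm.values[i, j]
    return scores


def loocv(
    Y: InteractionMatrix,
    view: FeatureMatrix | str = "profile",
    lns_params: LnsHyperParams | None = None,
    prop_params: PropagationParams | None = None,
    similarity: str = "lns",
    refit: str = "full",
) -> CVResult:
    """Leave-one-out cross-validation over all nd*nt drug-target pairs."""
    scores = held_out_scores(
        Y, view, lns_params, prop_params, similarity, refit
    )
    nd, nt = Y.values.shape
    di, tj = np.meshgrid(np.arange(nd), np.arange(nt), indexing="ij")
    records = pd.DataFrame(
        {
            "drug_id": np.array(Y.drug_ids, dtype=object)[di.ravel()],
            "target_id": np.array(Y.target_ids, dtype=object)[tj.ravel()],
            "label": Y.values.ravel().astype(int),
            "score": scores.ravel(),
        }
    )
    params_used = {
        "K": lns_params.K if lns_params else None,
        "alpha": prop_params.alpha if prop_params else None,
        "similarity": similarity,
        "view": view if isinstance(view, str) else view.feature_kind,
        "refit": refit,
    }
    return CVResult(
        records=records,
        auc=auc(records["score"], records["label"]),
        aupr=aupr(records["score"], records["label"]),
        params_used=params_used,
    )


@dataclass
class GridSearchResult:
    """One row per (K, alpha) cell; ``best`` is the cell with top AUPR."""

    table: pd.DataFrame
    best: CVResult


def grid_search(
    Y: InteractionMatrix,
    view: FeatureMatrix | str = "profile",
    K_grid: list[int] | None = None,
    alpha_grid: list[float] | None = None,
    similarity: str = "lns",
    refit: str = "full",
    epsilon: float = 0.01,
) -> GridSearchResult:
    """Sweep neighborhood size and absorbing probability, ranked by AUPR."""
    if not K_grid or not alpha_grid:
        raise ParameterError("K_grid and alpha_grid must be non-empty")
    rows = []
    best: CVResult | None = None
    for K, alpha in product(K_grid, alpha_grid):
        res = loocv(
            Y,
            view,
            LnsHyperParams(K=int(K), epsilon=epsilon),
            PropagationParams(alpha=float(alpha)),
            similarity=similarity,
            refit=refit,
        )
        rows.append(
            {"K": int(K), "alpha": float(alpha), "auc": res.auc, "aupr": res.aupr}
        )
        if best is None or res.aupr > best.aupr:
            best = res
    table = pd.DataFrame(rows)
    assert best is not None
    return GridSearchResult(table=table, best=best)
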