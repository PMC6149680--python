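"""Label propagation over the directed drug-similarity graph.

Known interactions are the initial node labels; at each step a drug absorbs
a fraction alpha of its neighbors' labels and retains 1 - alpha of its own
initial labels:

    F(0) = Y,    F(k) = alpha * W @ F(k-1) + (1 - alpha) * Y.

When W is nonnegative with spectral radius <= 1 (row-stochastic similarity
rows qualify) and 0 < alpha < 1, the iteration is a contraction and
converges to the closed form F = (1 - alpha) (I - alpha W)^-1 Y, which is
what the default mode computes — as a linear solve, never an explicit
inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .datamodel import InteractionMatrix
from .errors import NumericalError, ParameterError, ValidationError
from .similarity import SimilarityMatrix

__all__ = [
    "PropagationParams",
    "ScoreMatrix",
    "propagate_iterative",
    "propagate_closed_form",
    "propagate",
    "rank_novel_pairs",
]


@dataclass(frozen=True)
class PropagationParams:
    """Propagation hyperparameters: absorbing probability and solver mode."""

    alpha: float
    mode: str = "closed_form"
    max_iter: int = 1000
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError(
                f"alpha must lie strictly in (0, 1), got {self.alpha}"
            )
        if self.mode not in ("closed_form", "iterative"):
            raise ParameterError(f"unknown propagation mode {self.mode!r}")


@dataclass
class ScoreMatrix:
    """Predicted drug-target scores F with convergence bookkeeping."""

    values: np.ndarray
    iterations_run: int = 0
    converged: bool = True
    drug_ids: list[str] | None = None
    target_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValidationError("score matrix contains non-finite entries")


def _as_array(W: SimilarityMatrix | np.ndarray) -> np.ndarray:
    return W.values if isinstance(W, SimilarityMatrix) else np.asarray(W, float)


def _validate_transition(W: np.ndarray, Y: np.ndarray) -> None:
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValidationError("similarity matrix must be square")
    if W.shape[0] != Y.shape[0]:
        raise ValidationError(
            f"similarity ({W.shape[0]} drugs) and interactions "
            f"({Y.shape[0]} drugs) do not conform"
        )
    if (W < -1e-12).any():
        raise ValidationError("similarity matrix has negative entries")
    sums = W.sum(axis=1)
    if (sums > 1.0 + 1e-8).any():
        i = int(np.argmax(sums))
        raise ValidationError(
            f"row {i} of the similarity matrix sums to {sums[i]:.6g} > 1; "
            f"row-normalize it before propagating"
        )


def _ids(Y: InteractionMatrix | np.ndarray):
    if isinstance(Y, InteractionMatrix):
        return list(Y.drug_ids), list(Y.target_ids)
    return None, None


def propagate_iterative(
    W: SimilarityMatrix | np.ndarray,
    Y: InteractionMatrix | np.ndarray,
    params: PropagationParams,
) -> ScoreMatrix:
    """Run the fixed-point iteration until max|F(k) - F(k-1)| < tol."""
    Wv = _as_array(W)
    Yv = Y.values if isinstance(Y, InteractionMatrix) else np.asarray(Y, float)
    _validate_transition(Wv, Yv)
    alpha = params.alpha
    F = Yv.copy()
    converged = False
    k = 0
    for k in range(1, params.max_iter + 1):
        F_next = alpha * (Wv @ F) + (1.0 - alpha) * Yv
        delta = np.abs(F_next - F).max()
        F = F_next
        if delta < params.tol:
            converged = True
            break
    drug_ids, target_ids = _ids(Y)
    return ScoreMatrix(
        values=F,
        iterations_run=k,
        converged=converged,
        drug_ids=drug_ids,
        target_ids=target_ids,
    )


def propagate_closed_form(
    W: SimilarityMatrix | np.ndarray,
    Y: InteractionMatrix | np.ndarray,
    alpha: float,
) -> ScoreMatrix:
    """Solve (I - alpha W) F = (1 - alpha) Y for the propagation fixed point."""
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must lie strictly in (0, 1), got {alpha}")
    Wv = _as_array(W)
    Yv = Y.values if isinstance(Y, InteractionMatrix) else np.asarray(Y, float)
    _validate_transition(Wv, Yv)
    A = np.eye(Wv.shape[0]) - alpha * Wv
    try:
        F = scipy.linalg.solve(A, (1.0 - alpha) * Yv)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
        cond = np.linalg.cond(A)
        raise NumericalError(
            f"(I - alpha W) is numerically singular (cond ~ {cond:.3g})"
        ) from exc
    drug_ids, target_ids = _ids(Y)
    return ScoreMatrix(
        values=F,
        iterations_run=0,
        converged=True,
        drug_ids=drug_ids,
        target_ids=target_ids,
    )


def propagate(
    W: SimilarityMatrix | np.ndarray,
    Y: InteractionMatrix | np.ndarray,
    params: PropagationParams,
) -> ScoreMatrix:
    if params.mode == "iterative":
        return propagate_iterative(W, Y, params)
    return propagate_closed_form(W, Y, params.alpha)


def rank_novel_pairs(
    F: ScoreMatrix,
    Y: InteractionMatrix,
    top_n: int,
) -> list[tuple[str, str, float]]:
    """Top-scoring drug-target pairs that are *not* known interactions.

    Pairs with y_ij = 0 are sorted by score descending; exact score ties are
    broken by ascending (drug index, target index).  Returns at most top_n
    (drug ID, target ID, score) triples.
    """
    Fv = F.values
    Yv = Y.values
    if Fv.shape != Yv.shape:
        raise ValidationError(
            f"score matrix {Fv.shape} and interactions {Yv.shape} differ"
        )
    di, tj = np.where(Yv == 0)
    if di.size == 0:
        return []
    scores = Fv[di, tj]
    order = np.lexsort((tj, di, -scores))
    order = order[: max(0, int(top_n))]
    return [
        (Y.drug_ids[di[k]], Y.target_ids[tj[k]], float(scores[k]))
        for k in order
    ]
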