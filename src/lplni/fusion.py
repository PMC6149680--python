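"""Score-level fusion of several prediction models (LPLNI-II).

Given n score matrices F^1..F^n for the same drug-target grid, the fused
score of pair (i, j) is the binomial logistic model

    P(y_ij = 1 | F) = sigmoid( sum_k a_k F^k_ij + b ).

The coefficients are fitted by maximum likelihood over all nd*nt pairs —
known interactions are the positive class, everything else the negative
class — with a small ridge penalty on the slopes (never the intercept) so
that perfectly separable score columns still have a unique finite optimum.
The fit is Newton-Raphson with step halving; the problem is convex, so the
result is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import FeatureMatrix, InteractionMatrix
from .errors import NumericalError, ParameterError, ValidationError
from .evaluation import build_scores, held_out_scores
from .propagation import PropagationParams, ScoreMatrix
from .similarity import LnsHyperParams

__all__ = ["FusionModel", "fit_fusion", "predict_fusion", "fuse_views"]


@dataclass
class FusionModel:
    """Fitted logistic fusion: one slope per input model plus an intercept."""

    coefficients: np.ndarray
    intercept: float
    ridge: float
    n_iter: int = 0
    final_grad_norm: float = np.nan

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.isfinite(self.coefficients).all() or not np.isfinite(
            self.intercept
        ):
            raise ValidationError("fusion parameters must be finite")


def _design(scores: list[ScoreMatrix | np.ndarray]) -> np.ndarray:
    mats = [
        s.values if isinstance(s, ScoreMatrix) else np.asarray(s, float)
        for s in scores
    ]
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise ValidationError("score matrices differ in shape")
    return np.column_stack([m.ravel() for m in mats])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _penalized_nll(theta, Z, y, ridge) -> float:
    z = Z @ theta[:-1] + theta[-1]
    # log(1 + e^z) - y z, computed stably
    nll = np.sum(np.logaddexp(0.0, z) - y * z)
    return float(nll + ridge * np.sum(theta[:-1] ** 2))


def fit_fusion(
    scores: list[ScoreMatrix | np.ndarray],
    Y: InteractionMatrix,
    ridge: float = 1e-6,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> FusionModel:
    """Penalized maximum-likelihood fit of the logistic fusion model.

    Newton-Raphson on the penalized negative log-likelihood; the gradient
    norm at the optimum is recorded so callers can verify convergence.
    """
    if len(scores) == 0:
        raise ParameterError("at least one score matrix is required")
    if ridge < 0:
        raise ParameterError("ridge penalty must be nonnegative")
    Z = _design(scores)
    y = Y.values.ravel().astype(float)
    if Z.shape[0] != y.size:
        raise ValidationError("score matrices do not conform with Y")
    n_feat = Z.shape[1]
    X = np.column_stack([Z, np.ones(Z.shape[0])])
    pen = 2.0 * ridge * np.append(np.ones(n_feat), 0.0)  # intercept unpenalized
    theta = np.zeros(n_feat + 1)
    nll = _penalized_nll(theta, Z, y, ridge)
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        p = _sigmoid(X @ theta)
        grad = X.T @ (p - y) + pen * theta
        grad_norm = float(np.linalg.norm(grad))
        if grad_norm <= tol * max(1.0, y.size):
            break
        w = np.clip(p * (1.0 - p), 1e-12, None)
        H = (X.T * w) @ X + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise NumericalError("singular Hessian in fusion fit") from exc
        # step halving keeps the penalized likelihood monotone
        t = 1.0
        for _ in range(60):
            cand = theta - t * step
            cand_nll = _penalized_nll(cand, Z, y, ridge)
            if cand_nll <= nll + 1e-12:
                theta, nll = cand, cand_nll
                break
            t /= 2.0
        else:
            raise NumericalError("fusion line search failed to decrease NLL")
    else:
        raise NumericalError(
            f"fusion fit did not converge in {max_iter} Newton iterations "
            f"(grad norm {grad_norm:.3g})"
        )
    return FusionModel(
        coefficients=theta[:-1],
        intercept=float(theta[-1]),
        ridge=ridge,
        n_iter=it,
        final_grad_norm=grad_norm,
    )


def predict_fusion(
    model: FusionModel, scores: list[ScoreMatrix | np.ndarray]
) -> ScoreMatrix:
    """Entrywise logistic transform of the fitted linear combination."""
    if len(scores) != model.coefficients.size:
        raise ValidationError(
            f"{len(scores)} score matrices for "
            f"{model.coefficients.size} coefficients"
        )
    Z = _design(scores)
    shape = (
        scores[0].values.shape
        if isinstance(scores[0], ScoreMatrix)
        else np.asarray(scores[0]).shape
    )
    probs = _sigmoid(Z @ model.coefficients + model.intercept)
    first = scores[0]
    return ScoreMatrix(
        values=probs.reshape(shape),
        iterations_run=0,
        converged=True,
        drug_ids=getattr(first, "drug_ids", None),
        target_ids=getattr(first, "target_ids", None),
    )


def fuse_views(
    Y: InteractionMatrix,
    feature_views: list[FeatureMatrix | str],
    lns_params: LnsHyperParams,
    prop_params: PropagationParams,
    ridge: float = 1e-6,
    train: str = "held_out",
    similarity: str = "lns",
    return_model: bool = False,
):
    """Build one propagation model per feature view and fuse their scores.

    The logistic coefficients are fitted on leave-one-out held-out scores by
    default (``train="held_out"``): in-sample scores of known pairs carry
    their own label and would bias the slopes upward.  ``train="in_sample"``
    fits on the full-data scores instead.  Prediction always combines the
    full-data scores of each view.
    """
    if not feature_views:
        raise ParameterError("at least one feature view is required")
    if train not in ("held_out", "in_sample"):
        raise ParameterError(f"unknown fusion training mode {train!r}")
    full = [
        build_scores(Y, v, lns_params, prop_params, similarity)
        for v in feature_views
    ]
    if train == "held_out":
        fit_scores = [
            held_out_scores(Y, v, lns_params, prop_params, similarity)
            for v in feature_views
        ]
    else:
        fit_scores = [f.values for f in full]
    model = fit_fusion(fit_scores, Y, ridge=ridge)
    fused = predict_fusion(model, full)
    fused.drug_ids = list(Y.drug_ids)
    fused.target_ids = list(Y.target_ids)
    if return_model:
        return fused, model
    return fused
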