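"""Model/Results front end over the functional pipeline.

``LPLNI`` bundles an interaction matrix, a feature view and the
hyperparameters; ``fit()`` builds the similarity graph, runs label
propagation and returns an ``LPLNIResults`` carrying the score matrix,
diagnostics, novel-pair ranking, cross-validation and a text summary —
the same shape statsmodels gives its estimators.
"""

from __future__ import annotations

import numpy as np

from . import __version__ as _version
from .datamodel import (
    FeatureMatrix,
    InteractionMatrix,
    dataset_stats,
    read_feature_matrix,
    read_interaction_matrix,
)
from .errors import ParameterError
from .evaluation import CVResult, build_similarity, loocv, _resolve_view
from .fusion import FusionModel, fuse_views
from .propagation import (
    PropagationParams,
    ScoreMatrix,
    propagate,
    rank_novel_pairs,
)
from .similarity import LnsHyperParams, SimilarityMatrix

__all__ = ["LPLNI", "LPLNIResults"]


class LPLNI:
    """Label propagation with linear neighborhood information.

    Parameters
    ----------
    Y : InteractionMatrix
        Binary drug-target adjacency; the label source.
    feature_view : FeatureMatrix or "profile" or list thereof
        Drug features for the similarity graph.  The default "profile" uses
        the rows of Y themselves.  A list of views activates score-level
        logistic fusion (LPLNI-II).
    K, epsilon : neighborhood size and ridge scale of the LNS construction.
    alpha : absorbing probability of the propagation, in (0, 1).
    similarity : "lns" (default) or a baseline ("cosine", "gauss", "jaccard").
    ridge : slope penalty of the fusion fit (multi-view only).
    """

    def __init__(
        self,
        Y: InteractionMatrix,
        feature_view="profile",
        K: int = 10,
        alpha: float = 0.5,
        epsilon: float = 0.01,
        similarity: str = "lns",
        ridge: float = 1e-6,
    ):
        self.Y = Y
        self.feature_view = feature_view
        self.similarity = similarity
        self.lns_params = LnsHyperParams(K=K, epsilon=epsilon)
        self.alpha = alpha
        self.ridge = ridge

    @classmethod
    def from_files(
        cls,
        interaction_path,
        feature_paths=None,
        orientation: str = "drugs_as_rows",
        **kwargs,
    ) -> "LPLNI":
        """Build a model from TSV files (feature_paths=None uses profiles)."""
        Y = read_interaction_matrix(interaction_path, orientation=orientation)
        if feature_paths is None:
            view = "profile"
        elif isinstance(feature_paths, (list, tuple)):
            view = [read_feature_matrix(p) for p in feature_paths]
        else:
            view = read_feature_matrix(feature_paths)
        return cls(Y, feature_view=view, **kwargs)

    @property
    def is_fused(self) -> bool:
        return isinstance(self.feature_view, (list, tuple))

    def fit(self, mode: str = "closed_form") -> "LPLNIResults":
        prop = PropagationParams(alpha=self.alpha, mode=mode)
        if self.is_fused:
            views = list(self.feature_view)
            if len(views) < 1:
                raise ParameterError("fusion needs at least one view")
            scores, fusion_model = fuse_views(
                self.Y,
                views,
                self.lns_params,
                prop,
                ridge=self.ridge,
                similarity=self.similarity,
                return_model=True,
            )
            return LPLNIResults(self, scores, None, prop, fusion_model)
        X = _resolve_view(self.Y, self.feature_view)
        W = build_similarity(X, self.similarity, self.lns_params)
        scores = propagate(W, self.Y, prop)
        return LPLNIResults(self, scores, W, prop, None)


class LPLNIResults:
    """Fitted scores plus diagnostics, ranking, CV and a summary table."""

    def __init__(
        self,
        model: LPLNI,
        scores: ScoreMatrix,
        W: SimilarityMatrix | None,
        prop_params: PropagationParams,
        fusion_model: FusionModel | None,
    ):
        self.model = model
        self.scores = scores
        self.similarity_matrix = W
        self.prop_params = prop_params
        self.fusion_model = fusion_model

    def predict(self) -> np.ndarray:
        """The nd x nt matrix of predicted interaction scores."""
        return self.scores.values

    def rank_novel(self, top_n: int = 10):
        """Highest-scoring pairs not already known to interact."""
        return rank_novel_pairs(self.scores, self.model.Y, top_n)

    def loocv(self, refit: str = "full") -> CVResult:
        """Leave-one-out cross-validation at the model's hyperparameters."""
        if self.model.is_fused:
            raise ParameterError(
                "run loocv per view; fused CV is not defined pairwise"
            )
        return loocv(
            self.model.Y,
            self.model.feature_view,
            self.model.lns_params,
            self.prop_params,
            similarity=self.model.similarity,
            refit=refit,
        )

    def summary(self) -> str:
        m = self.model
        st = dataset_stats(m.Y)
        view = (
            f"{len(m.feature_view)} fused views"
            if m.is_fused
            else (
                m.feature_view
                if isinstance(m.feature_view, str)
                else m.feature_view.feature_kind
            )
        )
        rows = [
            ("drugs (nd)", st.nd),
            ("targets (nt)", st.nt),
            ("known interactions", st.edges),
            ("sparsity", f"{st.sparsity:.4f}"),
            ("feature view", view),
            ("similarity", m.similarity),
            ("neighbors K", m.lns_params.K),
            ("epsilon", m.lns_params.epsilon),
            ("alpha", m.alpha),
            ("mode", self.prop_params.mode),
            ("iterations", self.scores.iterations_run),
            ("converged", self.scores.converged),
            ("score range", f"[{self.scores.values.min():.4f}, "
                            f"{self.scores.values.max():.4f}]"),
        ]
        if self.fusion_model is not None:
            coeffs = ", ".join(
                f"{c:.4f}" for c in self.fusion_model.coefficients
            )
            rows.append(("fusion coefficients", coeffs))
            rows.append(("fusion intercept", f"{self.fusion_model.intercept:.4f}"))
        width = max(len(str(k)) for k, _ in rows)
        title = f"LPLNI results (lplni {_version})"
        bar = "=" * (width + 24)
        lines = [bar, title, bar]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        lines.append(bar)
        return "\n".join(lines)
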