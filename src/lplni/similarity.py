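"""Drug-drug similarity construction.

The centrepiece is the *linear neighborhood similarity* (LNS): each drug's
feature vector is reconstructed as a convex combination of its K nearest
neighbors, and the optimal reconstruction weights serve as directed
similarities.  Per drug i the weights solve

    min_w  w' G_i w + lambda_i ||w||^2    s.t.  e'w = 1,  w >= 0

where G_i[j, k] = (x_i - x_ij)' (x_i - x_ik) is the Gram matrix of
difference vectors and lambda_i = epsilon * rho(G_i) scales the ridge term
by the spectral radius so that both objective terms live on comparable
scales.  Rows of the assembled similarity matrix W are therefore
nonnegative, sum to one, and have at most K nonzeros; W is generally
asymmetric (w_ij != w_ji).

Cosine, Gauss and Jaccard similarities are provided as baselines, with a
row-normalization step that makes any nonnegative similarity usable as the
transition matrix of the label-propagation stage (row sums <= 1 guarantee
convergence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .datamodel import FeatureMatrix
from .errors import NumericalError, ParameterError, ValidationError

__all__ = [
    "LnsHyperParams",
    "WeightVector",
    "SimilarityMatrix",
    "find_neighbors",
    "gram_matrix",
    "regularization_lambda",
    "solve_weights",
    "lns_similarity",
    "baseline_similarity",
    "row_normalize",
    "read_similarity",
    "write_similarity",
]

BASELINE_METHODS = ("cosine", "gauss", "jaccard")


@dataclass(frozen=True)
class LnsHyperParams:
    """Hyperparameters of the linear neighborhood similarity.

    K is the neighborhood size (0 < K < nd); epsilon scales the ridge
    regularizer relative to the spectral radius of the Gram matrix
    (default 0.01).
    """

    K: int
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ParameterError(f"K must be a positive integer, got {self.K}")
        if not self.epsilon > 0:
            raise ParameterError(f"epsilon must be > 0, got {self.epsilon}")


@dataclass
class WeightVector:
    """Solution of one drug's reconstruction QP.

    ``objective_value`` is the attained reconstruction error w'Gw (without
    the ridge term); ``uniform_fallback`` flags the degenerate G = 0 case
    where every simplex point is optimal and the uniform weights are chosen.
    """

    weights: np.ndarray
    objective_value: float
    lambda_used: float
    uniform_fallback: bool = False


@dataclass
class SimilarityMatrix:
    """nd x nd nonnegative weight matrix with its construction method."""

    values: np.ndarray
    method: str
    row_stochastic: bool = False
    drug_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError("similarity matrix must be square")
        if (self.values < -1e-12).any():
            raise ValidationError("similarity matrix has negative entries")

    @property
    def nd(self) -> int:
        return self.values.shape[0]


def find_neighbors(X: FeatureMatrix | np.ndarray, K: int) -> np.ndarray:
    """Indices of the K nearest neighbors of each drug (self excluded).

    Euclidean distance; ties are broken by ascending row index so results
    are deterministic across platforms.  Returns an (nd, K) integer array
    ordered by increasing distance.
    """
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    nd = values.shape[0]
    if not 0 < K < nd:
        raise ParameterError(f"K must satisfy 0 < K < nd, got K={K}, nd={nd}")
    dist = cdist(values, values, metric="sqeuclidean")
    np.fill_diagonal(dist, np.inf)
    # stable sort keeps ascending-index order among exact distance ties
    order = np.argsort(dist, axis=1, kind="stable")
    return order[:, :K]


def gram_matrix(
    X: FeatureMatrix | np.ndarray, i: int, neighbors: np.ndarray
) -> np.ndarray:
    """Gram matrix of difference vectors G[j,k] = (x_i - x_ij)'(x_i - x_ik)."""
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    neighbors = np.asarray(neighbors, dtype=int)
    if i in neighbors:
        raise ValidationError(f"drug {i} appears in its own neighbor list")
    D = values[i][None, :] - values[neighbors]  # K x p rows of differences
    G = D @ D.T
    return (G + G.T) / 2.0  # exact symmetry despite BLAS rounding


def regularization_lambda(G: np.ndarray, epsilon: float) -> float:
    """lambda = epsilon * spectral radius of the (PSD) Gram matrix."""
    rho = float(np.linalg.eigvalsh(G)[-1])
    return epsilon * max(rho, 0.0)


def _simplex_qp(A: np.ndarray, max_iter: int | None = None) -> np.ndarray:
    """Minimize w'Aw over the probability simplex (A symmetric PSD).

    Primal active-set method: on the current free set the equality-
    constrained minimizer is w_F = A_FF^-1 e / (e' A_FF^-1 e); infeasible
    steps are truncated at the first blocking bound, and bound constraints
    are released while their Lagrange multipliers are negative.
    """
    K = A.shape[0]
    if K == 1:
        return np.ones(1)
    x = np.full(K, 1.0 / K)
    free = np.ones(K, dtype=bool)
    if max_iter is None:
        max_iter = 50 * K + 100
    for _ in range(max_iter):
        idx = np.flatnonzero(free)
        Af = A[np.ix_(idx, idx)]
        ones = np.ones(idx.size)
        try:
            u = np.linalg.solve(Af, ones)
        except np.linalg.LinAlgError:
            u, *_ = np.linalg.lstsq(Af, ones, rcond=None)
        s = u.sum()
        if abs(s) < 1e-300 or not np.isfinite(u).all():
            raise NumericalError("singular reduced system in simplex QP")
        xt = np.zeros(K)
        xt[idx] = u / s
        if (xt[idx] >= -1e-12).all():
            x = np.clip(xt, 0.0, None)
            x /= x.sum()
            g = 2.0 * A @ x
            mu = g[idx] @ x[idx]  # e'w=1 on the free set => weighted mean
            bound = np.flatnonzero(~free)
            if bound.size == 0:
                return x
            nu = g[bound] - mu
            jmin = int(np.argmin(nu))
            if nu[jmin] >= -1e-10 * max(1.0, abs(mu)):
                return x
            free[bound[jmin]] = True
        else:
            d = xt - x
            blocking = idx[d[idx] < -1e-15]
            steps = x[blocking] / -d[blocking]
            t = steps.min()
            x = np.clip(x + t * d, 0.0, None)
            hit = blocking[np.argmin(steps)]
            x[hit] = 0.0
            free[hit] = False
            x /= x.sum()
    raise NumericalError("simplex QP active-set iteration limit exceeded")


def solve_weights(
    G: np.ndarray, lam: float, drug_index: int | None = None
) -> WeightVector:
    """Solve the per-drug reconstruction QP on the effective matrix G + lam*I.

    The ridge term lam*||w||^2 merges algebraically with the quadratic form,
    so a single convex QP over the simplex is solved.  Tiny negative solver
    outputs (round-off) are clipped and the row renormalized.  When G = 0
    and lam = 0 every simplex point attains the optimum; the symmetric
    uniform weights are returned with ``uniform_fallback=True``.
    """
    G = np.asarray(G, dtype=float)
    if lam < 0:
        raise ParameterError(f"lambda must be nonnegative, got {lam}")
    K = G.shape[0]
    A = G + lam * np.eye(K)
    scale = float(np.abs(A).max())
    if scale < 1e-300:
        return WeightVector(
            weights=np.full(K, 1.0 / K),
            objective_value=0.0,
            lambda_used=lam,
            uniform_fallback=True,
        )
    try:
        w = _simplex_qp(A / scale)
    except NumericalError as exc:
        where = f" (drug {drug_index})" if drug_index is not None else ""
        raise NumericalError(f"{exc}{where}") from exc
    if (w < -1e-10).any() or abs(w.sum() - 1.0) > 1e-8:
        where = f" (drug {drug_index})" if drug_index is not None else ""
        raise NumericalError(f"simplex QP returned infeasible weights{where}")
    w = np.clip(w, 0.0, None)
    w /= w.sum()
    return WeightVector(
        weights=w,
        objective_value=float(w @ G @ w),
        lambda_used=lam,
    )


def lns_similarity(
    X: FeatureMatrix, params: LnsHyperParams
) -> SimilarityMatrix:
    """Assemble the linear neighborhood similarity matrix row by row.

    Row i holds drug i's reconstruction weights scattered into the columns
    of its K nearest neighbors; all other entries (including the diagonal)
    are zero.
    """
    nd = X.nd
    neighbors = find_neighbors(X, params.K)
    W = np.zeros((nd, nd))
    for i in range(nd):
        G = gram_matrix(X, i, neighbors[i])
        lam = regularization_lambda(G, params.epsilon)
        wv = solve_weights(G, lam, drug_index=i)
        W[i, neighbors[i]] = wv.weights
    return SimilarityMatrix(
        values=W, method="lns", row_stochastic=True, drug_ids=list(X.drug_ids)
    )


def _cosine(values: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(values, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    S = (values @ values.T) / np.outer(safe, safe)
    S[norms == 0, :] = 0.0  # cosine with a zero vector is defined as 0
    S[:, norms == 0] = 0.0
    np.fill_diagonal(S, np.where(norms > 0, 1.0, 0.0))
    return S


def _gauss(values: np.ndarray, bandwidth: str) -> np.ndarray:
    sq = cdist(values, values, metric="sqeuclidean")
    if bandwidth == "squared_norm":
        sigma = float(np.mean(np.sum(values**2, axis=1)))
    elif bandwidth == "norm":
        sigma = float(np.mean(np.linalg.norm(values, axis=1)))
    else:
        raise ParameterError(f"unknown gauss bandwidth rule {bandwidth!r}")
    if sigma <= 0:
        # all-zero feature matrix: every pair is at distance 0
        return np.ones_like(sq)
    return np.exp(-sq / sigma)


def _jaccard(values: np.ndarray) -> np.ndarray:
    if not np.isin(values, (0.0, 1.0)).all():
        raise ValidationError("jaccard similarity requires binary features")
    inter = values @ values.T
    sizes = values.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return S


def baseline_similarity(
    X: FeatureMatrix, method: str, gauss_bandwidth: str = "squared_norm"
) -> SimilarityMatrix:
    """Cosine, Gauss or Jaccard similarity between drug feature vectors.

    The Gauss kernel is exp(-||x_i - x_j||^2 / sigma) with the bandwidth
    sigma set from the data as the mean squared feature norm (the
    ``gauss_bandwidth="norm"`` switch uses the mean Euclidean norm instead).
    Jaccard is |support intersection| / |support union|, 0 when both
    supports are empty.  All three are symmetric with entries in [0, 1]
    for nonnegative features.
    """
    if method not in BASELINE_METHODS:
        raise ParameterError(
            f"method must be one of {BASELINE_METHODS}, got {method!r}"
        )
    values = X.values
    if method == "cosine":
        S = _cosine(values)
    elif method == "gauss":
        S = _gauss(values, gauss_bandwidth)
    else:
        S = _jaccard(values)
    return SimilarityMatrix(
        values=S, method=method, row_stochastic=False, drug_ids=list(X.drug_ids)
    )


def row_normalize(W: SimilarityMatrix) -> SimilarityMatrix:
    """Zero the diagonal and divide each nonzero row by its sum.

    Makes any nonnegative similarity matrix row-stochastic (rows summing to
    1, or to 0 for isolated drugs), the precondition under which label
    propagation converges.  All-zero rows are left zero and reported with a
    warning.
    """
    V = W.values.copy()
    np.fill_diagonal(V, 0.0)
    sums = V.sum(axis=1)
    zero_rows = np.flatnonzero(sums == 0)
    if zero_rows.size:
        warnings.warn(
            f"{zero_rows.size} drug(s) have no similarity mass and stay "
            f"isolated: rows {zero_rows.tolist()[:10]}",
            stacklevel=2,
        )
    safe = np.where(sums > 0, sums, 1.0)
    V = V / safe[:, None]
    return SimilarityMatrix(
        values=V,
        method=W.method,
        row_stochastic=True,
        drug_ids=list(W.drug_ids) if W.drug_ids else None,
    )


def write_similarity(W: SimilarityMatrix, path) -> None:
    import pandas as pd

    ids = W.drug_ids or [str(i) for i in range(W.nd)]
    pd.DataFrame(W.values, index=ids, columns=ids).to_csv(path, sep="\t")


def read_similarity(path, method: str = "lns") -> SimilarityMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(
        values=df.to_numpy(dtype=float),
        method=method,
        drug_ids=[str(x) for x in df.index],
    )
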