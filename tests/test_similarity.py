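import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import grid_search_qp
from lplni import FeatureMatrix, LnsHyperParams, baseline_similarity, lns_similarity, row_normalize
from lplni.errors import ParameterError, ValidationError
from lplni.similarity import (
    find_neighbors,
    gram_matrix,
    regularization_lambda,
    solve_weights,
)


def fm(values, kind="other"):
    values = np.asarray(values, float)
    return FeatureMatrix(
        values=values,
        drug_ids=[f"D{i}" for i in range(values.shape[0])],
        feature_kind=kind,
    )


class TestFindNeighbors:
    def test_1d_exhaustive(self):
        X = fm([[0.0], [1.0], [3.0]])
        nbrs = find_neighbors(X, 1)
        assert nbrs.tolist() == [[1], [0], [1]]

    def test_complete_graph_at_K_nd_minus_1(self):
        X = fm(np.random.default_rng(0).random((5, 3)))
        nbrs = find_neighbors(X, 4)
        for i in range(5):
            assert sorted(nbrs[i]) == sorted(set(range(5)) - {i})

    def test_duplicate_rows_tie_break_by_index(self):
        X = fm([[0.0, 0.0], [0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        nbrs = find_neighbors(X, 2)
        assert nbrs[0].tolist() == [1, 2]
        assert nbrs[3].tolist() == [0, 1]

    def test_K_too_large_raises(self):
        X = fm(np.ones((3, 2)))
        with pytest.raises(ParameterError):
            find_neighbors(X, 3)


class TestGramMatrix:
    def test_hand_inner_products(self):
        X = fm([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        G = gram_matrix(X, 0, [1, 2])
        assert np.allclose(G, np.eye(2))

    def test_coincident_neighbor_gives_zero_row(self):
        X = fm([[1.0, 2.0], [1.0, 2.0], [3.0, 0.0]])
        G = gram_matrix(X, 0, [1, 2])
        assert np.allclose(G[0], 0) and np.allclose(G[:, 0], 0)

    def test_single_neighbor_is_squared_distance(self):
        X = fm([[0.0, 0.0], [3.0, 4.0]])
        G = gram_matrix(X, 0, [1])
        assert G.shape == (1, 1) and G[0, 0] == pytest.approx(25.0)

    def test_psd_on_random_features(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            X = fm(rng.normal(size=(8, 4)))
            nbrs = find_neighbors(X, 3)
            G = gram_matrix(X, 0, nbrs[0])
            eigs = np.linalg.eigvalsh(G)
            assert eigs.min() >= -1e-8 * max(eigs.max(), 1e-12)
            assert np.allclose(G, G.T)


class TestRegularizationLambda:
    def test_diagonal_spectral_radius(self):
        assert regularization_lambda(np.diag([2.0, 1.0]), 0.01) == pytest.approx(0.02)

    def test_zero_matrix(self):
        assert regularization_lambda(np.zeros((3, 3)), 0.01) == 0.0

    def test_rank_one_ones_matrix(self):
        G = np.ones((2, 2))
        assert regularization_lambda(G, 0.01) == pytest.approx(0.02)


class TestSolveWeights:
    def test_diagonal_closed_form_lambda_zero(self):
        wv = solve_weights(np.diag([2.0, 1.0]), 0.0)
        assert np.allclose(wv.weights, [1 / 3, 2 / 3], atol=1e-9)

    def test_diagonal_closed_form_with_ridge(self):
        wv = solve_weights(np.diag([2.0, 1.0]), 0.02)
        # w_i proportional to 1/(d_i + lambda)
        expect = np.array([1 / 2.02, 1 / 1.02])
        expect /= expect.sum()
        assert np.allclose(wv.weights, expect, atol=1e-9)
        assert wv.lambda_used == 0.02

    def test_single_neighbor_simplex_is_a_point(self):
        wv = solve_weights(np.array([[7.3]]), 0.5)
        assert wv.weights.tolist() == [1.0]

    def test_zero_gram_falls_back_to_uniform(self):
        wv = solve_weights(np.zeros((4, 4)), 0.0)
        assert wv.uniform_fallback
        assert np.allclose(wv.weights, 0.25)

    def test_matches_grid_search_oracle_on_random_psd(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            K = int(rng.integers(1, 4))
            B = rng.normal(size=(K + 1, K))
            G = B.T @ B
            lam = float(rng.choice([0.0, 0.01, 0.1])) * max(
                np.linalg.eigvalsh(G).max(), 1e-12
            )
            wv = solve_weights(G, lam)
            A = G + lam * np.eye(K)
            _, obj_grid = grid_search_qp(A, step=1e-3)
            obj_mine = float(wv.weights @ A @ wv.weights)
            assert obj_mine <= obj_grid + 1e-4
            assert abs(wv.weights.sum() - 1.0) <= 1e-8
            assert wv.weights.min() >= 0.0

    def test_matches_slsqp_on_larger_K(self):
        from scipy.optimize import minimize

        rng = np.random.default_rng(11)
        for _ in range(10):
            K = 8
            B = rng.normal(size=(K + 2, K))
            G = B.T @ B
            lam = 0.01 * np.linalg.eigvalsh(G).max()
            A = G + lam * np.eye(K)
            wv = solve_weights(G, lam)
            res = minimize(
                lambda w: w @ A @ w,
                np.full(K, 1.0 / K),
                jac=lambda w: 2 * A @ w,
                method="SLSQP",
                bounds=[(0.0, 1.0)] * K,
                constraints={"type": "eq", "fun": lambda w: w.sum() - 1.0},
                options={"maxiter": 500, "ftol": 1e-14},
            )
            assert wv.weights @ A @ wv.weights <= res.fun + 1e-8

    def test_large_lambda_drives_weights_uniform(self):
        rng = np.random.default_rng(3)
        B = rng.normal(size=(5, 4))
        G = B.T @ B
        lam = 1e6 * np.linalg.eigvalsh(G).max()
        wv = solve_weights(G, lam)
        assert np.allclose(wv.weights, 0.25, atol=1e-5)


class TestLnsSimilarity:
    def test_rows_sum_to_one_diagonal_zero(self):
        rng = np.random.default_rng(8)
        X = fm(rng.random((12, 6)))
        W = lns_similarity(X, LnsHyperParams(K=4))
        assert np.allclose(W.values.sum(axis=1), 1.0, atol=1e-8)
        assert np.allclose(np.diag(W.values), 0.0)
        assert (W.values >= 0).all()
        assert ((W.values > 0).sum(axis=1) <= 4).all()

    def test_collinear_middle_point_symmetric_weights(self):
        X = fm([[0.0], [1.0], [2.0]])
        W = lns_similarity(X, LnsHyperParams(K=2))
        assert W.values[1, 0] == pytest.approx(0.5, abs=1e-6)
        assert W.values[1, 2] == pytest.approx(0.5, abs=1e-6)

    def test_rows_match_per_row_grid_search(self):
        rng = np.random.default_rng(17)
        X = fm(rng.random((5, 3)))
        params = LnsHyperParams(K=3)
        W = lns_similarity(X, params)
        nbrs = find_neighbors(X, 3)
        for i in range(5):
            G = gram_matrix(X, i, nbrs[i])
            lam = regularization_lambda(G, params.epsilon)
            A = G + lam * np.eye(3)
            _, obj_grid = grid_search_qp(A, step=1e-3)
            w = W.values[i, nbrs[i]]
            assert w @ A @ w <= obj_grid + 1e-4

    def test_feature_column_permutation_invariance(self):
        rng = np.random.default_rng(23)
        V = rng.random((8, 5))
        perm = rng.permutation(5)
        W1 = lns_similarity(fm(V), LnsHyperParams(K=3)).values
        W2 = lns_similarity(fm(V[:, perm]), LnsHyperParams(K=3)).values
        assert np.allclose(W1, W2, atol=1e-10)

    def test_drug_row_permutation_equivariance(self):
        rng = np.random.default_rng(29)
        V = rng.random((7, 4))
        perm = rng.permutation(7)
        W1 = lns_similarity(fm(V), LnsHyperParams(K=3)).values
        W2 = lns_similarity(fm(V[perm]), LnsHyperParams(K=3)).values
        assert np.allclose(W1[np.ix_(perm, perm)], W2, atol=1e-10)


class TestBaselineSimilarity:
    def test_gauss_identical_rows_similarity_one(self):
        X = fm([[1.0, 2.0], [1.0, 2.0], [0.0, 5.0]])
        S = baseline_similarity(X, "gauss")
        assert S.values[0, 1] == pytest.approx(1.0)

    def test_cosine_orthogonal_rows_zero(self):
        X = fm([[1.0, 0.0], [0.0, 1.0]])
        S = baseline_similarity(X, "cosine")
        assert S.values[0, 1] == pytest.approx(0.0)

    def test_cosine_zero_vector_defined_as_zero(self):
        X = fm([[0.0, 0.0], [1.0, 1.0]])
        S = baseline_similarity(X, "cosine")
        assert S.values[0, 1] == 0.0 and S.values[0, 0] == 0.0

    def test_jaccard_set_computation(self):
        X = fm([[1.0, 1.0, 0.0], [1.0, 0.0, 1.0]])
        S = baseline_similarity(X, "jaccard")
        assert S.values[0, 1] == pytest.approx(1 / 3)

    def test_jaccard_empty_supports_zero(self):
        X = fm([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        S = baseline_similarity(X, "jaccard")
        assert S.values[0, 1] == 0.0

    def test_jaccard_rejects_non_binary(self):
        with pytest.raises(ValidationError):
            baseline_similarity(fm([[0.5, 1.0], [1.0, 0.0]]), "jaccard")

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(31)
        X = fm((rng.random((10, 6)) < 0.5).astype(float))
        for method in ("cosine", "gauss", "jaccard"):
            S = baseline_similarity(X, method).values
            assert np.allclose(S, S.T)
            assert S.min() >= 0.0 and S.max() <= 1.0 + 1e-12

    def test_gauss_bandwidth_switch_changes_scale(self):
        rng = np.random.default_rng(37)
        X = fm(rng.random((6, 4)) * 3)
        S1 = baseline_similarity(X, "gauss", gauss_bandwidth="squared_norm")
        S2 = baseline_similarity(X, "gauss", gauss_bandwidth="norm")
        assert not np.allclose(S1.values, S2.values)


class TestRowNormalize:
    def test_scaling(self):
        S = baseline_similarity(fm([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]), "gauss")
        W = row_normalize(S)
        assert np.allclose(W.values.sum(axis=1), 1.0)
        assert np.allclose(np.diag(W.values), 0.0)

    def test_lns_output_unchanged(self):
        rng = np.random.default_rng(41)
        X = fm(rng.random((9, 5)))
        W = lns_similarity(X, LnsHyperParams(K=3))
        W2 = row_normalize(W)
        assert np.allclose(W.values, W2.values, atol=1e-12)

    def test_zero_row_left_zero_with_warning(self):
        X = fm([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
        S = baseline_similarity(X, "jaccard")
        with pytest.warns(UserWarning, match="isolated"):
            W = row_normalize(S)
        assert np.allclose(W.values[0], 0.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**16),
    nd=st.integers(4, 9),
    p=st.integers(1, 5),
    K=st.integers(1, 3),
)
def test_lns_simplex_invariants_property(seed, nd, p, K):
    """Every LNS row is a probability vector supported on K neighbors."""
    rng = np.random.default_rng(seed)
    X = fm(rng.normal(size=(nd, p)))
    W = lns_similarity(X, LnsHyperParams(K=min(K, nd - 1))).values
    assert np.allclose(W.sum(axis=1), 1.0, atol=1e-8)
    assert W.min() >= 0.0
    assert np.allclose(np.diag(W), 0.0)
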