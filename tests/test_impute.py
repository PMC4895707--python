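"""Neighbour selection, weighted-KNN and LLS imputation, and the estimators."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from mirgoimpute.distance import combined_distance, pairwise_expression_distance
from mirgoimpute.impute import (
    GOKNNImputer,
    GOLLSImputer,
    ImputationError,
    knn_impute,
    lls_impute,
    select_neighbors,
)
from mirgoimpute.ontology import TermSimilarityModel
from mirgoimpute.similarity import functional_similarity
from mirgoimpute.simulate import SimulationConfig, apply_mask, generate_missing_mask


def expr_with_missing(rows, missing):
    X = pd.DataFrame(np.asarray(rows, dtype=float))
    for r, c in missing:
        X.iloc[r, c] = np.nan
    return X


class TestSelectNeighbors:
    C = np.array([
        [0.0, 1.0, 2.0, 3.0],
        [1.0, 0.0, 1.0, 1.0],
        [2.0, 1.0, 0.0, 2.0],
        [3.0, 1.0, 2.0, 0.0],
    ])

    def test_k_nearest_in_order(self):
        X = expr_with_missing(np.ones((4, 3)), [(0, 0)])
        assert select_neighbors(self.C, X, 0, 0, K=2) == [1, 2]

    def test_candidate_missing_at_column_excluded(self):
        X = expr_with_missing(np.ones((4, 3)), [(0, 0), (1, 0)])
        assert select_neighbors(self.C, X, 0, 0, K=2) == [2, 3]

    def test_tie_broken_by_row_index(self):
        X = expr_with_missing(np.ones((4, 3)), [(1, 1)])
        # rows 0, 2 and 3 all at distance 1 from row 1
        assert select_neighbors(self.C, X, 1, 1, K=2) == [0, 2]

    def test_undefined_distance_excluded(self):
        C = self.C.copy()
        C[0, 1] = C[1, 0] = np.nan
        X = expr_with_missing(np.ones((4, 3)), [(0, 0)])
        assert select_neighbors(C, X, 0, 0, K=2) == [2, 3]

    def test_fewer_candidates_than_k(self):
        X = expr_with_missing(np.ones((3, 2)), [(0, 0), (1, 0)])
        assert select_neighbors(self.C[:3, :3], X, 0, 0, K=5) == [2]

    def test_observed_cell_rejected(self):
        X = expr_with_missing(np.ones((4, 3)), [(0, 0)])
        with pytest.raises(ValueError, match="not missing"):
            select_neighbors(self.C, X, 1, 1, K=1)


class TestKnnImpute:
    def test_equal_distances_average(self):
        X = expr_with_missing([[0, 0], [10, 1], [20, 1]], [(0, 0)])
        C = np.array([[0.0, 2.0, 2.0], [2.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        result = knn_impute(X, C, K=2)
        assert result.completed.iloc[0, 0] == pytest.approx(15.0)

    def test_inverse_distance_weights(self):
        # distances 1 and 3 -> weights 0.75 / 0.25
        X = expr_with_missing([[0, 0], [10, 1], [20, 1]], [(0, 0)])
        C = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 1.0], [3.0, 1.0, 0.0]])
        result = knn_impute(X, C, K=2)
        assert result.completed.iloc[0, 0] == pytest.approx(12.5)

    def test_zero_distance_neighbour_takes_all_weight(self):
        X = expr_with_missing([[0, 0], [7, 1], [100, 1]], [(0, 0)])
        C = np.array([[0.0, 0.0, 2.0], [0.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        result = knn_impute(X, C, K=2)
        assert result.completed.iloc[0, 0] == pytest.approx(7.0)

    def test_estimate_within_neighbour_range(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(10, 6)))
        mask = np.zeros(X.shape, bool)
        mask[2, 3] = mask[5, 1] = True
        masked = apply_mask(X, mask)
        C = pairwise_expression_distance(masked)
        result = knn_impute(masked, C, K=3)
        for r, c, est in result.imputed_cells:
            nb = select_neighbors(C, masked, r, c, K=3)
            vals = masked.to_numpy()[nb, c]
            assert vals.min() - 1e-12 <= est <= vals.max() + 1e-12

    def test_observed_cells_bit_exact(self, small_expr):
        C = pairwise_expression_distance(small_expr)
        result = knn_impute(small_expr, C, K=2)
        obs = ~small_expr.isna().to_numpy()
        np.testing.assert_array_equal(result.completed.to_numpy()[obs],
                                      small_expr.to_numpy()[obs])

    def test_no_neighbour_falls_back_to_row_mean(self):
        # column 0 missing in every row: no candidate is valid there
        X = expr_with_missing([[0, 2.0, 4.0], [0, 1.0, 1.0]], [(0, 0), (1, 0)])
        C = np.array([[0.0, 1.0], [1.0, 0.0]])
        result = knn_impute(X, C, K=1)
        assert result.completed.iloc[0, 0] == pytest.approx(3.0)
        assert (0, 0) in result.fallback_cells

    def test_all_missing_row_without_neighbours_errors(self):
        X = expr_with_missing([[0, 0], [1.0, 2.0]], [(0, 0), (0, 1)])
        C = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ImputationError, match="no observed value"):
            knn_impute(X, C, K=1)


class TestLlsImpute:
    def test_identical_neighbour_coefficient_one(self):
        X = expr_with_missing([[1.0, 2.0, 0], [1.0, 2.0, 9.0]], [(0, 2)])
        C = np.array([[0.0, 0.5], [0.5, 0.0]])
        result = lls_impute(X, C, K=1)
        assert result.completed.iloc[0, 2] == pytest.approx(9.0, abs=1e-9)

    def test_scaled_neighbour_coefficient_two(self):
        X = expr_with_missing([[2.0, 4.0, 0], [1.0, 2.0, 5.0]], [(0, 2)])
        C = np.array([[0.0, 0.5], [0.5, 0.0]])
        result = lls_impute(X, C, K=1)
        assert result.completed.iloc[0, 2] == pytest.approx(10.0, abs=1e-9)

    def test_exact_linear_combination_recovered(self):
        # target = 2*n1 - 0.5*n2 on every sample; K=2 must recover it exactly
        rng = np.random.default_rng(3)
        n1 = rng.normal(size=8)
        n2 = rng.normal(size=8)
        target = 2.0 * n1 - 0.5 * n2
        X = pd.DataFrame([target, n1, n2])
        truth = X.iloc[0, 5]
        Xm = X.copy()
        Xm.iloc[0, 5] = np.nan
        C = pairwise_expression_distance(Xm)
        result = lls_impute(Xm, C, K=2)
        assert result.completed.iloc[0, 5] == pytest.approx(truth, abs=1e-9)

    def test_no_shared_sample_falls_back_to_knn(self):
        # neighbour is valid at the target column but shares no other sample
        X = expr_with_missing(
            [[1.0, 2.0, 0], [np.nan, np.nan, 9.0], [1.0, 2.0, 3.0]], [(0, 2)]
        )
        C = np.array([[0.0, 0.1, 5.0], [0.1, 0.0, 5.0], [5.0, 5.0, 0.0]])
        result = lls_impute(X, C, K=1)
        knn = knn_impute(X, C, K=1)
        assert result.completed.iloc[0, 2] == knn.completed.iloc[0, 2]
        assert (0, 2) in result.fallback_cells

    def test_rank_deficient_uses_minimum_norm(self):
        # two identical neighbours: w = (0.5, 0.5) is the min-norm solution
        X = expr_with_missing([[1.0, 2.0, 0], [1.0, 2.0, 8.0], [1.0, 2.0, 8.0]], [(0, 2)])
        C = np.array([[0.0, 0.5, 0.5], [0.5, 0.0, 0.1], [0.5, 0.1, 0.0]])
        result = lls_impute(X, C, K=2)
        assert result.completed.iloc[0, 2] == pytest.approx(8.0, abs=1e-9)


class TestExpressionOnlyEquivalence:
    def test_alpha_zero_combined_equals_expression_knn(self, clustered_dataset):
        expr = clustered_dataset.expression
        mask = generate_missing_mask(*expr.shape, SimulationConfig(p=20, seed=9))
        masked = apply_mask(expr, mask)
        D = pairwise_expression_distance(masked)
        H = pd.DataFrame(np.random.default_rng(1).uniform(0, 1, size=D.shape),
                         index=D.index, columns=D.columns)
        C0 = combined_distance(D, H, alpha=0.0)
        a = knn_impute(masked, D, K=5).completed.to_numpy()
        b = knn_impute(masked, C0, K=5).completed.to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-12, rtol=0)


class TestEstimators:
    def test_sklearn_contract(self):
        imp = GOKNNImputer(n_neighbors=3, alpha=0.5)
        params = imp.get_params()
        assert params["n_neighbors"] == 3 and params["alpha"] == 0.5
        clone(imp)  # must be cloneable for model selection

    def test_fit_transform_fills_all_missing(self, clustered_dataset):
        expr = clustered_dataset.expression
        mask = generate_missing_mask(*expr.shape, SimulationConfig(p=40, seed=4))
        masked = apply_mask(expr, mask)
        out = GOKNNImputer(functional_similarity=None).fit_transform(masked)
        assert not out.isna().any().any()
        obs = ~masked.isna().to_numpy()
        np.testing.assert_array_equal(out.to_numpy()[obs], masked.to_numpy()[obs])

    def test_similarity_aligned_by_index(self, clustered_dataset):
        ds = clustered_dataset
        expr = ds.expression
        model = TermSimilarityModel()
        mirnas = list(expr.index)
        H = functional_similarity(model, ds.ontology, ds.annotations, ds.targets,
                                  mirnas=mirnas)
        shuffled = H.iloc[::-1, ::-1]  # reversed id order must be realigned
        mask = generate_missing_mask(*expr.shape, SimulationConfig(p=20, seed=8))
        masked = apply_mask(expr, mask)
        out1 = GOKNNImputer(alpha=1.0, functional_similarity=H).fit_transform(masked)
        out2 = GOKNNImputer(alpha=1.0, functional_similarity=shuffled).fit_transform(masked)
        np.testing.assert_allclose(out1.to_numpy(), out2.to_numpy())

    def test_lls_estimator_matches_function(self, clustered_dataset):
        expr = clustered_dataset.expression
        mask = generate_missing_mask(*expr.shape, SimulationConfig(p=20, seed=6))
        masked = apply_mask(expr, mask)
        D = pairwise_expression_distance(masked)
        expected = lls_impute(masked, D, K=5).completed
        out = GOLLSImputer(n_neighbors=5, functional_similarity=None).fit_transform(masked)
        np.testing.assert_allclose(out.to_numpy(), expected.to_numpy())

    def test_ndarray_input_round_trip(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 5))
        X[1, 2] = np.nan
        out = GOKNNImputer().fit_transform(X)
        assert isinstance(out, np.ndarray)
        assert np.isfinite(out).all()

    def test_mismatched_similarity_shape_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        with pytest.raises(ValueError, match="shape"):
            GOKNNImputer(functional_similarity=np.ones((3, 3))).fit(X)
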