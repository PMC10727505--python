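import numpy as np
import pytest

import corrsearch.matrix as matrix_mod
from corrsearch import (
    FeatureMatrix,
    SearchConfig,
    build_joint_index,
    count_pairs,
    empirical_sensitivity,
    merge_batch_results,
    project_correlation,
    symmetrize,
    threshold_correlation_search,
    threshold_from_matrix,
    topk_correlation_search,
    topk_from_matrix,
)
from corrsearch.search import resolve_k_prime
from corrsearch.simulate import generate_block_correlated

EXHAUSTIVE = SearchConfig(approximation_factor=1e6)


def edges_equal(a, b, atol=1e-10):
    return (
        list(zip(a.i, a.j)) == list(zip(b.i, b.j))
        and np.allclose(a.value, b.value, atol=atol)
    )


class TestJointIndex:
    def test_index_size(self, random_matrix):
        P = project_correlation(random_matrix(8, 10))
        index = build_joint_index(P)
        assert index.n_points == 20

    def test_self_match_at_distance_zero(self, random_matrix):
        P = project_correlation(random_matrix(8, 10))
        index = build_joint_index(P)
        dist, idx = index.tree.query(P.values[:, 3][None, :], k=1)
        feature, sign = index.origin(idx[0])
        assert feature[0] == 3 and sign[0] == 1.0
        assert dist[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_knn_matches_brute_force(self, random_matrix):
        P = project_correlation(random_matrix(8, 10, seed=17))
        index = build_joint_index(P)
        points = np.vstack([P.values.T, -P.values.T])
        query = P.values[:, 0][None, :]
        dist, idx = index.tree.query(query, k=6)
        brute = np.linalg.norm(points - query, axis=1)
        np.testing.assert_allclose(np.sort(dist[0]), np.sort(brute)[:6], atol=1e-12)

    def test_empty_errors(self):
        from corrsearch.projections import ProjectedMatrix

        P = ProjectedMatrix(np.empty((5, 0)), "pearson", [])
        with pytest.raises(ValueError, match="empty"):
            build_joint_index(P)


class TestKPrime:
    def test_ceiling_and_cap(self):
        assert resolve_k_prime(10, 100, 1.0) == 1  # ceil(0.1) = 1
        assert resolve_k_prime(10, 4, 1e9) == 8  # capped at 2n
        assert resolve_k_prime(7, 3, 2.0) == 5  # ceil(14/3)


class TestTopkSearch:
    def test_exhaustive_equals_matrix_backend(self, random_matrix):
        X = random_matrix(10, 12, seed=23)
        exact = topk_from_matrix(X, 8)
        approx = topk_correlation_search(X, 8, EXHAUSTIVE)
        assert edges_equal(exact, approx)

    def test_all_pairs(self, random_matrix):
        X = random_matrix(6, 7, seed=2)
        edges = topk_correlation_search(X, count_pairs(7), EXHAUSTIVE)
        assert len(edges) == count_pairs(7)

    def test_planted_blocks_found_at_moderate_factor(self):
        # a=10, k=10, n=20 -> k'=5: every block feature retrieves all 4 partners
        X, truth = generate_block_correlated(20, 2000, [5], rho=0.95, seed=3)
        edges = topk_correlation_search(X, 10, SearchConfig(approximation_factor=10))
        assert edges.pair_set() == truth.pair_set()

    def test_negative_correlations_found(self, rng):
        values = rng.standard_normal((30, 10))
        values[:, 5] = -values[:, 2] + 0.01 * rng.standard_normal(30)
        edges = topk_correlation_search(FeatureMatrix(values), 1, EXHAUSTIVE)
        assert edges.pair_set() == {(2, 5)}
        assert edges.value[0] < -0.99

    def test_no_self_pairs_or_duplicates(self, random_matrix):
        edges = topk_correlation_search(random_matrix(8, 15, seed=4), 40, EXHAUSTIVE)
        assert np.all(edges.i < edges.j)
        assert len(edges.pair_set()) == len(edges)

    def test_invalid_args(self, random_matrix):
        with pytest.raises(ValueError, match="k must be"):
            topk_correlation_search(random_matrix(), 0)
        with pytest.raises(ValueError, match="approximation factor"):
            SearchConfig(approximation_factor=0.5)

    def test_never_materializes_full_matrix(self, random_matrix, monkeypatch):
        def boom(*args, **kwargs):  # structural memory contract
            raise AssertionError("index backend must not build the n x n matrix")

        monkeypatch.setattr(matrix_mod, "full_correlation_matrix", boom)
        edges = topk_correlation_search(random_matrix(8, 10, seed=1), 5, EXHAUSTIVE)
        assert len(edges) == 5


class TestDeterminism:
    @pytest.mark.parametrize("batch_size", [1, 3, None])
    @pytest.mark.parametrize("n_workers", [1, 4])
    def test_topk_invariant_to_batching(self, random_matrix, batch_size, n_workers):
        X = random_matrix(12, 20, seed=31)
        base = topk_correlation_search(X, 15, SearchConfig(approximation_factor=8))
        config = SearchConfig(approximation_factor=8, batch_size=batch_size,
                              n_workers=n_workers)
        other = topk_correlation_search(X, 15, config)
        np.testing.assert_array_equal(base.i, other.i)
        np.testing.assert_array_equal(base.j, other.j)
        np.testing.assert_array_equal(base.value, other.value)  # byte-identical

    def test_dualtree_identical(self, random_matrix):
        X = random_matrix(10, 15, seed=8)
        a = topk_correlation_search(X, 10, SearchConfig(approximation_factor=5))
        b = topk_correlation_search(X, 10, SearchConfig(approximation_factor=5, dualtree=True))
        np.testing.assert_array_equal(a.value, b.value)

    def test_low_memory_identical(self, random_matrix):
        X = random_matrix(10, 15, seed=8)
        a = topk_correlation_search(X, 10, SearchConfig(approximation_factor=5, batch_size=4))
        b = topk_correlation_search(
            X, 10, SearchConfig(approximation_factor=5, batch_size=4, low_memory=True)
        )
        np.testing.assert_array_equal(a.value, b.value)


class TestThresholdSearch:
    def test_exact_at_any_threshold(self, random_matrix):
        X = random_matrix(6, 12, seed=13)
        for t in (0.1, 0.3, 0.5, 0.8, 0.99):
            exact = threshold_from_matrix(X, t)
            approx = threshold_correlation_search(X, t)
            assert edges_equal(exact, approx), f"mismatch at t={t}"

    def test_high_threshold_empty(self, random_matrix):
        assert len(threshold_correlation_search(random_matrix(20, 8, seed=1), 1.0)) == 0

    def test_negation_pair(self, rng):
        col = rng.standard_normal(10)
        values = np.column_stack([col, -col, rng.standard_normal(10)])
        edges = threshold_correlation_search(FeatureMatrix(values), 0.9)
        assert (0, 1) in edges.pair_set()
        row = edges.value[[p == (0, 1) for p in zip(edges.i, edges.j)]]
        assert row[0] == pytest.approx(-1.0, abs=1e-12)

    def test_signed_ranking_excludes_negative(self, rng):
        col = rng.standard_normal(10)
        values = np.column_stack([col, -col, col + 0.01 * rng.standard_normal(10)])
        X = FeatureMatrix(values)
        edges = threshold_correlation_search(X, 0.9, SearchConfig(ranking="signed"))
        assert (0, 1) not in edges.pair_set()
        assert (0, 2) in edges.pair_set()

    def test_out_of_range(self, random_matrix):
        with pytest.raises(ValueError, match="threshold"):
            threshold_correlation_search(random_matrix(), 0.0)


class TestMergeAndSymmetrize:
    def test_single_batch_identity(self, random_matrix):
        X = random_matrix(8, 10, seed=3)
        edges = topk_correlation_search(X, 12, EXHAUSTIVE)
        merged = merge_batch_results([edges], 12)
        assert edges_equal(edges, merged)

    def test_split_invariance(self, random_matrix):
        X = random_matrix(12, 14, seed=9)
        one = topk_correlation_search(X, 10, SearchConfig(approximation_factor=6))
        seven = topk_correlation_search(
            X, 10, SearchConfig(approximation_factor=6, batch_size=2)
        )
        np.testing.assert_array_equal(one.i, seven.i)
        np.testing.assert_array_equal(one.value, seven.value)

    def test_duplicate_pair_dedup(self, random_matrix):
        X = random_matrix(8, 6, seed=2)
        edges = topk_correlation_search(X, 5, EXHAUSTIVE)
        merged = merge_batch_results([edges, edges], 5)
        assert edges_equal(edges, merged)

    def test_k_larger_than_available_sets_flag(self, random_matrix):
        X = random_matrix(8, 6, seed=2)
        edges = topk_correlation_search(X, 3, EXHAUSTIVE)
        merged = merge_batch_results([edges], 10)
        assert merged.truncated
        assert len(merged) == 3

    def test_symmetrize_doubles(self, random_matrix):
        edges = topk_correlation_search(random_matrix(8, 6, seed=2), 4, EXHAUSTIVE)
        sym = symmetrize(edges)
        assert len(sym) == 8
        assert {(j, i) for i, j in edges.pair_set()} <= sym.pair_set()

    def test_symmetrize_empty(self, random_matrix):
        edges = threshold_correlation_search(random_matrix(20, 5, seed=1), 1.0)
        assert len(symmetrize(edges)) == 0

    def test_symmetrized_backends_agree(self, random_matrix):
        X = random_matrix(9, 8, seed=12)
        a = symmetrize(topk_from_matrix(X, 6))
        b = topk_correlation_search(X, 6, SearchConfig(approximation_factor=1e6,
                                                       symmetrize=True))
        assert a.pair_set() == b.pair_set()


class TestEmpiricalSensitivity:
    def test_monotone_and_reaches_one(self):
        X, _ = generate_block_correlated(30, 200, [4, 4], rho=0.9, seed=5)
        rows = empirical_sensitivity(X, 12, [1.0, 4.0, 1e6])
        sens = [s for _, _, s in rows]
        assert all(0.0 <= s <= 1.0 for s in sens)
        assert sens == sorted(sens)
        assert sens[-1] == 1.0

    def test_exhaustive_factor_is_one(self, random_matrix):
        X = random_matrix(10, 10, seed=3)
        rows = empirical_sensitivity(X, 5, [1e6])
        assert rows[0][2] == 1.0
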