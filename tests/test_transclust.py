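"""Transitivity clustering: cost model, CAST, refinement, exact solver."""

import itertools

import numpy as np
import pytest

import homclust as hc


def all_partitions(items):
    """Independent brute-force set-partition enumerator."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def brute_cost(A, T, partition, roster):
    pos = {p: i for i, p in enumerate(roster)}
    member = {}
    for k, cl in enumerate(partition):
        for p in cl:
            member[p] = k
    cost = 0.0
    n = len(roster)
    for i in range(n):
        for j in range(i + 1, n):
            s = A[i, j]
            same = member[roster[i]] == member[roster[j]]
            if same and s <= T:
                cost += T - s
            elif not same and s > T:
                cost += s - T
    return cost


class TestClusteringCost:
    def test_three_node_enumeration(self, triangle_matrix):
        assert hc.clustering_cost(triangle_matrix, 5.0, hc.Clustering([["a", "b", "c"]])) == pytest.approx(4.0)
        assert hc.clustering_cost(triangle_matrix, 5.0, hc.Clustering([["a"], ["b"], ["c"]])) == pytest.approx(10.0)

    def test_zero_on_transitive_input(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 10.0
        A[2, 3] = A[3, 2] = 10.0
        S = hc.SimilarityMatrix.from_dense(A, list("abcd"))
        assert hc.clustering_cost(S, 5.0, hc.Clustering([["a", "b"], ["c", "d"]])) == 0.0

    def test_invalid_partition_rejected(self, triangle_matrix):
        with pytest.raises(ValueError):
            hc.clustering_cost(triangle_matrix, 5.0, hc.Clustering([["a", "b"]]))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        A = rng.uniform(0, 10, (6, 6))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        roster = list("abcdef")
        part = hc.Clustering([["a", "c", "e"], ["b", "d"], ["f"]])
        c1 = hc.clustering_cost(hc.SimilarityMatrix.from_dense(A, roster), 5.0, part)
        perm = rng.permutation(6)
        Ap = A[np.ix_(perm, perm)]
        rp = [roster[i] for i in perm]
        c2 = hc.clustering_cost(hc.SimilarityMatrix.from_dense(Ap, rp), 5.0, part)
        assert c1 == pytest.approx(c2)


class TestCastGreedy:
    def test_two_clean_cliques(self):
        A = np.zeros((6, 6))
        for block in (range(3), range(3, 6)):
            for i in block:
                for j in block:
                    if i != j:
                        A[i, j] = 10.0
        cp = hc.cast_greedy(hc.SimilarityMatrix.from_dense(A), 5.0)
        assert cp.cost == 0.0
        assert sorted(sorted(map(int, c)) for c in cp.clustering.clusters) == [[0, 1, 2], [3, 4, 5]]

    def test_single_node(self):
        cp = hc.cast_greedy(hc.SimilarityMatrix.from_dense(np.zeros((1, 1)), ["x"]), 5.0)
        assert cp.clustering.clusters == [["x"]] and cp.cost == 0.0

    def test_bounded_by_exact_on_triangle(self, triangle_matrix):
        cast = hc.cast_greedy(triangle_matrix, 5.0)
        exact = hc.exact_partition(triangle_matrix, 5.0)
        assert exact.cost == pytest.approx(4.0)
        assert 4.0 - 1e-9 <= cast.cost <= 10.0 + 1e-9


class TestRefinePartition:
    def test_exact_optimum_unchanged(self, triangle_matrix):
        exact = hc.exact_partition(triangle_matrix, 5.0)
        refined = hc.refine_partition(triangle_matrix, 5.0, exact.clustering)
        assert refined.cost == pytest.approx(exact.cost)

    def test_improves_all_singletons(self, triangle_matrix):
        start = hc.Clustering([["a"], ["b"], ["c"]])
        refined = hc.refine_partition(triangle_matrix, 5.0, start)
        assert refined.cost == pytest.approx(4.0)  # reaches the optimum here

    def test_never_increases_cost(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(3, 8))
            A = rng.uniform(0, 10, (n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0)
            S = hc.SimilarityMatrix.from_dense(A)
            labels = rng.integers(0, 3, n)
            start = hc.Clustering.from_labels([str(i) for i in range(n)], labels)
            start_cost = hc.clustering_cost(S, 5.0, start)
            refined = hc.refine_partition(S, 5.0, start)
            assert refined.cost <= start_cost + 1e-9


class TestExactPartition:
    def test_triangle_optimum(self, triangle_matrix):
        cp = hc.exact_partition(triangle_matrix, 5.0)
        assert cp.cost == pytest.approx(4.0)
        assert sorted(map(sorted, cp.clustering.clusters)) == [["a", "b", "c"]]

    def test_single_node_and_size_cap(self):
        cp = hc.exact_partition(hc.SimilarityMatrix.from_dense(np.zeros((1, 1))), 5.0)
        assert cp.cost == 0.0
        big = hc.SimilarityMatrix.from_dense(np.zeros((12, 12)))
        with pytest.raises(ValueError, match="n_max"):
            hc.exact_partition(big, 5.0, n_max=10)

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(15):
            n = int(rng.integers(2, 7))
            A = rng.uniform(0, 10, (n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0)
            roster = [str(i) for i in range(n)]
            best = min(
                brute_cost(A, 5.0, part, roster) for part in all_partitions(roster)
            )
            cp = hc.exact_partition(hc.SimilarityMatrix.from_dense(A, roster), 5.0)
            assert cp.cost == pytest.approx(best)


class TestTransclustCluster:
    def test_small_instances_hit_exact_optimum(self, triangle_matrix):
        cp = hc.transclust_cluster(triangle_matrix, 5.0)
        assert cp.cost == pytest.approx(4.0)

    def test_empty_roster(self):
        cp = hc.transclust_cluster(hc.SimilarityMatrix.from_dense(np.zeros((0, 0))), 5.0)
        assert cp.clustering.clusters == [] and cp.cost == 0.0

    def test_threshold_extremes(self):
        rng = np.random.default_rng(21)
        A = rng.uniform(1, 10, (7, 7)) * (rng.uniform(size=(7, 7)) < 0.4)
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        S = hc.SimilarityMatrix.from_dense(A)
        # T below every positive similarity: optimum = connected components
        lo = hc.transclust_cluster(S, 0.0).clustering
        n_comp, comp = S.connected_components()
        expected = sorted(sorted(np.where(comp == c)[0].tolist()) for c in range(n_comp))
        assert sorted(sorted(map(int, c)) for c in lo.clusters) == expected
        # T above every similarity: optimum = all singletons
        hi = hc.transclust_cluster(S, A.max() + 1.0).clustering
        assert all(len(c) == 1 for c in hi.clusters)

    def test_heuristic_never_beats_exact(self):
        rng = np.random.default_rng(33)
        equal = 0
        n_inst = 60
        for _ in range(n_inst):
            n = int(rng.integers(4, 9))
            A = rng.uniform(0, 10, (n, n)) * (rng.uniform(size=(n, n)) < 0.6)
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0)
            S = hc.SimilarityMatrix.from_dense(A)
            cast = hc.cast_greedy(S, 5.0)
            refined = hc.refine_partition(S, 5.0, cast.clustering)
            exact = hc.exact_partition(S, 5.0)
            assert refined.cost >= exact.cost - 1e-9
            if refined.cost <= exact.cost + 1e-9:
                equal += 1
        assert equal / n_inst >= 0.8  # heuristic quality floor on tiny instances


class TestEstimatorApi:
    def test_fit_predict_and_attrs(self, triangle_matrix):
        est = hc.TransitivityClustering(threshold=5.0)
        labels = est.fit_predict(triangle_matrix)
        assert list(labels) == [0, 0, 0]
        assert est.cost_ == pytest.approx(4.0)
        assert est.method_ in ("cast", "refined", "exact")
        assert est.get_params()["threshold"] == 5.0
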