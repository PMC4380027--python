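import itertools

import numpy as np
import pytest

from ampfam.cluster_eval import (
    ClusteringResult,
    cluster,
    evaluate,
    init_centroids,
    kmeans,
)
from ampfam.preprocess import LabeledMatrix


def labeled(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    return LabeledMatrix(
        X=X,
        y=y,
        feature_names=[f"composition:M:f{i}" for i in range(X.shape[1])],
        peptide_ids=[f"p{i}" for i in range(X.shape[0])],
    )


def wcss(X, assignment, K):
    total = 0.0
    for k in range(K):
        members = X[assignment == k]
        if len(members):
            total += ((members - members.mean(axis=0)) ** 2).sum()
    return total


class TestInitCentroids:
    def test_k2_class_means(self):
        m = labeled([[0, 0], [0, 2], [10, 0], [10, 2]], [1, 1, 0, 0])
        c = init_centroids(m, 2)
        np.testing.assert_array_equal(c, [[0, 1], [10, 1]])

    def test_k2_single_point_classes(self):
        m = labeled([[1, 1], [5, 5]], [1, 0])
        c = init_centroids(m, 2)
        np.testing.assert_array_equal(c, [[1, 1], [5, 5]])

    def test_k3_first_centroid_is_target_mean(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (5, 2)),
                       rng.normal(8, 1, (6, 2)),
                       rng.normal(-8, 1, (6, 2))])
        y = np.array([1] * 5 + [0] * 12, bool)
        m = labeled(X, y)
        c = init_centroids(m, 3, seed=4)
        np.testing.assert_allclose(c[0], X[:5].mean(axis=0))
        assert c.shape == (3, 2)
        # deterministic given the seed
        np.testing.assert_array_equal(c, init_centroids(m, 3, seed=4))

    def test_k_out_of_range(self):
        m = labeled([[0.0], [1.0]], [1, 0])
        with pytest.raises(ValueError, match="out of range"):
            init_centroids(m, 3)


class TestKmeans:
    def test_separated_clouds_converge_fast(self):
        m = labeled(
            [[0, 0], [0.5, 0], [0, 0.5], [10, 10], [10.5, 10], [10, 10.5]],
            [1, 1, 1, 0, 0, 0],
        )
        c0 = init_centroids(m, 2)
        assignment, _, iters = kmeans(m.X, c0)
        assert iters <= 2
        assert len(set(assignment[:3])) == 1
        assert len(set(assignment[3:])) == 1
        assert assignment[0] != assignment[3]

    def test_k_equals_n_each_point_own_cluster(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        assignment, _, _ = kmeans(X, X.copy())
        assert sorted(assignment) == [0, 1, 2, 3]

    def test_final_wcss_matches_exhaustive_two_partition(self):
        # 6 points, mildly separated; Lloyd from class-mean init must land
        # on the globally optimal 2-partition
        X = np.array(
            [[0.0, 0.0], [1.0, 0.2], [0.4, 0.9],
             [5.0, 5.0], [5.6, 4.4], [4.6, 5.4]]
        )
        y = np.array([1, 1, 1, 0, 0, 0], bool)
        m = labeled(X, y)
        assignment, _, _ = kmeans(m.X, init_centroids(m, 2))
        got = wcss(X, assignment, 2)
        best = min(
            wcss(X, np.array(a), 2)
            for a in itertools.product([0, 1], repeat=6)
            if len(set(a)) == 2
        )
        assert got == pytest.approx(best)

    def test_agrees_with_sklearn_from_same_init(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(6, 1, (15, 3))])
        y = np.array([1] * 10 + [0] * 15, bool)
        m = labeled(X, y)
        init = init_centroids(m, 2)
        ours, _, _ = kmeans(m.X, init)
        sk = KMeans(n_clusters=2, init=init, n_init=1, algorithm="lloyd").fit(X)
        assert wcss(X, ours, 2) == pytest.approx(wcss(X, sk.labels_, 2))

    def test_nonfinite_rejected(self):
        X = np.array([[np.nan, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="non-finite"):
            kmeans(X, np.zeros((2, 2)))


class TestEvaluate:
    def _result(self, assignment, K, target_cluster=0):
        assignment = np.asarray(assignment)
        return ClusteringResult(
            K=K,
            assignment=assignment,
            centroids=np.zeros((K, 1)),
            target_cluster=target_cluster,
            iterations=1,
        )

    def test_perfect_two_clustering(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0], bool)
        res = self._result([0, 0, 0, 1, 1, 1, 1], 2)
        m = evaluate(res, y)
        assert (m.sensitivity, m.specificity, m.precision, m.f_measure) == (
            1.0, 1.0, 1.0, 1.0,
        )
        assert m.entropy == 0.0 and m.purity == 1.0
        assert m.jaccard == 1.0

    def test_hand_computed_confusion(self):
        # n=10: TP=3, FP=1, FN=1, TN=5
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], bool)
        assignment = [0, 0, 0, 1, 0, 1, 1, 1, 1, 1]
        m = evaluate(self._result(assignment, 2), y)
        assert (m.TP, m.FP, m.FN, m.TN) == (3, 1, 1, 5)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(5 / 6)
        assert m.precision == pytest.approx(0.75)
        assert m.f_measure == pytest.approx(0.75)
        assert m.jaccard == pytest.approx(0.6)
        assert m.accuracy == pytest.approx(0.8)

    def test_counts_always_total_n(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            K = int(rng.integers(2, 5))
            y = rng.random(n) < 0.4
            if not y.any() or y.all():
                continue
            assignment = rng.integers(0, K, size=n)
            m = evaluate(self._result(assignment, K), y)
            assert m.TP + m.TN + m.FP + m.FN == n
            for v in (m.accuracy, m.sensitivity, m.specificity,
                      m.precision, m.f_measure, m.jaccard, m.purity):
                assert 0.0 <= v <= 1.0
            assert m.entropy >= 0.0

    def test_invariant_to_cluster_relabeling(self):
        y = np.array([1, 1, 0, 0, 0, 1, 0], bool)
        assignment = np.array([0, 0, 1, 1, 2, 2, 0])
        perm = {0: 2, 1: 0, 2: 1}
        m1 = evaluate(self._result(assignment, 3), y)
        m2 = evaluate(
            self._result(np.array([perm[a] for a in assignment]), 3), y
        )
        assert m1 == m2

    def test_target_cluster_tie_goes_to_lower_index(self):
        y = np.array([1, 1, 0, 0], bool)
        assignment = np.array([1, 0, 0, 1])  # one target in each cluster
        m = evaluate(self._result(assignment, 2), y)
        # cluster 0 wins the tie: TP = 1 (p1), FP = 1 (p2)
        assert (m.TP, m.FP) == (1, 1)

    def test_no_targets_rejected(self):
        with pytest.raises(ValueError, match="no target rows"):
            evaluate(self._result([0, 1], 2), np.array([0, 0], bool))


class TestMetricIdentities:
    def test_f_measure_two_forms_agree(self):
        # harmonic mean of precision/recall vs the 2TP/(2TP+FN+FP) form
        rng = np.random.default_rng(123)
        for _ in range(1000):
            TP, FP, FN = rng.integers(0, 50, size=3)
            precision = TP / (TP + FP) if TP + FP else 0.0
            recall = TP / (TP + FN) if TP + FN else 0.0
            if precision + recall == 0:
                continue
            harmonic = 2 * precision * recall / (precision + recall)
            count_form = 2 * TP / (2 * TP + FN + FP)
            assert harmonic == pytest.approx(count_form, abs=1e-12)

    def test_purity_one_iff_entropy_zero(self):
        rng = np.random.default_rng(321)
        seen_pure = seen_impure = False
        for _ in range(400):
            n = int(rng.integers(4, 20))
            K = int(rng.integers(2, 4))
            y = rng.random(n) < 0.5
            if not y.any() or y.all():
                continue
            assignment = rng.integers(0, K, size=n)
            res = ClusteringResult(
                K=K, assignment=assignment, centroids=np.zeros((K, 1)),
                target_cluster=0, iterations=1,
            )
            m = evaluate(res, y)
            assert (m.purity == 1.0) == (m.entropy == 0.0)
            seen_pure |= m.purity == 1.0
            seen_impure |= m.purity < 1.0
        assert seen_pure and seen_impure
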