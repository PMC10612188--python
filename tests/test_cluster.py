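"""Clustering algorithms, validation indices, and k selection."""

import numpy as np
import pandas as pd
import pytest

from glyvar import (
    calinski_harabasz_index,
    davies_bouldin_index,
    kmeans_fit,
    kmedians_fit,
    order_clusters,
    quantile_clusters,
    select_k,
    silhouette_index,
    standardize,
)
from glyvar.cluster import apply_scaling
from oracles import (
    calinski_harabasz_loop,
    davies_bouldin_loop,
    kmeans_global_optimum,
    silhouette_loop,
)

# the hand-workable 4-point configuration: two tight pairs far apart
FOUR_POINTS = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
FOUR_LABELS = np.array([0, 0, 1, 1])


class TestStandardize:
    def test_hand_example(self):
        Z, sc = standardize(np.array([[0.0], [100.0]]))
        np.testing.assert_allclose(Z.ravel(), [-0.7071067811865476, 0.7071067811865476])

    def test_idempotent_with_stored_scaling(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 3, (50, 2))
        Z, sc = standardize(X)
        np.testing.assert_allclose(apply_scaling(X, sc), Z, atol=1e-12)

    def test_constant_column_named(self):
        X = pd.DataFrame({"hvs": [1.0, 2.0, 3.0], "sd": [0.5, 0.5, 0.5]})
        with pytest.raises(ValueError, match="sd"):
            standardize(X)


class TestKMeans:
    def test_k_equals_n_zero_objective(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 2))
        m = kmeans_fit(X, k=6, seed=0, n_init=5)
        assert m.objective == pytest.approx(0.0, abs=1e-12)

    def test_one_dimensional_pairs(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        m = kmeans_fit(X, 2, seed=0, n_init=10)
        cents = sorted(m.centroids.ravel().tolist())
        assert cents == pytest.approx([0.5, 10.5])
        assert m.labels[0] == m.labels[1] != m.labels[2]

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_fit(np.zeros((3, 2)), 4)

    def test_objective_nonincreasing_within_run(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 2))
        m = kmeans_fit(X, 4, seed=3, n_init=5)
        assert np.all(np.diff(m.objective_trace) <= 1e-9)

    def test_matches_bruteforce_optimum(self):
        rng = np.random.default_rng(11)
        hits = 0
        trials = 40
        for _ in range(trials):
            n = int(rng.integers(6, 11))
            k = int(rng.integers(2, 4))
            X = rng.normal(size=(n, 2))
            m = kmeans_fit(X, k, seed=int(rng.integers(1 << 30)), n_init=20)
            best = kmeans_global_optimum(X, k)
            if m.objective <= best + 1e-8:
                hits += 1
        assert hits >= 0.95 * trials

    def test_determinism(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(120, 2))
        a = kmeans_fit(X, 3, seed=9, n_init=10)
        b = kmeans_fit(X, 3, seed=9, n_init=10)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.centroids, b.centroids)


class TestKMedians:
    def test_singletons_zero_objective(self):
        X = np.array([[0.0], [5.0], [9.0]])
        m = kmedians_fit(X, 3, seed=0, n_init=5)
        assert m.objective == pytest.approx(0.0, abs=1e-12)

    def test_outlier_grouping(self):
        X = np.array([[0.0], [1.0], [2.0], [100.0]])
        m = kmedians_fit(X, 2, seed=0, n_init=10)
        assert m.labels[0] == m.labels[1] == m.labels[2] != m.labels[3]
        cents = sorted(m.centroids.ravel().tolist())
        assert cents == pytest.approx([1.0, 100.0])

    def test_median_more_outlier_robust_than_mean(self):
        # one cluster with an extreme outlier: the k-means centroid moves
        # further from the clean-cluster center than the k-medians one
        X = np.vstack(
            [
                np.array([[0.0, 0.0], [0.1, 0.0], [0.0, 0.1], [-0.1, 0.0], [0.0, -0.1]]),
                np.array([[40.0, 0.0]]),
                np.array([[10.0, 10.0], [10.1, 10.0], [10.0, 10.1]]),
            ]
        )
        km = kmeans_fit(X, 2, seed=1, n_init=20)
        kd = kmedians_fit(X, 2, seed=1, n_init=20)

        def shift(model):
            lab = model.labels[0]
            return np.linalg.norm(model.centroids[lab] - np.array([0.0, 0.0]))

        assert shift(kd) < shift(km)


class TestQuantileClusters:
    def test_even_split(self):
        labels = quantile_clusters(np.arange(1.0, 10.0))
        np.testing.assert_array_equal(labels, [0, 0, 0, 1, 1, 1, 2, 2, 2])

    def test_n10_sizes(self):
        labels = quantile_clusters(np.arange(10.0))
        sizes = np.bincount(labels)
        np.testing.assert_array_equal(sizes, [4, 3, 3])

    def test_total_tie_warns_and_collapses(self):
        with pytest.warns(UserWarning, match="ties"):
            labels = quantile_clusters(np.full(9, 1.0))
        assert set(labels) == {0}

    def test_empty_error(self):
        with pytest.raises(ValueError):
            quantile_clusters(np.array([]))

    def test_tie_block_not_split(self):
        values = np.array([1.0, 2.0, 2.0, 2.0, 5.0, 6.0])
        with pytest.warns(UserWarning, match="ties"):
            labels = quantile_clusters(values, 3)
        assert len(set(labels[values == 2.0])) == 1


class TestIndices:
    def test_silhouette_hand_example(self):
        s = silhouette_index(FOUR_POINTS, FOUR_LABELS)
        b = (np.sqrt(100) + np.sqrt(101)) / 2
        assert s == pytest.approx((b - 1.0) / b, abs=1e-12)
        assert s > 0.9

    def test_silhouette_tight_far_pairs(self):
        X = np.array([[0, 0], [0, 0.01], [50, 0], [50, 0.01]], dtype=float)
        assert silhouette_index(X, [0, 0, 1, 1]) > 0.99

    def test_silhouette_random_labels_near_zero(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 2))
        labels = rng.integers(0, 2, 200)
        assert abs(silhouette_index(X, labels)) < 0.1

    def test_davies_bouldin_hand_example(self):
        assert davies_bouldin_index(FOUR_POINTS, FOUR_LABELS) == pytest.approx(0.1)

    def test_davies_bouldin_coincident_centroids_error(self):
        # both clusters have centroid (1, 0)
        X = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, -1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="coincident"):
            davies_bouldin_index(X, [0, 0, 1, 1])

    def test_calinski_harabasz_hand_example(self):
        assert calinski_harabasz_index(FOUR_POINTS, FOUR_LABELS) == pytest.approx(200.0)

    def test_calinski_monotone_in_separation(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(60, 2))
        labels = np.repeat([0, 1], 30)
        vals = []
        for sep in (2.0, 20.0):
            X = base.copy()
            X[30:, 0] += sep
            vals.append(calinski_harabasz_index(X, labels))
        assert vals[1] > vals[0]

    def test_duplicate_points_error(self):
        X = np.zeros((6, 2))
        X[3:] += 1.0
        with pytest.raises(ValueError, match="dispersion"):
            calinski_harabasz_index(X, [0, 0, 0, 1, 1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_random_data(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 120))
        k = int(rng.integers(2, 5))
        X = rng.normal(size=(n, 2)) + rng.integers(0, 4, (n, 1))
        labels = rng.integers(0, k, n)
        if len(set(labels.tolist())) < 2:
            labels[0] = (labels[0] + 1) % k
        assert silhouette_index(X, labels) == pytest.approx(
            silhouette_loop(X, labels), abs=1e-10
        )
        assert davies_bouldin_index(X, labels) == pytest.approx(
            davies_bouldin_loop(X, labels), abs=1e-10
        )
        assert calinski_harabasz_index(X, labels) == pytest.approx(
            calinski_harabasz_loop(X, labels), abs=1e-8
        )

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(80, 2)) + rng.integers(0, 3, (80, 1)) * 4
        labels = rng.integers(0, 3, 80)
        perm = np.array([2, 0, 1])
        for fn in (silhouette_index, davies_bouldin_index, calinski_harabasz_index):
            assert fn(X, labels) == pytest.approx(fn(X, perm[labels]), abs=1e-10)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(70, 2)) + rng.integers(0, 3, (70, 1)) * 5
        labels = rng.integers(0, 3, 70)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        XR = X @ R.T
        for fn in (silhouette_index, davies_bouldin_index, calinski_harabasz_index):
            assert fn(X, labels) == pytest.approx(fn(XR, labels), abs=1e-8)

    def test_k_bounds(self):
        X = np.random.default_rng(9).normal(size=(5, 2))
        with pytest.raises(ValueError):
            silhouette_index(X, [0, 0, 0, 0, 0])


class TestSelectK:
    @staticmethod
    def blobs(k, n_per=60, seed=0, spread=0.3):
        rng = np.random.default_rng(seed)
        centers = np.array([[0, 0], [8, 0], [4, 7], [12, 7], [0, 9]])[:k]
        return np.vstack(
            [rng.normal(c, spread, size=(n_per, 2)) for c in centers]
        )

    def test_three_blobs_select_three(self):
        table, k = select_k(self.blobs(3), range(2, 10), seed=1)
        assert k == 3
        assert sorted(table["k"]) == list(range(2, 10))

    def test_two_blobs_select_two(self):
        _, k = select_k(self.blobs(2), range(2, 10), seed=2)
        assert k == 2

    def test_worse_separation_lowers_silhouette(self):
        tight, _ = select_k(self.blobs(3, spread=0.3, seed=3), range(3, 4), seed=3)
        loose, _ = select_k(self.blobs(3, spread=2.5, seed=3), range(3, 4), seed=3)
        assert loose["silhouette"].iloc[0] < tight["silhouette"].iloc[0]


class TestOrderClusters:
    def test_ordering_by_mean_hvs(self):
        X = np.array([[70.0], [72.0], [20.0], [22.0], [45.0], [46.0]])
        m = kmeans_fit(X, 3, seed=0, n_init=10)
        mapping = order_clusters(m, X.ravel())
        names = m.group_names()
        assert names[list(X.ravel()).index(20.0)] == "low"
        assert names[0] == "high" and names[4] == "medium"
        assert sorted(mapping.values()) == ["high", "low", "medium"]

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(10)
        hvs = np.concatenate([rng.normal(20, 2, 30), rng.normal(45, 2, 30), rng.normal(75, 2, 30)])
        X = hvs[:, None]
        a = kmeans_fit(X, 3, seed=1, n_init=10)
        b = kmeans_fit(X, 3, seed=77, n_init=10)
        order_clusters(a, hvs)
        order_clusters(b, hvs)
        np.testing.assert_array_equal(a.group_names(), b.group_names())

    def test_requires_k3(self):
        m = kmeans_fit(np.arange(8.0)[:, None], 2, seed=0)
        with pytest.raises(ValueError, match="k=3"):
            order_clusters(m, np.arange(8.0))
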