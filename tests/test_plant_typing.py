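"""Standardization, K-medoids, silhouette/WCSS diagnostics and type naming."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score as sk_silhouette

from cabbage3d import (TypeLabel, assign_type_labels, kmedoids, select_k,
                       silhouette_score, wcss_curve, zscore_standardize)
from cabbage3d.errors import ValidationError

# centroid trait means of the four published clusters, reordered into the
# canonical trait order (T, theta_bar, W, V, S, S1, S2, S3, O, M); the
# inclination column is the table's undefined "R" column, in degrees
PUBLISHED_CENTROIDS = np.array([
    # T       theta   W       V       S       S1      S2      S3      O        M
    [1.1274, 60.9285, 0.9157, 0.2484, 2.1247, 0.8359, 0.7769, 0.7046, 86.6433, 0.1862],
    [1.5136, 67.8658, 0.6823, 0.1457, 1.5216, 0.4127, 0.4109, 0.4555, 105.3768, 0.1638],
    [1.2058, 61.4423, 0.4127, 0.0422, 0.5850, 0.2217, 0.1768, 0.3443, 155.3771, 0.0877],
    [1.4600, 70.3238, 0.7195, 0.1739, 1.6990, 0.7689, 0.6320, 1.6705, 372.2589, 0.1764],
])


def blobs(centers, n_each, sd, seed, p=None):
    r = np.random.default_rng(seed)
    centers = np.asarray(centers, dtype=float)
    if p is None:
        p = centers.shape[1]
    X = np.vstack([c + sd * r.normal(size=(n_each, p)) for c in centers])
    y = np.repeat(np.arange(len(centers)), n_each)
    return X, y


class TestZscore:
    def test_simple_column(self):
        sm = zscore_standardize(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(sm.values[:, 0], [-1, 0, 1])
        assert sm.col_sds[0] == pytest.approx(1.0)

    def test_idempotent_on_standardized_input(self, rng):
        X = rng.normal(size=(40, 5))
        once = zscore_standardize(X).values
        twice = zscore_standardize(once).values
        np.testing.assert_allclose(once, twice, atol=1e-9)

    def test_constant_column_zeroed_with_warning(self, rng):
        X = np.column_stack([rng.normal(size=20), np.full(20, 7.0)])
        with pytest.warns(UserWarning, match="constant"):
            sm = zscore_standardize(X)
        assert np.all(sm.values[:, 1] == 0)
        assert sm.constant_cols[1]

    def test_needs_two_rows(self):
        with pytest.raises(ValidationError):
            zscore_standardize(np.ones((1, 3)))


class TestKMedoids:
    def test_1d_medoid_tie_breaks_low_index(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0]])
        model = kmedoids(X, k=1, seed=0)
        # costs: 13, 11, 11, 29 -> tie between index 1 and 2, lowest wins
        assert model.medoid_indices.tolist() == [1]
        assert model.total_cost == pytest.approx(11.0)

    def test_k_equals_n(self, rng):
        X = rng.normal(size=(6, 3))
        model = kmedoids(X, k=6, seed=0)
        assert model.total_cost == 0.0
        assert sorted(model.medoid_indices) == list(range(6))

    def test_separated_blobs_recovered_across_seeds(self):
        centers = 10 * np.eye(3)
        X, y = blobs(centers, 50, 0.2, seed=0)
        for seed in range(10):
            model = kmedoids(X, k=3, seed=seed)
            assert adjusted_rand_score(y, model.labels) == 1.0

    def test_medoids_are_one_iteration_stable(self, rng):
        X = rng.normal(size=(60, 4))
        model = kmedoids(X, k=3, seed=2)
        # replay one more Voronoi iteration from the final state
        d = np.linalg.norm(X[:, None] - X[model.medoid_indices][None], axis=2)
        labels = d.argmin(axis=1)
        np.testing.assert_array_equal(labels, model.labels)
        for c in range(3):
            members = np.flatnonzero(labels == c)
            dd = np.linalg.norm(X[members][:, None] - X[members][None], axis=2)
            best = members[int(np.argmin(dd.sum(axis=1)))]
            assert best == model.medoid_indices[c]

    def test_cost_consistency_invariant(self, rng):
        X = rng.normal(size=(50, 3))
        model = kmedoids(X, k=4, seed=1)
        d = np.linalg.norm(X - X[model.medoid_indices][model.labels], axis=1)
        assert model.total_cost == pytest.approx(d.sum(), abs=1e-9)

    def test_invalid_k(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValidationError):
            kmedoids(X, k=6)
        with pytest.raises(ValidationError):
            kmedoids(X, k=0)


class TestSilhouette:
    def test_two_tight_blobs_near_one(self):
        X = np.array([[0.0], [0.01], [10.0], [10.01]])
        assert silhouette_score(X, [0, 0, 1, 1]) >= 0.99

    def test_random_split_of_one_blob_near_zero(self):
        vals = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(40, 3))
            labels = r.integers(0, 2, 40)
            if len(np.unique(labels)) < 2:
                continue
            vals.append(silhouette_score(X, labels))
        assert np.all(np.abs(vals) <= 0.2)

    def test_six_point_hand_example(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        # hand computation, e.g. point 0: a=(1+2)/2=1.5, b=(10+11+12)/3=11
        expected = np.mean([
            (11 - 1.5) / 11, (10 - 1.0) / 10, (9 - 1.5) / 9,
            (9 - 1.5) / 9, (10 - 1.0) / 10, (11 - 1.5) / 11,
        ])
        assert silhouette_score(X, labels) == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn_on_random_data(self, rng):
        X = rng.normal(size=(50, 4))
        labels = rng.integers(0, 3, 50)
        ours = silhouette_score(X, labels)
        assert ours == pytest.approx(sk_silhouette(X, labels), abs=1e-12)

    def test_single_cluster_is_an_error(self, rng):
        with pytest.raises(ValidationError):
            silhouette_score(rng.normal(size=(10, 2)), np.zeros(10))


class TestWcss:
    def test_k_equals_n_is_zero(self, rng):
        X = rng.normal(size=(8, 2))
        assert wcss_curve(X, [8], seed=0)[8] == pytest.approx(0.0, abs=1e-12)

    def test_k1_equals_total_sum_of_squares(self, rng):
        X = rng.normal(size=(30, 3))
        expected = ((X - X.mean(axis=0)) ** 2).sum()
        assert wcss_curve(X, [1], seed=0)[1] == pytest.approx(expected, rel=1e-9)

    def test_elbow_at_four_blobs(self):
        centers = 20 * np.eye(4)
        X, _ = blobs(centers, 30, 0.3, seed=1)
        wcss = wcss_curve(X, range(1, 8), seed=0)
        ks = sorted(wcss)
        vals = np.array([wcss[k] for k in ks])
        assert np.all(np.diff(vals) <= 1e-9)  # non-increasing
        second_diff = vals[:-2] - 2 * vals[1:-1] + vals[2:]
        assert ks[1 + int(np.argmax(second_diff))] == 4


class TestSelectK:
    def test_four_separated_clusters(self):
        centers = 12 * np.eye(4)
        X, _ = blobs(centers, 25, 0.5, seed=3)
        sm = zscore_standardize(X)
        k_best, sil, wcss = select_k(sm, range(2, 9), seed=0)
        assert k_best == 4
        assert set(sil) == set(range(2, 9)) and set(wcss) == set(range(2, 9))

    def test_two_blobs(self):
        X, _ = blobs([[0, 0], [15, 0]], 20, 0.5, seed=4)
        k_best, _, _ = select_k(zscore_standardize(X), range(2, 6), seed=0)
        assert k_best == 2


class TestAssignTypeLabels:
    def test_published_centroid_matrix(self):
        mapping = assign_type_labels(PUBLISHED_CENTROIDS)
        assert mapping == {0: TypeLabel.FULL, 1: TypeLabel.HIGHLY_LEAN,
                           2: TypeLabel.TIGHT, 3: TypeLabel.ROUND_SPREAD}

    @pytest.mark.parametrize("seed", range(5))
    def test_row_permutation_equivariance(self, seed):
        perm = np.random.default_rng(seed).permutation(4)
        base = assign_type_labels(PUBLISHED_CENTROIDS)
        permuted = assign_type_labels(PUBLISHED_CENTROIDS[perm])
        for new_row, old_row in enumerate(perm):
            assert permuted[new_row] == base[old_row]

    def test_unsupported_k(self):
        with pytest.raises(ValidationError, match="4 clusters"):
            assign_type_labels(PUBLISHED_CENTROIDS[:3])


from hypothesis import given, settings, strategies as st


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 10_000), st.integers(3, 20), st.integers(2, 5))
def test_silhouette_always_within_bounds(seed, n, k):
    """The mean silhouette coefficient lies in [-1, 1] for any labeling."""
    r = np.random.default_rng(seed)
    X = r.normal(size=(n, 3))
    labels = r.integers(0, k, n)
    if len(np.unique(labels)) < 2:
        labels[0] = 0
        labels[1] = 1
    assert -1.0 <= silhouette_score(X, labels) <= 1.0


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 10_000), st.integers(2, 40), st.integers(1, 8))
def test_zscore_columns_centered_and_unit(seed, n, p):
    """Non-constant z-scored columns have mean 0 and sample sd 1."""
    X = np.random.default_rng(seed).normal(size=(n, p)) * 7 + 3
    sm = zscore_standardize(X)
    np.testing.assert_allclose(sm.values.mean(axis=0), 0, atol=1e-9)
    np.testing.assert_allclose(sm.values.std(axis=0, ddof=1), 1, atol=1e-9)
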