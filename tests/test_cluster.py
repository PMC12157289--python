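import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score, silhouette_score

import mealpatterns as mp
from tests.conftest import euclidean_matrix


def test_ward_hand_example():
    """1-D points {0, 1, 10}: merge (0,1) at height 1, then at
    sqrt(361/3) by the Lance-Williams update."""
    D = euclidean_matrix(np.array([[0.0], [1.0], [10.0]]))
    tree = mp.ward_linkage(D)
    assert tree.merges[0, :2].tolist() == [0, 1]
    assert tree.merges[0, 2] == pytest.approx(1.0)
    assert tree.merges[1, 2] == pytest.approx(np.sqrt(361 / 3))


def test_ward_identical_points_merge_at_zero():
    D = np.zeros((5, 5))
    tree = mp.ward_linkage(D)
    assert np.allclose(tree.heights, 0.0)


def test_ward_heights_monotone_on_dtw_input(small_series):
    _, _, series = small_series
    dm = mp.distance_matrix(series)
    tree = mp.ward_linkage(dm)
    assert np.all(np.diff(tree.heights) >= -1e-12)


@pytest.mark.parametrize("seed", range(10))
def test_ward_matches_scipy_reference_on_euclidean(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    points = rng.normal(size=(n, 2))
    ours = mp.ward_linkage(euclidean_matrix(points))
    ref = linkage(pdist(points), method="ward")
    assert np.allclose(ours.heights, ref[:, 2], atol=1e-8)
    for k in range(1, n + 1):
        mine = mp.cut_tree(ours, k)
        theirs = fcluster(ref, t=k, criterion="maxclust")
        assert adjusted_rand_score(mine, theirs) == pytest.approx(1.0)


def test_ward_rejects_invalid_matrix():
    with pytest.raises(ValueError):
        mp.ward_linkage(np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError):
        mp.ward_linkage(np.array([[0.0, -1.0], [-1.0, 0.0]]))


def test_cut_tree_extremes_and_range():
    D = euclidean_matrix(np.arange(6, dtype=float)[:, None])
    tree = mp.ward_linkage(D)
    assert len(set(mp.cut_tree(tree, 1))) == 1
    assert len(set(mp.cut_tree(tree, 6))) == 6
    with pytest.raises(ValueError):
        mp.cut_tree(tree, 0)
    with pytest.raises(ValueError):
        mp.cut_tree(tree, 7)


def test_cut_tree_partitions_are_nested():
    rng = np.random.default_rng(1)
    points = rng.normal(size=(15, 2))
    tree = mp.ward_linkage(euclidean_matrix(points))
    for k in range(2, 15):
        coarse = mp.cut_tree(tree, k)
        fine = mp.cut_tree(tree, k + 1)
        # every fine cluster maps into exactly one coarse cluster
        for lab in np.unique(fine):
            assert len(np.unique(coarse[fine == lab])) == 1


def test_renumber_by_value_orders_clusters_semantically():
    labels = np.array([0, 0, 1, 1, 2, 2])
    values = np.array([20.0, 18.0, 5.0, 7.0, 11.0, 12.0])
    renumbered = mp.renumber_by_value(labels, values)
    assert renumbered.tolist() == [3, 3, 1, 1, 2, 2]


def test_silhouette_two_tight_pairs():
    """Within-distance 1, between-distance 10: every width is 0.9."""
    D = np.array(
        [
            [0.0, 1.0, 10.0, 10.0],
            [1.0, 0.0, 10.0, 10.0],
            [10.0, 10.0, 0.0, 1.0],
            [10.0, 10.0, 1.0, 0.0],
        ]
    )
    mean, widths = mp.avg_silhouette(D, [0, 0, 1, 1])
    assert widths == pytest.approx([0.9] * 4)
    assert mean == pytest.approx(0.9)


def test_silhouette_identical_points_zero_and_bounds():
    D = np.zeros((6, 6))
    mean, widths = mp.avg_silhouette(D, [0, 0, 0, 1, 1, 1])
    assert mean == 0.0
    rng = np.random.default_rng(2)
    points = rng.normal(size=(20, 3))
    D = euclidean_matrix(points)
    labels = rng.integers(0, 3, size=20)
    while len(np.unique(labels)) < 2:  # pragma: no cover
        labels = rng.integers(0, 3, size=20)
    _, widths = mp.avg_silhouette(D, labels)
    assert np.all(widths >= -1.0) and np.all(widths <= 1.0)


def test_silhouette_singleton_scores_zero():
    D = euclidean_matrix(np.array([[0.0], [0.5], [9.0]]))
    _, widths = mp.avg_silhouette(D, [0, 0, 1])
    assert widths[2] == 0.0


def test_silhouette_matches_sklearn_oracle():
    rng = np.random.default_rng(3)
    points = rng.normal(size=(30, 2))
    points[15:] += 4.0
    D = euclidean_matrix(points)
    labels = (np.arange(30) >= 15).astype(int)
    mean, _ = mp.avg_silhouette(D, labels)
    assert mean == pytest.approx(
        silhouette_score(D, labels, metric="precomputed"), abs=1e-12
    )


def test_silhouette_single_cluster_is_error():
    with pytest.raises(ValueError):
        mp.avg_silhouette(np.zeros((3, 3)), [0, 0, 0])


def test_silhouette_improves_with_separation():
    rng = np.random.default_rng(4)
    base = rng.normal(size=(20, 2))
    labels = (np.arange(20) >= 10).astype(int)

    def mean_width(shift):
        points = base.copy()
        points[10:] += shift
        return mp.avg_silhouette(euclidean_matrix(points), labels)[0]

    assert mean_width(8.0) > mean_width(3.0)


def test_silhouette_scan_flags_argmax():
    rng = np.random.default_rng(5)
    points = np.concatenate(
        [rng.normal(size=(10, 2)), rng.normal(size=(10, 2)) + 8,
         rng.normal(size=(10, 2)) + [8, -8]]
    )
    D = euclidean_matrix(points)
    tree = mp.ward_linkage(D)
    table = mp.silhouette_scan(D, tree, range(2, 7))
    assert int(table.loc[table["is_best"], "k"].iloc[0]) == 3
    single = mp.silhouette_scan(D, tree, [4])
    assert len(single) == 1 and bool(single["is_best"].iloc[0])


# ---------------------------------------------------------------------------
# classical MDS

def test_mds_recovers_collinear_points():
    D = euclidean_matrix(np.array([[0.0], [1.0], [2.0]]))
    emb = mp.classical_mds(D, dims=1)
    assert emb.variance_fraction[0] == pytest.approx(1.0)
    assert np.allclose(euclidean_matrix(emb.coordinates), D, atol=1e-8)


def test_mds_unit_square_symmetric_spectrum():
    corners = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    emb = mp.classical_mds(euclidean_matrix(corners), dims=2)
    assert emb.variance_fraction == pytest.approx([0.5, 0.5])


@pytest.mark.parametrize("seed", range(5))
def test_mds_reproduces_euclidean_distances(seed):
    rng = np.random.default_rng(seed)
    points = rng.normal(size=(12, 2))
    D = euclidean_matrix(points)
    emb = mp.classical_mds(D, dims=2)
    assert np.allclose(euclidean_matrix(emb.coordinates), D, atol=1e-8)
    assert np.all(np.diff(emb.eigenvalues) <= 1e-9)


def test_mds_warns_and_reduces_when_rank_deficient():
    D = euclidean_matrix(np.array([[0.0], [3.0]]))
    with pytest.warns(UserWarning, match="reducing"):
        emb = mp.classical_mds(D, dims=2)
    assert emb.coordinates.shape == (2, 1)


# ---------------------------------------------------------------------------
# estimator facades

def test_ward_estimator_facade(small_series):
    _, _, series = small_series
    dm = mp.distance_matrix(series)
    model = mp.WardClustering(n_clusters=3).fit(dm)
    assert sorted(np.unique(model.labels_)) == [0, 1, 2]
    assert model.get_params() == {"n_clusters": 3}
    assert np.array_equal(model.fit_predict(dm), model.labels_)


def test_mds_estimator_facade():
    rng = np.random.default_rng(6)
    D = euclidean_matrix(rng.normal(size=(8, 2)))
    est = mp.ClassicalMDS(n_components=2)
    coords = est.fit_transform(D)
    assert coords.shape == (8, 2)
    assert est.variance_fraction_.shape == (2,)
    assert est.get_params() == {"n_components": 2}
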