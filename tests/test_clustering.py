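"""Distances, linkage, validity indices and cluster-number selection."""

import math
import warnings

import numpy as np
import pytest

from bernet.clustering import (
    DISTANCES,
    LINKAGES,
    calinski_harabasz,
    cluster_with_local_ch,
    hierarchical_cluster,
    interior_ch_maxima,
    linkage_tree,
    mean_split_silhouette,
    model_selection,
    pairwise_distances,
)
from bernet.synth import generate_invariant_vectors


def scalar_distance(x, y, name, p=3.0):
    """Direct per-formula computation for the oracle comparison."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if name == "binary":
        nz = (x != 0) | (y != 0)
        if not nz.any():
            return 0.0
        return float(((x != 0) != (y != 0))[nz].mean())
    if name == "canberra":
        den = np.abs(x) + np.abs(y)
        terms = np.where(den > 0, np.abs(x - y) / np.where(den > 0, den, 1), 0.0)
        return float(terms.sum())
    if name == "euclidean":
        return float(np.sqrt(((x - y) ** 2).sum()))
    if name == "manhattan":
        return float(np.abs(x - y).sum())
    if name == "maximum":
        return float(np.abs(x - y).max())
    if name == "minkowski":
        return float((np.abs(x - y) ** p).sum() ** (1 / p))
    if name == "pearson_uncentered":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            return 0.0 if (x == y).all() else 1.0
        return float(1 - (x @ y) / (nx * ny))
    xc, yc = x - x.mean(), y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        return 0.0 if (x == y).all() else 1.0
    return float(1 - (xc @ yc) / (nx * ny))


class TestDistances:
    @pytest.mark.parametrize("name", DISTANCES)
    def test_matrix_matches_scalar_formula(self, name):
        rng = np.random.Generator(np.random.PCG64(7))
        X = rng.integers(0, 3, size=(10, 6)).astype(float)
        D = pairwise_distances(X, name)
        for i in range(10):
            for j in range(10):
                assert D[i, j] == pytest.approx(scalar_distance(X[i], X[j], name), abs=1e-10)

    @pytest.mark.parametrize("name", DISTANCES)
    def test_identical_vectors_at_distance_zero(self, name):
        X = np.array([[1, 2, 0], [1, 2, 0], [0, 1, 1]], dtype=float)
        D = pairwise_distances(X, name)
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)
        assert (D >= 0).all()

    def test_orthogonal_binary_supports(self):
        D = pairwise_distances(np.array([[1.0, 0.0], [0.0, 1.0]]), "binary")
        assert D[0, 1] == 1.0

    def test_constant_vector_convention_under_centered_pearson(self):
        X = np.array([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0], [1.0, 0.0, 3.0]])
        D = pairwise_distances(X, "pearson_centered")
        assert D[0, 1] == 0.0
        assert D[0, 2] == 1.0


class TestLinkage:
    def test_upgma_merge_heights_match_hand_computation(self):
        # 1-d points 0, 1, 5, 7: merges (0,1)@1, (5,7)@2, then average
        # distance between {0,1} and {5,7} = (5+7+4+6)/4 = 5.5
        X = np.array([[0.0], [1.0], [5.0], [7.0]])
        D = pairwise_distances(X, "euclidean")
        tree = linkage_tree(D, "upgma")
        assert tree.heights == pytest.approx([1.0, 2.0, 5.5])

    def test_single_vs_complete_on_elongated_pairs(self):
        X = np.array([[0.0], [1.0], [2.9], [4.0]])
        D = pairwise_distances(X, "euclidean")
        assert linkage_tree(D, "single").heights[-1] == pytest.approx(1.9)
        assert linkage_tree(D, "complete").heights[-1] == pytest.approx(4.0)

    @pytest.mark.parametrize("link", LINKAGES)
    def test_two_blobs_recovered_by_every_linkage(self, link):
        rng = np.random.Generator(np.random.PCG64(0))
        X = np.vstack([rng.normal(0, 0.1, (8, 3)), rng.normal(5, 0.1, (8, 3))])
        D = pairwise_distances(X, "euclidean")
        res = hierarchical_cluster(D, link, 2)
        labels = res.labels
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1
        assert labels[0] != labels[-1]

    @pytest.mark.parametrize("link", ["upgma", "complete", "single", "ward"])
    def test_cuts_are_nested(self, link):
        """Cut at k and k+1 differ by splitting exactly one cluster."""
        rng = np.random.Generator(np.random.PCG64(1))
        X = rng.normal(0, 1, (20, 4))
        D = pairwise_distances(X, "manhattan")
        tree = linkage_tree(D, link)
        for k in range(2, 10):
            coarse = {frozenset(np.flatnonzero(tree.cut(k) == c)) for c in range(k)}
            fine = {frozenset(np.flatnonzero(tree.cut(k + 1) == c)) for c in range(k + 1)}
            split = coarse - fine
            halves = fine - coarse
            assert len(split) == 1 and len(halves) == 2
            assert set().union(*halves) == next(iter(split))

    def test_k_out_of_range_rejected(self):
        D = pairwise_distances(np.eye(4), "euclidean")
        with pytest.raises(ValueError):
            hierarchical_cluster(D, "upgma", 5)


class TestIndices:
    def test_ch_matches_hand_computation(self):
        # clusters {0,2} and {10,14} in 1-d: centroids 1 and 12, grand 6.5
        X = np.array([[0.0], [2.0], [10.0], [14.0]])
        labels = [0, 0, 1, 1]
        B = 2 * (1 - 6.5) ** 2 + 2 * (12 - 6.5) ** 2
        W = 1 + 1 + 4 + 4
        expected = (B / 1) / (W / 2)
        assert calinski_harabasz(X, labels) == pytest.approx(expected)

    def test_ch_infinite_for_zero_within_variance(self):
        X = np.array([[0.0], [0.0], [5.0]])
        assert math.isinf(calinski_harabasz(X, [0, 0, 1]))

    def test_ch_much_larger_at_true_k_for_two_blobs(self):
        rng = np.random.Generator(np.random.PCG64(2))
        X = np.vstack([rng.normal(0, 1.0, (10, 2)), rng.normal(20, 1.0, (10, 2))])
        D = pairwise_distances(X, "euclidean")
        tree = linkage_tree(D, "upgma")
        ch2 = calinski_harabasz(X, tree.cut(2))
        assert all(ch2 > calinski_harabasz(X, tree.cut(k)) for k in (3, 4, 5))

    def test_indices_invariant_to_label_permutation(self):
        rng = np.random.Generator(np.random.PCG64(3))
        X = rng.normal(0, 1, (12, 3))
        D = pairwise_distances(X, "euclidean")
        labels = np.array([0, 1, 2] * 4)
        permuted = (labels + 1) % 3
        assert calinski_harabasz(X, labels) == pytest.approx(
            calinski_harabasz(X, permuted)
        )
        assert mean_split_silhouette(D, labels, "upgma") == pytest.approx(
            mean_split_silhouette(D, permuted, "upgma")
        )

    def test_mss_flags_undersplit_cluster(self):
        """A cluster made of two tight sub-blobs has split silhouette near 1,
        well above that of a homogeneous cluster."""
        rng = np.random.Generator(np.random.PCG64(4))
        two_blobs = np.vstack([rng.normal(0, 0.01, (5, 2)), rng.normal(8, 0.01, (5, 2))])
        homogeneous = rng.normal(0, 1.0, (10, 2))
        X = np.vstack([two_blobs, homogeneous])
        D = pairwise_distances(X, "euclidean")
        labels = np.array([0] * 10 + [1] * 10)
        mixed = mean_split_silhouette(D, labels, "upgma")
        pure = mean_split_silhouette(
            D, np.array([0] * 5 + [1] * 5 + [2] * 10), "upgma"
        )
        assert mixed > pure

    def test_mss_neutral_for_singletons_only(self):
        D = pairwise_distances(np.eye(3), "euclidean")
        with pytest.warns(UserWarning, match="size < 3"):
            assert mean_split_silhouette(D, [0, 1, 2], "upgma") == 1.0


class TestSelection:
    def test_planted_four_clusters_recovered(self):
        X, labels = generate_invariant_vectors(4, 6, 24, noise=0.02, seed=5)
        best, table = model_selection(
            X, k_range=range(2, 9), distances=("binary", "euclidean"),
            linkages=("upgma", "complete", "ward"),
        )
        assert best.k == 4
        # recovered partition matches the planted labels up to renaming
        mapping = {}
        for lab, truth in zip(best.labels, labels):
            mapping.setdefault(lab, truth)
            assert mapping[lab] == truth

    def test_selection_invariant_to_vector_order(self):
        X, _ = generate_invariant_vectors(3, 5, 18, noise=0.0, seed=6)
        perm = np.random.Generator(np.random.PCG64(7)).permutation(len(X))
        b1, _ = model_selection(X, k_range=range(2, 7),
                                distances=("euclidean",), linkages=("upgma",))
        b2, _ = model_selection(X[perm], k_range=range(2, 7),
                                distances=("euclidean",), linkages=("upgma",))
        assert b1.k == b2.k

    def test_interior_maxima_extraction(self):
        curve = {2: 10.0, 3: 4.0, 4: 6.0, 5: 3.0, 6: 2.0}
        assert interior_ch_maxima(curve) == [4]

    def test_local_ch_protocol_on_planted_vectors(self):
        X, _ = generate_invariant_vectors(5, 8, 40, noise=0.0, seed=8)
        res = cluster_with_local_ch(X, distance="euclidean", linkage="upgma",
                                    binary=False, k_range=range(2, 12))
        assert res.k == 5
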