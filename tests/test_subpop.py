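"""Partitive clustering, cluster-number selection, ordering, composition."""

import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from scqpcr.subpop import (
    composition,
    hierarchical_order,
    kmeans_partition,
    select_k,
)


def _blobs(rng, centers, n_per, sd=0.5):
    X = np.vstack([rng.normal(c, sd, size=(n, len(c))) for c, n in zip(centers, n_per)])
    truth = np.repeat(np.arange(len(centers)), n_per)
    return X, truth


class TestKmeansPartition:
    def test_k1_is_total_sum_of_squares(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        res = kmeans_partition(X, k=1, seed=0, n_restarts=5)
        assert np.all(res.labels == 1)
        tss = ((X - X.mean(axis=0)) ** 2).sum()
        assert res.wcss == pytest.approx(tss)

    def test_two_well_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(1)
        X, truth = _blobs(rng, [np.zeros(5), np.full(5, 8.0)], [40, 20], sd=0.5)
        res = kmeans_partition(X, k=2, seed=3, n_restarts=10)
        assert adjusted_rand_score(truth, res.labels) == 1.0
        # labels ordered by size: the 40-cell blob is cluster 1
        assert (res.labels[:40] == 1).all() and (res.labels[40:] == 2).all()

    def test_determinism(self, study_matrix):
        a = kmeans_partition(study_matrix, k=3, seed=11, n_restarts=10)
        b = kmeans_partition(study_matrix, k=3, seed=11, n_restarts=10)
        assert np.array_equal(a.labels, b.labels)
        assert a.wcss == b.wcss

    def test_wcss_trace_non_increasing(self, study_matrix):
        res = kmeans_partition(study_matrix, k=3, seed=5, n_restarts=10)
        trace = np.array(res.wcss_trace)
        assert np.all(np.diff(trace) <= 1e-7)
        assert res.wcss == trace[-1]

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(4)
        X, _ = _blobs(rng, [np.zeros(3), np.full(3, 9.0), np.full(3, -9.0)], [30, 20, 10])
        res = kmeans_partition(X, k=3, seed=7, n_restarts=10)
        perm = rng.permutation(len(X))
        res_p = kmeans_partition(X[perm], k=3, seed=7, n_restarts=10)
        # cluster sizes differ, so size-ordered labels must transport exactly
        assert np.array_equal(res_p.labels, res.labels[perm])

    def test_parameter_errors(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            kmeans_partition(X, k=6, seed=0)
        with pytest.raises(ValueError):
            kmeans_partition(X, k=0, seed=0)

    def test_wcss_matches_sklearn(self):
        """Independent check: restarted Lloyd reaches sklearn's optimum."""
        rng = np.random.default_rng(8)
        X, _ = _blobs(rng, [np.zeros(4), np.full(4, 6.0), np.full(4, -6.0)], [25, 25, 25])
        ours = kmeans_partition(X, k=3, seed=0, n_restarts=20)
        sk = KMeans(n_clusters=3, n_init=20, random_state=0).fit(X)
        assert ours.wcss == pytest.approx(sk.inertia_, rel=1e-6)


class TestSelectK:
    def test_single_blob_gives_k1(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0.0, 0.5, size=(100, 10))
        assert select_k(X, k_max=5, seed=0).chosen_k == 1

    def test_three_blobs_give_k3(self):
        rng = np.random.default_rng(3)
        centers = [np.zeros(10), np.full(10, 8.0), np.r_[np.full(5, 8.0), np.full(5, -8.0)]]
        X, _ = _blobs(rng, centers, [40, 30, 30], sd=0.5)
        assert select_k(X, k_max=6, seed=0).chosen_k == 3

    def test_kmax_one_forced(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        sel = select_k(X, k_max=1, seed=0)
        assert sel.chosen_k == 1 and sel.candidate_ks == [1]

    def test_parameter_error(self):
        with pytest.raises(ValueError):
            select_k(np.zeros((5, 2)), k_max=0, seed=0)


class TestHierarchicalOrder:
    def test_output_is_permutation(self, study_matrix):
        order = hierarchical_order(study_matrix, "cells")
        assert sorted(order) == list(range(study_matrix.n_cells))
        gorder = hierarchical_order(study_matrix, "genes")
        assert sorted(gorder) == list(range(study_matrix.n_genes))

    def test_identical_cells_adjacent(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 4))
        X[6] = X[2]  # duplicate cell
        order = list(hierarchical_order(X, "cells"))
        assert abs(order.index(2) - order.index(6)) == 1

    def test_three_points_on_line(self):
        # points at 0, 1, 10 on one gene: 0 and 1 must be leaf-adjacent
        X = np.array([[0.0], [1.0], [10.0]])
        order = list(hierarchical_order(X, "cells"))
        assert abs(order.index(0) - order.index(1)) == 1

    def test_correlation_on_constant_profile_errors(self):
        X = np.vstack([np.ones(4), np.arange(4.0), np.arange(4.0) * 2])
        with pytest.raises(ValueError, match="euclidean"):
            hierarchical_order(X, "cells", metric="correlation")


class TestComposition:
    def test_counts_and_fractions(self):
        from scqpcr.subpop import ClusterResult

        labels = np.array([1] * 10 + [2] * 5)
        groups = np.array(["KO"] * 8 + ["WT"] * 2 + ["WT"] * 5)
        res = ClusterResult(
            labels=labels, k=2, centroids=np.zeros((2, 1)), seed=0, n_restarts=1, wcss=0.0
        )
        comp = composition(res, groups)
        assert comp.counts.to_numpy().sum() == 15
        assert comp.cluster_fractions.loc[1, "KO"] == pytest.approx(0.80)
        assert comp.cluster_fractions.loc[2, "WT"] == 1.0
        assert np.allclose(comp.cluster_fractions.sum(axis=1), 1.0)
        assert np.allclose(comp.group_fractions.sum(axis=0), 1.0)

    def test_alignment_error(self):
        from scqpcr.subpop import ClusterResult

        res = ClusterResult(
            labels=np.array([1, 1, 2]), k=2, centroids=np.zeros((2, 1)),
            seed=0, n_restarts=1, wcss=0.0,
        )
        with pytest.raises(ValueError, match="aligned"):
            composition(res, ["WT", "KO"])
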