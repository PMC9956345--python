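"""UMAP projection, HDBSCAN, DBCV, grid search and cluster gene sets."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from oracles import brute_force_dbcv
from variclust.cluster import (
    ClusterLabels,
    ClusterParams,
    ReductionParams,
    cluster_gene_sets,
    coverage,
    grid_search,
    hdbscan_cluster,
    umap_project,
)
from variclust.dbcv import UndefinedDBCVError, dbcv, dbcv_or_none
from variclust.variant_io import IndividualGeneSet


def _blobs(n_per=60, centers=((0, 0), (10, 0), (0, 10)), spread=0.3, seed=0, dim=None):
    rng = np.random.default_rng(seed)
    pts, lab = [], []
    for c, center in enumerate(centers):
        center = np.asarray(center, dtype=float)
        if dim is not None:
            center = np.concatenate([center, np.zeros(dim - len(center))])
        pts.append(center + rng.normal(0, spread, size=(n_per, len(center))))
        lab += [c] * n_per
    return np.vstack(pts), np.array(lab)


class TestUmapProject:
    def test_output_shape(self):
        rng = np.random.default_rng(0)
        latent = rng.normal(size=(100, 64))
        out = umap_project(latent, ReductionParams(seed=1))
        assert out.shape == (100, 5)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        latent = rng.normal(size=(60, 16))
        p = ReductionParams(seed=7, n_neighbors=10, n_components=3)
        np.testing.assert_array_equal(umap_project(latent, p), umap_project(latent, p))

    def test_blob_identity_survives_projection(self):
        pts, truth = _blobs(n_per=40, spread=0.05, dim=16, seed=2)
        proj = umap_project(pts, ReductionParams(seed=3, n_neighbors=10,
                                                 n_components=3, metric="euclidean"))
        centroids = np.stack([proj[truth == c].mean(axis=0) for c in range(3)])
        assigned = np.argmin(
            np.linalg.norm(proj[:, None, :] - centroids[None], axis=2), axis=1
        )
        assert adjusted_rand_score(truth, assigned) == 1.0

    def test_too_few_samples_fatal(self):
        with pytest.raises(ValueError, match="n_neighbors"):
            umap_project(np.zeros((10, 8)), ReductionParams(seed=0, n_neighbors=15))


class TestCoverage:
    def test_no_noise_is_one(self):
        assert coverage(ClusterLabels(np.array([0, 1, 0, 2]))) == 1.0

    def test_all_noise_is_zero(self):
        assert coverage(ClusterLabels(np.array([-1, -1]))) == 0.0

    def test_one_in_four(self):
        assert coverage(ClusterLabels(np.array([0, -1, -1, -1]))) == 0.25


class TestDBCV:
    def test_well_separated_clusters_score_high(self):
        pts, lab = _blobs(n_per=20, centers=((0, 0), (10, 10)), spread=0.1, seed=7)
        assert dbcv(pts, lab) > 0.9

    def test_split_gaussian_scores_nonpositive(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(40, 2))
        lab = (pts[:, 0] > 0).astype(int)
        assert dbcv(pts, lab) <= 0

    def test_label_permutation_invariance(self):
        pts, lab = _blobs(n_per=15, spread=0.2, seed=4)
        perm = np.array([2, 0, 1])
        assert dbcv(pts, lab) == pytest.approx(dbcv(pts, perm[lab]), abs=1e-12)

    def test_undefined_below_two_clusters(self):
        pts = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(UndefinedDBCVError):
            dbcv(pts, np.zeros(10, dtype=int))
        assert dbcv_or_none(pts, np.zeros(10, dtype=int)) is None

    def test_noise_dilutes_through_size_weighting(self):
        pts, lab = _blobs(n_per=20, centers=((0, 0), (10, 10)), spread=0.1, seed=9)
        noisy = np.vstack([pts, [[5.0, 5.0]] * 10])
        lab_noisy = np.concatenate([lab, [-1] * 10])
        assert dbcv(noisy, lab_noisy) == pytest.approx(dbcv(pts, lab) * 40 / 50)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(8, 61))
        d = int(rng.integers(1, 5))
        pts = rng.normal(size=(n, d))
        lab = rng.integers(-1, 4, size=n)
        if trial % 4 == 0 and n > 4:  # coincident points stress zero distances
            pts[1] = pts[0]
            lab[1] = lab[0]
        ours = dbcv_or_none(pts, lab)
        ref = brute_force_dbcv(pts, lab)
        if ref is None:
            assert ours is None
        else:
            assert ours == pytest.approx(ref, abs=1e-9)


class TestHDBSCAN:
    def test_planted_blobs_recovered(self):
        pts, truth = _blobs(n_per=60, spread=0.5, seed=5)  # 10-sigma separation
        labels = hdbscan_cluster(pts, ClusterParams(min_cluster_size=20, min_samples=5))
        assert labels.n_clusters == 3
        assert adjusted_rand_score(truth, labels.labels) == 1.0

    def test_min_cluster_size_above_n_gives_all_noise(self):
        pts = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.warns(UserWarning, match="noise"):
            labels = hdbscan_cluster(pts, ClusterParams(min_cluster_size=10, min_samples=2))
        assert (labels.labels == -1).all()

    def test_repeat_runs_identical(self):
        pts, _ = _blobs(seed=6)
        p = ClusterParams(min_cluster_size=15, min_samples=5, metric="manhattan")
        np.testing.assert_array_equal(
            hdbscan_cluster(pts, p).labels, hdbscan_cluster(pts, p).labels
        )


class TestGridSearch:
    def test_single_combination_wins(self):
        pts, _ = _blobs(n_per=30, seed=8)
        labels, table = grid_search(pts, min_cluster_size=[10], min_samples=[5],
                                    metric=["euclidean"])
        assert len(table) == 1
        assert table[0].params.min_cluster_size == 10

    def test_planted_blobs_winner_has_full_coverage_and_ari_one(self):
        pts, truth = _blobs(n_per=60, spread=0.3, seed=10)
        labels, table = grid_search(pts, min_cluster_size=[10, 20], min_samples=[5])
        assert coverage(labels) == 1.0
        assert adjusted_rand_score(truth, labels.labels) == 1.0

    def test_table_length_is_grid_product(self):
        pts, _ = _blobs(n_per=30, seed=11)
        _, table = grid_search(
            pts, min_cluster_size=[10, 15], min_samples=[3, 5],
            metric=["euclidean", "manhattan"], cluster_selection_method=["eom", "leaf"],
        )
        assert len(table) == 16

    def test_winner_maximises_dbcv(self):
        pts, _ = _blobs(n_per=40, seed=12)
        labels, table = grid_search(pts, min_cluster_size=[5, 10, 20], min_samples=[3, 5])
        best = max(r.dbcv for r in table if r.dbcv is not None)
        assert dbcv_or_none(pts, labels.labels) == pytest.approx(best)


class TestClusterGeneSets:
    def test_union_of_member_sets(self):
        labels = ClusterLabels(np.array([0, 0]))
        sets = [IndividualGeneSet("I1", frozenset({"A", "B"})),
                IndividualGeneSet("I2", frozenset({"B", "C"}))]
        census = cluster_gene_sets(labels, sets)
        assert census[0].genes == frozenset({"A", "B", "C"})
        assert census[0].n_members == 2

    def test_noise_genes_in_no_cluster(self):
        labels = ClusterLabels(np.array([0, -1, 0]))
        sets = [IndividualGeneSet("I1", frozenset({"A"})),
                IndividualGeneSet("I2", frozenset({"ZZZ"})),
                IndividualGeneSet("I3", frozenset({"B"}))]
        census = cluster_gene_sets(labels, sets)
        assert all("ZZZ" not in row.genes for row in census)

    def test_member_counts_sum_to_n_at_full_coverage(self):
        rng = np.random.default_rng(0)
        labels = ClusterLabels(rng.integers(0, 4, size=50))
        sets = [IndividualGeneSet(f"I{i}", frozenset({f"G{i}"})) for i in range(50)]
        census = cluster_gene_sets(labels, sets)
        assert sum(r.n_members for r in census) == 50

    def test_asd_intersection_column(self):
        labels = ClusterLabels(np.array([0]))
        sets = [IndividualGeneSet("I1", frozenset({"A", "B", "C"}))]
        census = cluster_gene_sets(labels, sets, asd_genes={"B", "C", "D"})
        assert census[0].n_asd_linked == 2
        assert census[0].asd_linked == frozenset({"B", "C"})

    def test_misaligned_inputs_fatal(self):
        with pytest.raises(ValueError, match="misaligned"):
            cluster_gene_sets(ClusterLabels(np.array([0, 1])), [])
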