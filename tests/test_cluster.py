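"""Primary tier: feature scaling, epsilon selection and DBSCAN itself."""

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from duobin.cluster import (
    DBSCANClusterer,
    dbscan,
    primary_bin,
    scale_features,
    select_epsilon,
)
from duobin.features import build_feature_table
from duobin.io import UNCLASSIFIED


def graph_oracle(points, eps, min_points):
    """Independent DBSCAN oracle: connected components of the eps-graph
    restricted to core points; returns (core partition as a set of
    frozensets, noise set)."""
    d = cdist(points, points)
    core = (d <= eps).sum(axis=1) >= min_points
    core_idx = np.flatnonzero(core)
    adj = (d[np.ix_(core_idx, core_idx)] <= eps).astype(int)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    partition = {
        frozenset(core_idx[comp == c].tolist()) for c in range(n_comp)
    }
    # noise: non-core with no core neighbour within eps
    noise = {
        int(i)
        for i in np.flatnonzero(~core)
        if not (core & (d[i] <= eps)).any()
    }
    return partition, noise


def core_partition(labels, core_indices):
    return {
        frozenset(np.flatnonzero(labels == c).tolist() ) & frozenset(core_indices.tolist())
        for c in set(labels[core_indices])
    }


class TestScaleFeatures:
    def test_binary_axis_maps_to_unit_zscores(self):
        pts = np.array([[0.0, 5.0], [1.0, 7.0]])
        scaled = scale_features(pts)
        np.testing.assert_allclose(scaled[:, 0], [-1.0, 1.0])
        np.testing.assert_allclose(scaled[:, 1], [-1.0, 1.0])

    def test_constant_axes_warn_and_zero(self):
        pts = np.array([[3.0, 3.0], [3.0, 3.0], [3.0, 3.0]])
        with pytest.warns(UserWarning):
            scaled = scale_features(pts)
        np.testing.assert_array_equal(scaled, np.zeros_like(pts))

    def test_affine_invariance(self, rng):
        pts = rng.normal(size=(30, 2))
        shifted = pts + np.array([100.0, -7.0])
        np.testing.assert_allclose(scale_features(pts), scale_features(shifted))

    def test_single_point_raises(self):
        with pytest.raises(ValueError):
            scale_features(np.array([[1.0, 2.0]]))


class TestSelectEpsilon:
    def test_user_override_returned_unchanged(self, rng):
        pts = rng.normal(size=(20, 2))
        assert select_epsilon(pts, 4, epsilon=0.5) == 0.5

    def test_duplicate_points_floor(self):
        pts = np.zeros((10, 2))
        assert select_epsilon(pts, 4) == pytest.approx(1e-6)

    def test_two_blob_fixture_resolves(self, two_blob_points):
        eps = select_epsilon(two_blob_points, 4)
        labels = dbscan(two_blob_points, eps=eps, min_points=4)
        assert len(set(labels) - {UNCLASSIFIED}) == 2
        assert (labels == UNCLASSIFIED).sum() == 3


class TestDBSCAN:
    def test_two_blobs_plus_singletons(self, two_blob_points):
        labels = dbscan(two_blob_points, eps=0.5, min_points=4)
        assert set(labels[:20]) == {labels[0]}
        assert set(labels[20:40]) == {labels[20]}
        assert labels[0] != labels[20]
        assert list(labels[40:]) == [UNCLASSIFIED] * 3

    def test_identical_points_one_cluster(self):
        labels = dbscan(np.zeros((6, 2)), eps=0.1, min_points=4)
        assert list(labels) == [0] * 6

    def test_scattered_points_all_noise(self):
        pts = np.arange(10, dtype=float)[:, None] * 100.0
        pts = np.hstack([pts, pts])
        labels = dbscan(pts, eps=1.0, min_points=2)
        assert list(labels) == [UNCLASSIFIED] * 10

    def test_labels_contiguous_from_zero(self, rng):
        pts = rng.uniform(size=(100, 2))
        labels = dbscan(pts, eps=0.08, min_points=4)
        found = sorted(set(labels) - {UNCLASSIFIED})
        assert found == list(range(len(found)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_graph_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(size=(150, 2))
        eps = float(rng.uniform(0.04, 0.12))
        mp = int(rng.integers(3, 7))
        model = DBSCANClusterer(eps=eps, min_points=mp).fit(pts)
        oracle_partition, oracle_noise = graph_oracle(pts, eps, mp)
        got = core_partition(model.labels_, model.core_sample_indices_)
        assert got == oracle_partition
        got_noise = {
            int(i)
            for i in np.flatnonzero(model.labels_ == UNCLASSIFIED)
        }
        assert got_noise == oracle_noise

    @pytest.mark.parametrize("seed", range(3))
    def test_core_partition_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(size=(80, 2))
        eps, mp = 0.1, 4
        perm = rng.permutation(len(pts))
        a = DBSCANClusterer(eps=eps, min_points=mp).fit(pts)
        b = DBSCANClusterer(eps=eps, min_points=mp).fit(pts[perm])
        part_a = core_partition(a.labels_, a.core_sample_indices_)
        # map permuted indices back to original ids
        part_b = {
            frozenset(int(perm[i]) for i in grp)
            for grp in core_partition(b.labels_, b.core_sample_indices_)
        }
        assert part_a == part_b


class TestPrimaryBin:
    def test_three_species_community(self, three_species_community):
        com = three_species_community
        feats = build_feature_table(com.contigs, com.coverage)
        labels = primary_bin(feats)
        assert labels.index.equals(feats.index)
        clustered = labels[labels != UNCLASSIFIED]
        assert clustered.nunique() >= 3
        # each bin >= 95% pure against ground truth
        for b, ids in clustered.groupby(clustered).groups.items():
            genomes = [com.truth[i] for i in ids]
            top = max(genomes.count(g) for g in set(genomes))
            assert top / len(genomes) >= 0.95

    def test_every_contig_labelled_once(self, three_species_community):
        com = three_species_community
        feats = build_feature_table(com.contigs, com.coverage)
        labels = primary_bin(feats)
        assert len(labels) == len(feats)
        found = sorted(set(labels) - {UNCLASSIFIED})
        assert found == list(range(len(found)))
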