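"""Cluster-network matching, overlap/consistency ratios, distances, profiles."""

from fractions import Fraction
from itertools import permutations

import numpy as np
import pytest

from fcnets import (ConfusionTable, RoiTemplate, adjacency_distance,
                    build_adjacency, centroid_distance_profile, confusion_table,
                    consistency_ratio, datasets, kmeans_cluster, match_clusters,
                    overlap_ratio, percent)

from oracles import confusion_oracle, squared_distance_oracle


@pytest.fixture(scope="module")
def static_table():
    return datasets.load_reference_confusion("static")


@pytest.fixture(scope="module")
def sampen_table():
    return datasets.load_reference_confusion("sampen")


class TestTemplateAndConfusion:
    def test_packaged_template_has_the_six_network_sizes(self):
        t = datasets.dosenbach_template()
        assert t.n_rois == 160
        assert t.network_sizes == dict(zip(datasets.NETWORK_NAMES,
                                           (34, 21, 32, 33, 22, 18)))

    def test_clusters_identical_to_networks_give_diagonal_table(self):
        t = datasets.dosenbach_template()
        table = confusion_table(t.labels_as_int(), t)
        np.testing.assert_array_equal(table.counts,
                                      np.diag([34, 21, 32, 33, 22, 18]))

    def test_single_cluster_column_equals_network_sizes(self):
        t = datasets.dosenbach_template()
        table = confusion_table(np.zeros(160, dtype=int), t)
        np.testing.assert_array_equal(table.counts.ravel(),
                                      [34, 21, 32, 33, 22, 18])

    def test_matches_counting_oracle(self, rng):
        t = datasets.dosenbach_template()
        labels = rng.integers(0, 6, size=160)
        table = confusion_table(labels, t)
        expected = confusion_oracle(labels, t.labels_as_int(), 6, 6)
        np.testing.assert_array_equal(table.counts, expected)
        assert table.counts.sum() == 160

    def test_roi_count_mismatch_errors(self):
        with pytest.raises(ValueError, match="labels"):
            confusion_table([0, 1], datasets.dosenbach_template())


class TestMatching:
    def test_reference_tables_match_identically(self, static_table, sampen_table):
        for table in (static_table, sampen_table):
            assert match_clusters(table) == {c: c for c in range(6)}

    def test_identity_diagonal_table(self):
        table = ConfusionTable(np.diag([3, 2, 1]), ("a", "b", "c"), ("1", "2", "3"))
        assert match_clusters(table) == {0: 0, 1: 1, 2: 2}

    def test_greedy_conflict_resolved_optimally(self):
        # clusters 0 and 1 share argmax network 0; enumerate all 6 bijections
        counts = np.array([[5, 4, 0], [3, 3, 1], [0, 1, 2]])
        table = ConfusionTable(counts, ("a", "b", "c"), ("1", "2", "3"))
        best = max(permutations(range(3)),
                   key=lambda p: sum(counts[p[c], c] for c in range(3)))
        assert match_clusters(table) == {c: best[c] for c in range(3)}

    def test_non_square_table_rejected(self):
        table = ConfusionTable(np.ones((2, 3), dtype=int), ("a", "b"),
                               ("1", "2", "3"))
        with pytest.raises(ValueError, match="square"):
            match_clusters(table)


class TestRatios:
    def test_reference_overlap_fractions_and_percentages(self, static_table,
                                                         sampen_table):
        mapping = {c: c for c in range(6)}
        static = overlap_ratio(static_table, mapping)
        assert static[0] == Fraction(25, 26)
        assert [percent(f) for f in static] == [96.15, 68.97, 91.30, 91.43,
                                                73.33, 82.35]
        dyn = overlap_ratio(sampen_table, mapping)
        assert dyn[3] == Fraction(30, 33)
        assert [percent(f) for f in dyn] == [96.67, 86.96, 85.19, 90.91,
                                             81.48, 90.00]

    def test_reference_consistency_fractions_and_percentages(self, static_table,
                                                             sampen_table):
        mapping = {c: c for c in range(6)}
        static = consistency_ratio(static_table, mapping)
        assert static[0] == Fraction(25, 25 + 9 + 1)
        assert static[3] == Fraction(32, 32 + 1 + 3)
        assert [percent(f) for f in static] == [71.43, 66.67, 61.76, 88.89,
                                                73.33, 66.67]
        dyn = consistency_ratio(sampen_table, mapping)
        assert dyn[2] == Fraction(23, 23 + 9 + 4)
        assert [percent(f) for f in dyn] == [82.86, 83.33, 63.89, 83.33,
                                             81.48, 90.00]

    def test_perfect_partition_gives_all_ones(self):
        table = ConfusionTable(np.diag([4, 3, 2]), ("a", "b", "c"), ("1", "2", "3"))
        mapping = match_clusters(table)
        assert overlap_ratio(table, mapping) == [1, 1, 1]
        assert consistency_ratio(table, mapping) == [1, 1, 1]

    def test_consistency_never_exceeds_overlap(self, static_table, sampen_table, rng):
        """Jaccard <= precision, on the reference tables and random ones."""
        tables = [static_table, sampen_table]
        t = datasets.dosenbach_template()
        for seed in range(5):
            labels = np.random.default_rng(seed).integers(0, 6, size=160)
            tables.append(confusion_table(labels, t))
        for table in tables:
            if np.any(table.cluster_sizes == 0):
                continue
            mapping = match_clusters(table)
            for o, c in zip(overlap_ratio(table, mapping),
                            consistency_ratio(table, mapping)):
                assert c <= o


class TestDistancesAndProfiles:
    def test_identical_matrices_distance_zero(self):
        a = build_adjacency([0, 0, 1, 1])
        assert adjacency_distance(a, a) == 0.0

    def test_binary_difference_reduces_to_hamming(self):
        a = build_adjacency([0, 0, 1, 1])
        b = build_adjacency([0, 0, 0, 1])
        differing = int((a != b).sum())
        assert adjacency_distance(a, b) == differing

    def test_matches_double_loop_summation_oracle(self, rng):
        a = rng.random((40, 40))
        b = rng.random((40, 40))
        assert adjacency_distance(a, b) == pytest.approx(
            squared_distance_oracle(a, b), abs=1e-9)

    def test_profile_minimum_on_the_diagonal(self, rng):
        centers = rng.uniform(-5, 5, (3, 4))
        pts = np.vstack([c + 0.3 * rng.standard_normal((8, 4)) for c in centers])
        res = kmeans_cluster(pts, 3, n_restarts=20, seed=0)
        means, sds = centroid_distance_profile(pts, res)
        assert means.shape == sds.shape == (3, 3)
        for j in range(3):
            assert means[:, j].argmin() == j

    def test_profile_matches_direct_summation(self, rng):
        pts = rng.standard_normal((12, 3))
        res = kmeans_cluster(pts, 2, n_restarts=10, seed=1)
        means, _ = centroid_distance_profile(pts, res)
        for i in range(2):
            for j in range(2):
                rows = pts[res.labels == j]
                d2 = [sum((r - res.centroids[i]) ** 2) for r in rows]
                assert means[i, j] == pytest.approx(np.mean(d2), abs=1e-9)

    def test_single_cluster_profile_is_grand_mean_distance(self, rng):
        pts = rng.standard_normal((10, 2))
        res = kmeans_cluster(pts, 1, n_restarts=1, seed=0)
        means, _ = centroid_distance_profile(pts, res)
        expected = ((pts - pts.mean(axis=0)) ** 2).sum(axis=1).mean()
        assert means[0, 0] == pytest.approx(expected, abs=1e-9)
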