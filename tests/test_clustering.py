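"""Ward.D2 dendrograms, static/dynamic cuts, cluster naming and classical MDS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from gomine.clustering import (
    cluster_set_matrix,
    cut_dynamic,
    cut_static,
    hclust_ward2,
    mds_classical,
    name_cluster,
    name_clusters,
)
from gomine.semsim import pairwise_measure, termset_sim

from conftest import A, B, C, D, build_dag


def ward_d2_oracle_heights(d: np.ndarray) -> list[float]:
    """Greedy Lance-Williams agglomeration on squared distances; sqrt heights.

    alpha_i = (n_i + n_k) / (n_i + n_j + n_k), beta = -n_k / (n_i + n_j + n_k).
    """
    d2 = d.astype(float) ** 2
    active = list(range(len(d)))
    sizes = {i: 1 for i in active}
    d2 = {(i, j): d2[i, j] for i in active for j in active if i < j}
    heights = []
    next_id = len(active)
    while len(active) > 1:
        (i, j) = min(d2, key=lambda k: (d2[k], k))
        heights.append(np.sqrt(d2[(i, j)]))
        ni, nj = sizes[i], sizes[j]
        merged = {}
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = d2[tuple(sorted((i, k)))]
            djk = d2[tuple(sorted((j, k)))]
            merged[k] = ((ni + nk) * dik + (nj + nk) * djk - nk * d2[(i, j)]) / (ni + nj + nk)
        active = [k for k in active if k not in (i, j)]
        d2 = {k: v for k, v in d2.items() if i not in k and j not in k}
        for k, v in merged.items():
            d2[tuple(sorted((k, next_id)))] = v
        sizes[next_id] = ni + nj
        active.append(next_id)
        next_id += 1
    return heights


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), n=st.integers(3, 8))
def test_ward_heights_match_oracle_property(seed, n):
    """Ward.D2 merge heights equal the greedy Lance-Williams recurrence."""
    rng = np.random.default_rng(seed)
    d = squareform(pdist(rng.random((n, 3))))
    tree = hclust_ward2(d)
    assert np.allclose(tree.heights, ward_d2_oracle_heights(d), atol=1e-9)


def line_distance(coords):
    return squareform(pdist(np.asarray(coords, dtype=float)[:, None]))


@pytest.fixture
def two_blob():
    """Two tight blobs far apart on a line."""
    coords = [0.0, 0.1, 0.2, 10.0, 10.1, 10.2]
    ids = [f"p{i}" for i in range(6)]
    return line_distance(coords), ids


class TestWardD2:
    def test_two_leaves_merge_at_their_distance(self):
        d = np.array([[0.0, 0.7], [0.7, 0.0]])
        tree = hclust_ward2(d, ids=["x", "y"])
        assert tree.heights[0] == pytest.approx(0.7)

    def test_heights_match_lance_williams_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            d = squareform(pdist(rng.random((n, 3))))
            tree = hclust_ward2(d)
            assert np.allclose(tree.heights, ward_d2_oracle_heights(d), atol=1e-9)

    def test_blobs_merge_internally_first(self, two_blob):
        d, ids = two_blob
        tree = hclust_ward2(d, ids=ids)
        # last merge joins the blobs, all earlier merges are tiny
        assert tree.heights[-1] > 10
        assert np.all(tree.heights[:-1] < 1)

    def test_deterministic_on_equidistant_points(self):
        d = np.ones((3, 3)) - np.eye(3)
        t1, t2 = hclust_ward2(d), hclust_ward2(d)
        assert np.array_equal(t1.merges, t2.merges)

    def test_heights_monotone_and_sizes_telescope(self, two_blob):
        d, ids = two_blob
        tree = hclust_ward2(d, ids=ids)
        assert np.all(np.diff(tree.heights) >= -1e-12)
        assert tree.merges[-1, 3] == len(ids)

    def test_rejects_asymmetric_input(self):
        with pytest.raises(ValueError, match="symmetric"):
            hclust_ward2(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_newick_round_trips_through_dendropy(self, two_blob):
        import dendropy

        d, ids = two_blob
        tree = hclust_ward2(d, ids=ids)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set(ids)


class TestCutStatic:
    def test_k_equals_n_gives_singletons(self, two_blob):
        d, ids = two_blob
        labels = cut_static(hclust_ward2(d, ids=ids), k=len(ids)).labels
        assert sorted(labels.values()) == list(range(1, len(ids) + 1))

    def test_k_one_single_cluster(self, two_blob):
        d, ids = two_blob
        labels = cut_static(hclust_ward2(d, ids=ids), k=1).labels
        assert set(labels.values()) == {1}

    def test_two_blobs_recovered(self, two_blob):
        d, ids = two_blob
        assignment = cut_static(hclust_ward2(d, ids=ids), k=2)
        groups = assignment.members()
        assert sorted(map(sorted, groups.values())) == [["p0", "p1", "p2"], ["p3", "p4", "p5"]]

    def test_exactly_one_of_k_h(self, two_blob):
        d, ids = two_blob
        tree = hclust_ward2(d, ids=ids)
        with pytest.raises(ValueError):
            cut_static(tree)
        with pytest.raises(ValueError):
            cut_static(tree, k=2, h=0.5)

    def test_labels_numbered_by_leaf_order(self, two_blob):
        d, ids = two_blob
        tree = hclust_ward2(d, ids=ids)
        assignment = cut_static(tree, k=2)
        first_leaf = tree.leaf_order()[0]
        assert assignment.labels[first_leaf] == 1


class TestCutDynamic:
    def test_two_blobs_no_unassigned(self, two_blob):
        d, ids = two_blob
        assignment = cut_dynamic(hclust_ward2(d, ids=ids), min_cluster_size=2)
        assert assignment.n_clusters == 2
        assert 0 not in assignment.labels.values()
        groups = assignment.members()
        assert sorted(map(sorted, groups.values())) == [["p0", "p1", "p2"], ["p3", "p4", "p5"]]

    def test_equidistant_leaves_single_cluster(self):
        d = np.ones((5, 5)) - np.eye(5)
        assignment = cut_dynamic(hclust_ward2(d), min_cluster_size=2)
        assert set(assignment.labels.values()) == {1}

    def test_min_size_above_n_all_unassigned(self, two_blob):
        d, ids = two_blob
        assignment = cut_dynamic(hclust_ward2(d, ids=ids), min_cluster_size=len(ids) + 1)
        assert set(assignment.labels.values()) == {0}

    def test_undersized_side_branch_unassigned(self):
        # one outlier against a tight blob of 5: blob clusters, outlier gets 0
        d = line_distance([0.0, 0.1, 0.2, 0.3, 0.4, 50.0])
        assignment = cut_dynamic(hclust_ward2(d), min_cluster_size=3)
        labels = list(assignment.labels.values())
        assert labels.count(0) == 1
        assert assignment.n_clusters == 1

    def test_clusters_respect_min_size(self, two_blob):
        d, ids = two_blob
        for min_size in (2, 3):
            assignment = cut_dynamic(hclust_ward2(d, ids=ids), min_cluster_size=min_size)
            assert all(len(m) >= min_size for m in assignment.members().values())

    def test_invalid_parameters(self, two_blob):
        d, ids = two_blob
        tree = hclust_ward2(d, ids=ids)
        with pytest.raises(ValueError):
            cut_dynamic(tree, min_cluster_size=0)
        with pytest.raises(ValueError):
            cut_dynamic(tree, deep_split=7)

    def test_deterministic(self, two_blob):
        d, ids = two_blob
        tree = hclust_ward2(d, ids=ids)
        assert cut_dynamic(tree).labels == cut_dynamic(tree).labels


class TestNameCluster:
    def test_singleton_names_itself(self, chain_dag):
        assert name_cluster(chain_dag, None, [A]) == A

    def test_siblings_named_by_parent(self, diamond_dag):
        assert name_cluster(diamond_dag, None, [B, C]) == D

    def test_mixed_depth_in_diamond(self, diamond_dag):
        # common ancestors of {A, B} are {B, D}; deepest is B
        assert name_cluster(diamond_dag, None, [A, B]) == B

    def test_name_is_ancestor_or_self_of_every_member(self, diamond_dag):
        for members in ([A], [A, B], [B, C], [A, B, C, D]):
            name = name_cluster(diamond_dag, None, members)
            for m in members:
                assert name == m or name in diamond_dag.ancestors(m)


class TestClusterSetMatrix:
    def _assignment(self, labels):
        from gomine.clustering import ClusterAssignment

        return ClusterAssignment(labels=labels, mode="static")

    def test_duplicate_clusters_similarity_one(self, diamond_dag):
        from gomine.semsim import similarity_matrix

        measure = pairwise_measure("wang", diamond_dag)
        mat = similarity_matrix({"1": [A, B], "2": [A, B]}, measure, "wang", combine="BMA")
        assert mat.values[0, 1] == pytest.approx(1.0)

    def test_single_cluster_errors(self, diamond_dag):
        measure = pairwise_measure("wang", diamond_dag)
        with pytest.raises(ValueError):
            cluster_set_matrix(self._assignment({A: 1, B: 1}), measure, "wang")

    def test_singleton_clusters_reduce_to_pairwise(self, diamond_dag):
        measure = pairwise_measure("wang", diamond_dag)
        assignment = self._assignment({A: 1, D: 2})
        mat = cluster_set_matrix(assignment, measure, "wang")
        assert mat.values[0, 1] == pytest.approx(measure(A, D))

    def test_matches_termset_oracle(self, diamond_dag):
        measure = pairwise_measure("wang", diamond_dag)
        assignment = self._assignment({A: 1, B: 1, C: 2, D: 2})
        mat = cluster_set_matrix(assignment, measure, "wang", combine="BMA")
        expected = termset_sim([A, B], [C, D], measure, "BMA")
        assert mat.values[mat.ids.index("1"), mat.ids.index("2")] == pytest.approx(expected)

    def test_unassigned_leaves_excluded(self, diamond_dag):
        measure = pairwise_measure("wang", diamond_dag)
        assignment = self._assignment({A: 1, B: 2, C: 0, D: 2})
        mat = cluster_set_matrix(assignment, measure, "wang")
        assert mat.ids == ["1", "2"]


class TestClassicalMds:
    def test_two_points(self):
        coords, distortion = mds_classical(np.array([[0.0, 2.0], [2.0, 0.0]]), dims=1)
        assert sorted(coords[:, 0]) == pytest.approx([-1.0, 1.0])
        assert distortion == pytest.approx(0.0, abs=1e-12)

    def test_three_equidistant_points(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords, _ = mds_classical(d, dims=2)
        embedded = squareform(pdist(coords))
        assert np.allclose(embedded[~np.eye(3, dtype=bool)], 1.0, atol=1e-9)

    def test_planar_configuration_recovered(self):
        rng = np.random.default_rng(3)
        points = rng.random((4, 2))
        d = squareform(pdist(points))
        coords, distortion = mds_classical(d, dims=2)
        assert np.allclose(squareform(pdist(coords)), d, atol=1e-9)
        assert distortion == pytest.approx(0.0, abs=1e-9)

    def test_procrustes_alignment_to_original(self):
        rng = np.random.default_rng(8)
        points = rng.random((6, 2))
        coords, _ = mds_classical(squareform(pdist(points)), dims=2)
        from scipy.spatial import procrustes

        _m1, _m2, disparity = procrustes(points, coords)
        assert disparity < 1e-6
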