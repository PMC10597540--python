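import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from episub import DistanceSpec, LinkageSpec, agglomerate, compute_distance, cut_dendrogram
from episub.hierarchy import LINKAGES, METRICS

from conftest import make_matrix
from oracles import naive_linkage

# hclust reference for the 6 points below (euclidean distances):
# merge heights frozen from an independent R run of ward.D / ward.D2 / complete.
R_POINTS = np.array(
    [[0.0, 1.0], [0.9, 0.2], [2.1, 1.8], [5.0, 4.8], [5.2, 6.0], [9.9, 9.0]]
)
R_HEIGHTS = {
    "ward_d": [1.20415945788, 1.21655250606, 2.43009385099, 7.61416374057, 17.83400524070],
    "ward_d2": [1.20415945788, 1.21655250606, 2.35584379788, 6.92820323028, 13.84015895862],
    "complete": [1.20415945788, 1.21655250606, 2.24722050542, 6.45368112011, 12.72831489240],
}
R_MERGES = [(0, 1), (3, 4), (2, 6), (5, 7), (8, 9)]


def dist_df(points: np.ndarray) -> pd.DataFrame:
    D = squareform(pdist(points))
    ids = [f"S{i}" for i in range(len(points))]
    return pd.DataFrame(D, index=ids, columns=ids)


class TestComputeDistance:
    def test_hand_computed_pair_values(self):
        # columns: x=(1,0), y=(0,1), z=(2,2); check the (x, y) entry
        mat = make_matrix([[1.0, 0.0, 2.0], [0.0, 1.0, 2.0]])
        expected = {"manhattan": 2.0, "euclidean": np.sqrt(2), "binary": 1.0, "canberra": 2.0}
        for metric, want in expected.items():
            d = compute_distance(mat, DistanceSpec(metric))
            assert d.iloc[0, 0] == 0.0
            np.testing.assert_allclose(d.iloc[0, 1], want, err_msg=metric)

    def test_identical_samples_give_zero_everywhere(self):
        mat = make_matrix(np.tile([[1.5], [-2.0], [0.5]], (1, 4)))
        for metric in METRICS:
            d = compute_distance(mat, DistanceSpec(metric))
            np.testing.assert_allclose(d.to_numpy(), 0.0, err_msg=metric)

    def test_minkowski_power_two_equals_euclidean(self):
        rng = np.random.default_rng(0)
        mat = make_matrix(rng.normal(size=(10, 5)))
        dm = compute_distance(mat, DistanceSpec("minkowski", minkowski_power=2.0))
        de = compute_distance(mat, DistanceSpec("euclidean"))
        np.testing.assert_allclose(dm.to_numpy(), de.to_numpy())

    def test_rejects_unscaled_and_nonfinite(self):
        raw = make_matrix([[1.0, 2.0, 3.0]], unit="cpm")
        with pytest.raises(ValueError, match="scaled"):
            compute_distance(raw, DistanceSpec("euclidean"))
        bad = make_matrix([[1.0, np.nan, 3.0], [0.0, 1.0, 2.0]])
        with pytest.raises(ValueError, match="f0"):
            compute_distance(bad, DistanceSpec("euclidean"))


class TestAgglomerate:
    @pytest.mark.parametrize("method", LINKAGES)
    def test_matches_frozen_hclust_reference(self, method):
        dendro = agglomerate(dist_df(R_POINTS), LinkageSpec(method))
        np.testing.assert_allclose(dendro.heights, R_HEIGHTS[method], rtol=1e-10)
        assert [(a, b) for a, b, _ in dendro.merges] == R_MERGES

    def test_one_dimensional_example_complete(self):
        # points {0, 1, 10}: merge {0},{1} at height 1, then with {10} at 10
        D = dist_df(np.array([[0.0], [1.0], [10.0]]))
        dendro = agglomerate(D, LinkageSpec("complete"))
        assert dendro.merges[0][:2] == (0, 1) and dendro.merges[0][2] == 1.0
        assert dendro.merges[1][2] == 10.0

    def test_two_leaves_single_merge_any_linkage(self):
        D = pd.DataFrame([[0.0, 3.0], [3.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        for method in LINKAGES:
            dendro = agglomerate(D, LinkageSpec(method))
            assert len(dendro.merges) == 1
            np.testing.assert_allclose(dendro.merges[0][2], 3.0)

    @pytest.mark.parametrize("method", LINKAGES)
    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_heights_match_bruteforce_oracle(self, method, n):
        for seed in range(6):
            rng = np.random.default_rng(1000 * n + seed)
            pts = rng.normal(size=(n, 3))
            D = dist_df(pts)
            dendro = agglomerate(D, LinkageSpec(method))
            np.testing.assert_allclose(
                dendro.heights, naive_linkage(D.to_numpy(), method), rtol=1e-9
            )

    @pytest.mark.parametrize("method,scipy_method", [("complete", "complete"), ("ward_d2", "ward")])
    def test_heights_match_scipy_on_random_instances(self, method, scipy_method):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pts = rng.normal(size=(8, 4))
            Z = scipy_linkage(pdist(pts), method=scipy_method)
            dendro = agglomerate(dist_df(pts), LinkageSpec(method))
            np.testing.assert_allclose(sorted(dendro.heights), sorted(Z[:, 2]), rtol=1e-9)

    def test_rejects_asymmetric_input(self):
        D = pd.DataFrame([[0.0, 1.0, 2.0], [9.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            agglomerate(D, LinkageSpec("complete"))


class TestCutDendrogram:
    @pytest.fixture()
    def line_dendro(self):
        return agglomerate(dist_df(np.array([[0.0], [1.0], [10.0]])), LinkageSpec("complete"))

    def test_k_equals_n_gives_singletons(self, line_dendro):
        assignment = cut_dendrogram(line_dendro, 3)
        assert sorted(assignment.labels.values()) == [1, 2, 3]

    def test_k2_separates_distant_point(self, line_dendro):
        assignment = cut_dendrogram(line_dendro, 2)
        assert assignment.labels["S0"] == assignment.labels["S1"] != assignment.labels["S2"]

    def test_labels_follow_leaf_order(self, line_dendro):
        assignment = cut_dendrogram(line_dendro, 2)
        first_leaf = line_dendro.leaf_ids[line_dendro.leaf_order[0]]
        assert assignment.labels[first_leaf] == 1

    def test_cuts_are_nested(self):
        rng = np.random.default_rng(3)
        dendro = agglomerate(dist_df(rng.normal(size=(9, 2))), LinkageSpec("ward_d2"))
        for k in range(2, 9):
            coarse = cut_dendrogram(dendro, k)
            fine = cut_dendrogram(dendro, k + 1)
            for label in range(1, k + 2):
                members = set(fine.members(label))
                if members:
                    parents = {coarse.labels[s] for s in members}
                    assert len(parents) == 1

    def test_k_out_of_range_rejected(self, line_dendro):
        with pytest.raises(ValueError):
            cut_dendrogram(line_dendro, 1)
        with pytest.raises(ValueError):
            cut_dendrogram(line_dendro, 4)
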