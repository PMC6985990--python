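"""Ward clustering, validity indices and cut selection against oracles."""

import numpy as np
import pandas as pd
import pytest

from neurophenoclust import clustering as cl
from neurophenoclust.synthetic_data import CohortSpec, simulate_cohort

from .oracles import (
    dunn_oracle,
    linkage_merge_sequence,
    silhouette_oracle,
    ward_merge_sequence,
)


def planted_clouds(rng, k=3, n_per=20, p=4, sep=25.0):
    centers = np.eye(k, p) * sep  # orthogonal: all pair distances sep*sqrt(2)
    x = np.concatenate([centers[g] + rng.normal(size=(n_per, p)) for g in range(k)])
    labels = np.repeat(np.arange(k), n_per)
    return x, labels


class TestWardLinkage:
    def test_merge_sequence_equals_exhaustive_greedy_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(6, 3))
            tree = cl.ward_linkage(x)
            got = linkage_merge_sequence(tree.linkage, 6)
            expected = ward_merge_sequence(x)
            for (ga, gb, gh), (ea, eb, eh) in zip(got, expected):
                assert {ga, gb} == {ea, eb}
                assert gh == pytest.approx(eh)

    def test_duplicated_points_merge_at_height_zero(self):
        x = np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]])
        tree = cl.ward_linkage(x)
        assert tree.linkage[0, 2] == pytest.approx(0.0)

    def test_separated_clouds_final_merge_dominates(self, rng):
        x, _ = planted_clouds(rng, k=2, sep=50.0)
        tree = cl.ward_linkage(x)
        heights = tree.linkage[:, 2]
        assert heights[-1] > 10 * heights[:-1].max()

    def test_heights_non_decreasing_ultrametric(self, rng):
        for _ in range(5):
            x = rng.normal(size=(30, 5))
            heights = cl.ward_linkage(x).linkage[:, 2]
            assert (np.diff(heights) >= -1e-9).all()

    def test_non_finite_matrix_rejected(self):
        x = np.ones((4, 2))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            cl.ward_linkage(x)


class TestCutTree:
    def test_extreme_cuts(self, rng):
        x = rng.normal(size=(10, 3))
        tree = cl.ward_linkage(x)
        assert len(set(cl.cut_tree(tree, 1))) == 1
        assert len(set(cl.cut_tree(tree, 10))) == 10

    def test_cuts_nest(self, rng):
        x = rng.normal(size=(40, 4))
        tree = cl.ward_linkage(x)
        for k in range(2, 12):
            coarse = cl.cut_tree(tree, k - 1)
            fine = cl.cut_tree(tree, k)
            # every fine cluster lies inside exactly one coarse cluster
            for lab in set(fine):
                assert len(set(coarse[fine == lab])) == 1

    def test_out_of_range_k_rejected(self, rng):
        tree = cl.ward_linkage(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            cl.cut_tree(tree, 6)


class TestValidityIndices:
    def test_against_brute_force_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(size=(12, 3))
            labels = rng.integers(0, 3, 12)
            if len(set(labels)) < 2:
                continue
            m = cl.validity_indices(x, labels)
            assert m.silhouette == pytest.approx(silhouette_oracle(x, labels))
            assert m.dunn == pytest.approx(dunn_oracle(x, labels))

    def test_tight_far_clusters_score_high(self, rng):
        x, labels = planted_clouds(rng, k=2, sep=100.0)
        m = cl.validity_indices(x, labels)
        assert m.silhouette > 0.95
        assert m.dunn > 5.0

    def test_random_labels_on_one_cloud_score_near_zero(self, rng):
        x = rng.normal(size=(200, 4))
        labels = rng.integers(0, 2, 200)
        m = cl.validity_indices(x, labels)
        assert abs(m.silhouette) < 0.05

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            cl.validity_indices(rng.normal(size=(5, 2)), np.zeros(5, dtype=int))


class TestSelectK:
    @pytest.mark.parametrize("k_true", [2, 3])
    def test_recovers_planted_cluster_count(self, rng, k_true):
        x, _ = planted_clouds(rng, k=k_true, n_per=30, sep=30.0)
        tree = cl.ward_linkage(x)
        chosen, table = cl.select_k(tree, x, (2, 6))
        assert chosen == k_true
        assert set(table["k"]) == set(range(2, 7))

    def test_force_k_overrides_but_keeps_table(self, rng):
        x, _ = planted_clouds(rng, k=3, sep=30.0)
        chosen, table = cl.select_k(cl.ward_linkage(x), x, (2, 6), force_k=5)
        assert chosen == 5
        assert len(table) == 5

    def test_empty_range_rejected(self, rng):
        with pytest.raises(ValueError):
            cl.select_k(cl.ward_linkage(rng.normal(size=(10, 2))),
                        rng.normal(size=(10, 2)), (5, 3))

    def test_full_cohort_recovery_across_seeds(self):
        """On 11 planted subgroups at >= 6 SD separation the rank-sum cut
        selection finds k = 11 and the cut recovers the planted labels."""
        from sklearn.metrics import adjusted_rand_score

        hits = 0
        for seed in range(10):
            feats, _, labels = simulate_cohort(
                CohortSpec(n_patients=400, seed=100 + seed, missingness={})
            )
            tree = cl.ward_linkage(feats)
            k, _ = cl.select_k(tree, feats, (2, 20))
            hits += k == 11
            cut = cl.cut_tree(tree, 11)
            assert adjusted_rand_score(labels, cut) >= 0.9
        assert hits >= 9


class TestRenumberByAge:
    def test_youngest_group_first(self):
        labels = np.array(["A", "B", "C", "A", "B", "C"])
        ages = np.array([70, 50, 60, 72, 48, 62])
        out = cl.renumber_by_age(labels, ages)
        assert out.labels.tolist() == [3, 1, 2, 3, 1, 2]
        assert out.mean_ages[1] == pytest.approx(49.0)

    def test_single_cluster_becomes_one(self):
        out = cl.renumber_by_age(np.zeros(4), np.arange(4))
        assert set(out.labels) == {1}

    def test_renumbering_is_bijective(self, rng):
        labels = rng.integers(0, 5, 100)
        ages = rng.normal(60, 10, 100)
        out = cl.renumber_by_age(labels, ages)
        assert sorted(out.labels.unique()) == sorted(
            range(1, len(set(labels)) + 1)
        )
        # same original label -> same new label
        df = pd.DataFrame({"old": labels, "new": out.labels.to_numpy()})
        assert (df.groupby("old")["new"].nunique() == 1).all()

    def test_missing_age_rejected(self):
        with pytest.raises(ValueError):
            cl.renumber_by_age(np.array([0, 1]), np.array([60.0, np.nan]))


class TestRenderedOutputs:
    def test_heatmap_is_leaf_ordered_matrix(self, rng):
        x = pd.DataFrame(rng.normal(size=(12, 4)),
                         index=[f"P{i}" for i in range(12)])
        tree = cl.ward_linkage(x)
        hm = cl.heatmap_data(x, tree)
        order = tree.leaf_order()
        pd.testing.assert_frame_equal(hm, x.iloc[order])

    def test_identical_masks_give_binary_frequency(self):
        mask = np.zeros((4, 4, 2), dtype=bool)
        mask[1:3, 1:3, :] = True
        masks = {"a": mask, "b": mask.copy()}
        assign = cl.SubgroupAssignment(
            labels=pd.Series([1, 1], index=["a", "b"]), mean_ages={1: 60.0})
        freq = cl.wmh_frequency_maps(masks, assign)
        assert set(np.unique(freq[1])) <= {0.0, 1.0}

    def test_subgroup_without_wmh_gives_zero_map(self):
        masks = {"a": np.zeros((3, 3, 3), bool), "b": np.zeros((3, 3, 3), bool)}
        assign = cl.SubgroupAssignment(
            labels=pd.Series([1, 1], index=["a", "b"]), mean_ages={1: 60.0})
        freq = cl.wmh_frequency_maps(masks, assign)
        assert not freq[1].any()

    def test_mismatching_grids_rejected(self):
        masks = {"a": np.zeros((3, 3, 3), bool), "b": np.zeros((4, 3, 3), bool)}
        assign = cl.SubgroupAssignment(
            labels=pd.Series([1, 1], index=["a", "b"]), mean_ages={1: 60.0})
        with pytest.raises(ValueError, match="differing grids"):
            cl.wmh_frequency_maps(masks, assign)

    def test_render_writes_figures_and_tsv(self, rng, tmp_path):
        x = pd.DataFrame(rng.normal(size=(15, 4)),
                         index=[f"P{i}" for i in range(15)])
        tree = cl.ward_linkage(x)
        assign = cl.renumber_by_age(cl.cut_tree(tree, 3),
                                    rng.normal(60, 5, 15), index=x.index)
        paths = cl.render_outputs(tree, assign, x, tmp_path)
        for key in ("dendrogram", "heatmap", "heatmap_tsv"):
            assert (tmp_path / paths[key].split("/")[-1]).exists()
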