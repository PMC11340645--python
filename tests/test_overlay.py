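import numpy as np
import pandas as pd
import pytest

import celltree as ct
from celltree.cluster_tree import ClusterNode, ClusterTree
from celltree.overlay import FeatureLookupError


@pytest.fixture
def store(tmp_path, toy_matrix):
    return ct.build_feature_store(toy_matrix, tmp_path / "store")


class TestFeatureStore:
    def test_round_trips_every_column(self, store, toy_matrix):
        for name in toy_matrix.feature_names:
            np.testing.assert_array_equal(
                store.get_feature_vector(name), toy_matrix.feature_vector(name))

    def test_persists_across_sessions_without_matrix(self, tmp_path, toy_matrix):
        ct.build_feature_store(toy_matrix, tmp_path / "s")
        del toy_matrix
        reopened = ct.open_feature_store(tmp_path / "s")
        assert reopened.get_feature_vector("g2").tolist() == [0, 1, 3, 0]

    def test_unknown_feature_lists_near_matches(self, store):
        with pytest.raises(FeatureLookupError, match="g1"):
            store.get_feature_vector("g11")

    def test_refuses_nonempty_dir_without_overwrite(self, tmp_path, toy_matrix):
        ct.build_feature_store(toy_matrix, tmp_path / "s")
        with pytest.raises(FileExistsError):
            ct.build_feature_store(toy_matrix, tmp_path / "s")
        ct.build_feature_store(toy_matrix, tmp_path / "s", overwrite=True)

    def test_substring_search(self, store):
        assert store.search("G") == ["g1", "g2", "g3"]
        assert store.search("2") == ["g2"]

    def test_bit_exact_for_integer_counts(self, tmp_path):
        m, _ = ct.simulate_block_counts(ct.BlockSpec(seed=21))
        s = ct.build_feature_store(m, tmp_path / "s")
        dense = m.counts.toarray()
        for j in (0, 100, 499):
            name = m.feature_names[j]
            assert (s.get_feature_vector(name) == dense[:, j]).all()


def small_tree():
    """root -> [leaf(2 cells), leaf(2 cells)]"""
    a = ClusterNode(1, cells=["c1", "c2"])
    b = ClusterNode(2, cells=["c3", "c4"])
    return ClusterTree(ClusterNode(0, distance=0.2, children=[a, b]))


class TestNodeFeatureMeans:
    def test_leaf_mean(self):
        ov = ct.node_feature_means(small_tree(), {"c1": 1, "c2": 3, "c3": 5, "c4": 5})
        assert ov.values[1] == 2.0

    def test_parent_is_weighted_mean_of_children(self):
        ov = ct.node_feature_means(small_tree(), {"c1": 1, "c2": 3, "c3": 5, "c4": 5})
        assert ov.values[0] == pytest.approx((2 * 2.0 + 2 * 5.0) / 4)

    @pytest.mark.parametrize("seed", range(10))
    def test_aggregation_conservation_on_random_trees(self, seed):
        t = ct.simulate_random_tree(7, cells_per_leaf=4, seed=seed)
        rng = np.random.default_rng(seed)
        v = {b: rng.normal() for b in t.barcodes()}
        ov = ct.node_feature_means(t, v)
        for node in t.nodes():
            direct = np.mean([v[b] for b in node.leaf_cells()])  # oracle
            assert ov.values[node.node_id] == pytest.approx(direct, abs=1e-10)
            if not node.is_leaf:
                num = sum(c.n_cells() * ov.values[c.node_id] for c in node.children)
                assert ov.values[node.node_id] == pytest.approx(
                    num / node.n_cells(), abs=1e-10)

    def test_missing_barcode_named(self):
        with pytest.raises(KeyError, match="c4"):
            ct.node_feature_means(small_tree(), {"c1": 1, "c2": 1, "c3": 1})

    def test_consistent_after_min_cells_prune(self):
        t = ct.simulate_random_tree(6, cells_per_leaf=3, seed=1)
        rng = np.random.default_rng(1)
        v = {b: rng.normal() for b in t.barcodes()}
        pruned = ct.prune_min_cells(t, 6)
        ov = ct.node_feature_means(pruned, v)
        for node in pruned.nodes():
            assert ov.values[node.node_id] == pytest.approx(
                np.mean([v[b] for b in node.leaf_cells()]), abs=1e-10)


class TestLabelComposition:
    def test_leaf_histogram(self):
        labels = ct.LabelMap({"c1": "a", "c2": "a", "c3": "b", "c4": "a"})
        comp = ct.node_label_composition(small_tree(), labels)
        assert comp[1] == {"a": 2}
        assert comp[2] == {"b": 1, "a": 1}

    def test_root_equals_global_histogram(self):
        labels = ct.LabelMap({"c1": "a", "c2": "a", "c3": "b", "c4": "a"})
        comp = ct.node_label_composition(small_tree(), labels)
        assert comp[0] == {"a": 3, "b": 1}

    def test_unlabeled_barcode_rejected(self):
        labels = ct.LabelMap({"c1": "a", "c2": "a", "c3": "b"})
        with pytest.raises(KeyError, match="c4"):
            ct.node_label_composition(small_tree(), labels)


class TestTwoFeatureClassification:
    def test_corner_categories(self):
        t = small_tree()
        vA = {"c1": 5.0, "c2": 0.0, "c3": 0.0, "c4": 2.0}
        vB = {"c1": 0.0, "c2": 5.0, "c3": 0.0, "c4": 2.0}
        ov = ct.two_feature_classification(t, vA, vB, hiA=1, loA=0, hiB=1, loB=0)
        root = ov.values[0]
        assert root["A-high/B-low"] == 0.25   # c1
        assert root["A-low/B-high"] == 0.25   # c2
        assert root["A-low/B-low"] == 0.25    # c3
        assert root["A-high/B-high"] == 0.25  # c4

    def test_between_thresholds_is_indeterminate(self):
        t = small_tree()
        v = {b: 0.5 for b in ["c1", "c2", "c3", "c4"]}
        ov = ct.two_feature_classification(t, v, v, hiA=1, loA=0, hiB=1, loB=0)
        assert all(vals["indeterminate"] == 1.0 for vals in ov.values.values())

    def test_proportions_sum_to_one(self):
        t = ct.simulate_random_tree(5, cells_per_leaf=4, seed=0)
        rng = np.random.default_rng(0)
        vA = {b: rng.random() for b in t.barcodes()}
        vB = {b: rng.random() for b in t.barcodes()}
        ov = ct.two_feature_classification(t, vA, vB, 0.8, 0.2, 0.8, 0.2)
        for vals in ov.values.values():
            assert sum(vals.values()) == pytest.approx(1.0)

    def test_inverted_thresholds_rejected(self):
        t = small_tree()
        v = {b: 0.0 for b in ["c1", "c2", "c3", "c4"]}
        with pytest.raises(ValueError):
            ct.two_feature_classification(t, v, v, hiA=0, loA=1, hiB=1, loB=0)


class TestNodeStatistics:
    def test_tooltip_record(self):
        t = small_tree()
        labels = ct.LabelMap({"c1": "a", "c2": "a", "c3": "b", "c4": "a"})
        rec = ct.node_statistics(t, 0, labels)
        assert rec["cell_count"] == 4 and rec["depth"] == 0
        assert rec["label_composition"] == {"a": 3, "b": 1}
        leaf = ct.node_statistics(t, 2)
        assert leaf["depth"] == 1 and leaf["is_leaf"]

    def test_unknown_node(self):
        with pytest.raises(KeyError):
            ct.node_statistics(small_tree(), 42)


class TestBenjaminiHochberg:
    def test_step_up_oracle_on_four_pvalues(self):
        q = ct.benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        # step-up: p_(i) * m / i = [.04, .04, .04, .04]; cummin from top = same
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_monotone_and_capped(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        q = ct.benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q <= 1).all() and (q >= p - 1e-15).all()


class TestDifferentialLog2fc:
    @staticmethod
    def uq(counts, barcodes, features):
        m = ct.CountMatrix(np.asarray(counts), barcodes, features)
        return ct.upper_quartile_normalize(m)

    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(0)
        block = rng.poisson(5, size=(10, 6)) + 1
        counts = np.vstack([block, block[rng.permutation(10)]])
        bcs = [f"c{i}" for i in range(20)]
        m = self.uq(counts, bcs, [f"g{j}" for j in range(6)])
        res = ct.differential_log2fc(m, bcs[:10], bcs[10:])
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)
        assert (res["p"] >= 0.9).all()

    def test_fourfold_means_give_log2fc_two(self):
        # 100 background features pin each cell's upper quartile at 4, so
        # UQ normalization leaves counts unchanged and the target feature
        # compares 8 vs 2 directly
        a = np.hstack([np.full((5, 1), 8), np.full((5, 100), 4)])
        b = np.hstack([np.full((5, 1), 2), np.full((5, 100), 4)])
        bcs = [f"c{i}" for i in range(10)]
        m = self.uq(np.vstack([a, b]), bcs, [f"g{j}" for j in range(101)])
        res = ct.differential_log2fc(m, bcs[:5], bcs[5:], pseudocount=0.01)
        assert res["log2fc"].iloc[0] == pytest.approx(np.log2(8.01 / 2.01), abs=1e-9)
        assert res["log2fc"].iloc[0] == pytest.approx(2.0, abs=0.01)

    def test_one_sided_flag_and_q_ordering(self):
        # background columns pin the upper quartile so the target
        # feature's 12-vs-3 shift survives normalization
        rng = np.random.default_rng(3)
        a = np.hstack([rng.poisson(12, size=(15, 1)) + 1, np.full((15, 40), 4)])
        b = np.hstack([rng.poisson(3, size=(15, 1)) + 1, np.full((15, 40), 4)])
        bcs = [f"c{i}" for i in range(30)]
        m = self.uq(np.vstack([a, b]), bcs, [f"g{j}" for j in range(41)])
        res = ct.differential_log2fc(m, bcs[:15], bcs[15:], alternative="greater")
        assert res["log2fc"].iloc[0] > 0
        assert res["p"].iloc[0] < 0.01
        assert (res["q"] >= res["p"] - 1e-15).all()

    def test_overlapping_sets_rejected(self, toy_matrix):
        m = ct.upper_quartile_normalize(toy_matrix)
        with pytest.raises(ValueError, match="overlap"):
            ct.differential_log2fc(m, ["c1", "c2"], ["c2", "c3"])

    def test_requires_upper_quartile(self, toy_matrix):
        from celltree.matrix_io import StateError
        with pytest.raises(StateError):
            ct.differential_log2fc(toy_matrix, ["c1"], ["c2"])
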