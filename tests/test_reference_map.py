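import numpy as np
import pandas as pd
import pytest

import leukomap as lm
from oracles import bfs_distances


def random_tree(rng, n_nodes, n_genes):
    cent = pd.DataFrame(rng.uniform(0, 10, size=(n_nodes, n_genes)),
                        index=range(n_nodes),
                        columns=[f"g{j}" for j in range(n_genes)])
    edges = [(int(rng.integers(0, i)), i) for i in range(1, n_nodes)]
    return lm.ReferenceTree(centroids=cent, edges=edges)


class TestReferenceTree:
    def test_rejects_cycle(self):
        cent = pd.DataFrame(np.zeros((3, 2)), index=[0, 1, 2], columns=["a", "b"])
        with pytest.raises(ValueError, match="acyclic"):
            lm.ReferenceTree(centroids=cent, edges=[(0, 1), (1, 2), (2, 0)])

    def test_rejects_disconnected(self):
        cent = pd.DataFrame(np.zeros((3, 2)), index=[0, 1, 2], columns=["a", "b"])
        with pytest.raises(ValueError, match="acyclic|connected"):
            lm.ReferenceTree(centroids=cent, edges=[(0, 1)])

    def test_rejects_unknown_edge_node(self):
        cent = pd.DataFrame(np.zeros((2, 2)), index=[0, 1], columns=["a", "b"])
        with pytest.raises(ValueError, match="unknown"):
            lm.ReferenceTree(centroids=cent, edges=[(0, 7)])

    def test_csv_and_json_round_trip(self, tmp_path, chain_tree):
        chain_tree.to_csv(tmp_path / "nodes.csv", tmp_path / "edges.csv")
        back = lm.ReferenceTree.from_csv(tmp_path / "nodes.csv", tmp_path / "edges.csv")
        pd.testing.assert_frame_equal(back.centroids, chain_tree.centroids)
        assert back.branch == chain_tree.branch
        chain_tree.to_json(tmp_path / "tree.json")
        back2 = lm.ReferenceTree.from_json(tmp_path / "tree.json")
        pd.testing.assert_frame_equal(back2.centroids, chain_tree.centroids)
        assert set(map(frozenset, back2.edges)) == set(map(frozenset, chain_tree.edges))
        assert back2.branch == chain_tree.branch


class TestNodeCentroids:
    def test_single_cell_node_equals_cell(self):
        expr = lm.ExpressionMatrix(pd.DataFrame([[1.0, 5.0]], index=["c"],
                                                columns=["g1", "g2"]))
        cent = lm.compute_node_centroids(expr, pd.Series({"c": 3}))
        np.testing.assert_allclose(cent.loc[3], [1.0, 5.0])

    def test_two_cell_mean(self):
        expr = lm.ExpressionMatrix(pd.DataFrame([[0.0, 2.0], [4.0, 2.0]],
                                                index=["c1", "c2"],
                                                columns=["g1", "g2"]))
        cent = lm.compute_node_centroids(expr, pd.Series({"c1": 0, "c2": 0}))
        np.testing.assert_allclose(cent.loc[0], [2.0, 2.0])

    def test_matches_direct_summation(self, rng):
        X = rng.uniform(0, 10, size=(10, 4))
        expr = lm.ExpressionMatrix(pd.DataFrame(
            X, index=[f"c{i}" for i in range(10)], columns=list("wxyz")))
        labels = pd.Series(rng.integers(0, 3, size=10),
                           index=expr.data.index)
        cent = lm.compute_node_centroids(expr, labels)
        for node in cent.index:
            rows = X[(labels == node).to_numpy()]
            np.testing.assert_allclose(cent.loc[node].to_numpy(),
                                       rows.sum(axis=0) / len(rows))


class TestMapCells:
    def test_cell_at_centroid_maps_exactly(self, chain_tree):
        expr = lm.ExpressionMatrix(pd.DataFrame([[2.0, 2.0]], index=["c"],
                                                columns=["g1", "g2"]))
        res = lm.map_cells(expr, chain_tree)
        assert res.assignments.loc["c", "node_id"] == 1
        assert res.assignments.loc["c", "distance"] == pytest.approx(0.0)

    def test_tie_goes_to_lowest_node_id(self, chain_tree):
        # equidistant between node 0 (0,0) and node 1 (2,2)
        expr = lm.ExpressionMatrix(pd.DataFrame([[1.0, 1.0]], index=["c"],
                                                columns=["g1", "g2"]))
        res = lm.map_cells(expr, chain_tree)
        assert res.assignments.loc["c", "node_id"] == 0

    def test_empty_panel_rejected(self, chain_tree):
        expr = lm.ExpressionMatrix(pd.DataFrame([[1.0, 1.0]], index=["c"],
                                                columns=["g1", "g2"]))
        with pytest.raises(ValueError, match="panel"):
            lm.map_cells(expr, chain_tree, panel=[])

    def test_matches_brute_force_distance_table(self, rng):
        tree = random_tree(rng, 12, 6)
        X = rng.uniform(0, 10, size=(50, 6))
        expr = lm.ExpressionMatrix(pd.DataFrame(
            X, index=[f"c{i}" for i in range(50)], columns=tree.gene_ids))
        panel = tree.gene_ids[:4]
        res = lm.map_cells(expr, tree, panel=panel)
        C = tree.centroids[panel].to_numpy()
        Xp = expr.data[panel].to_numpy()
        for ci, cell in enumerate(expr.cell_ids):
            dists = np.sqrt(((Xp[ci] - C) ** 2).sum(axis=1))
            best = min(range(12), key=lambda j: (dists[j], tree.node_ids[j]))
            assert res.assignments.loc[cell, "node_id"] == tree.node_ids[best]
            assert res.assignments.loc[cell, "distance"] == pytest.approx(dists[best])

    def test_centroid_cells_return_own_node_with_full_panel(self, rng):
        tree = random_tree(rng, 8, 5)
        expr = lm.ExpressionMatrix(tree.centroids.copy().set_axis(
            [f"cell_of_{n}" for n in tree.node_ids]))
        res = lm.map_cells(expr, tree)
        assert list(res.assignments["node_id"]) == tree.node_ids
        np.testing.assert_allclose(res.assignments["distance"], 0.0, atol=1e-12)


class TestTreeDistance:
    def test_chain_and_self(self, chain_tree):
        assert lm.tree_distance(chain_tree, 0, 2) == 2
        assert lm.tree_distance(chain_tree, 1, 1) == 0

    def test_unknown_node_rejected(self, chain_tree):
        with pytest.raises(KeyError):
            lm.tree_distance(chain_tree, 0, 99)

    def test_matches_bfs_oracle(self, rng):
        tree = random_tree(rng, 20, 3)
        for src in tree.node_ids:
            want = bfs_distances(tree.edges, src)
            for dst in tree.node_ids:
                assert lm.tree_distance(tree, src, dst) == want[dst]


class TestConcordance:
    def test_identical_mapping_is_perfect(self, chain_tree):
        df = pd.DataFrame({"node_id": [0, 1, 2], "distance": 0.0,
                           "original_node_id": [0, 1, 2]},
                          index=["a", "b", "c"])
        s = lm.concordance(lm.MappingResult(assignments=df), chain_tree)
        assert (s.fraction_exact, s.fraction_within) == (1.0, 1.0)

    def test_one_step_off_counts_within_two(self, chain_tree):
        df = pd.DataFrame({"node_id": [1, 2, 1], "distance": 0.0,
                           "original_node_id": [0, 1, 2]},
                          index=["a", "b", "c"])
        s = lm.concordance(lm.MappingResult(assignments=df), chain_tree, max_steps=2)
        assert (s.fraction_exact, s.fraction_within) == (0.0, 1.0)

    def test_mixed_case_equals_hand_enumeration(self, chain_tree):
        df = pd.DataFrame({"node_id": [0, 0, 2, 2], "distance": 0.0,
                           "original_node_id": [0, 2, 2, 0]},
                          index=list("abcd"))
        # steps: 0, 2, 0, 2 -> exact 2/4; within<=1: 2/4, within<=2: 4/4
        s1 = lm.concordance(lm.MappingResult(assignments=df), chain_tree, max_steps=1)
        s2 = lm.concordance(lm.MappingResult(assignments=df), chain_tree, max_steps=2)
        assert s1.fraction_exact == 0.5 and s1.fraction_within == 0.5
        assert s2.fraction_within == 1.0

    def test_monotone_in_max_steps(self, rng):
        tree = random_tree(rng, 10, 4)
        cells = [f"c{i}" for i in range(40)]
        df = pd.DataFrame({
            "node_id": rng.choice(tree.node_ids, size=40),
            "distance": 0.0,
            "original_node_id": rng.choice(tree.node_ids, size=40),
        }, index=cells)
        mapping = lm.MappingResult(assignments=df)
        fracs = [lm.concordance(mapping, tree, max_steps=s).fraction_within
                 for s in range(5)]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_missing_original_rejected(self, chain_tree):
        df = pd.DataFrame({"node_id": [0], "distance": [0.0]}, index=["a"])
        with pytest.raises(ValueError, match="original"):
            lm.concordance(lm.MappingResult(assignments=df), chain_tree)


class TestRandomPanelValidation:
    def test_full_panel_equals_full_concordance(self, rng):
        tree = random_tree(rng, 6, 5)
        X = tree.centroids.to_numpy() + rng.normal(0, 0.5, size=(6, 5))
        expr = lm.ExpressionMatrix(pd.DataFrame(
            np.clip(X, 0, 28), index=[f"c{i}" for i in range(6)],
            columns=tree.gene_ids))
        original = pd.Series(tree.node_ids, index=expr.cell_ids)
        full = lm.concordance(lm.map_cells(expr, tree, original=original), tree)
        pv = lm.random_panel_validation(expr, tree, original, panel_size=5,
                                        n_lists=4, seed=0)
        for s in pv.summaries:
            assert s.fraction_exact == full.fraction_exact
            assert s.fraction_within == full.fraction_within

    def test_single_list_equals_manual_composition(self, rng):
        tree = random_tree(rng, 6, 8)
        expr = lm.ExpressionMatrix(pd.DataFrame(
            rng.uniform(0, 10, size=(20, 8)),
            index=[f"c{i}" for i in range(20)], columns=tree.gene_ids))
        original = pd.Series(rng.choice(tree.node_ids, 20), index=expr.cell_ids)
        pv = lm.random_panel_validation(expr, tree, original, panel_size=3,
                                        n_lists=1, seed=5)
        manual = lm.concordance(
            lm.map_cells(expr, tree, panel=pv.panels[0], original=original), tree)
        assert pv.summaries[0].fraction_exact == manual.fraction_exact
        assert pv.summaries[0].fraction_within == manual.fraction_within

    def test_same_seed_bit_identical(self, rng):
        tree = random_tree(rng, 6, 8)
        expr = lm.ExpressionMatrix(pd.DataFrame(
            rng.uniform(0, 10, size=(15, 8)),
            index=[f"c{i}" for i in range(15)], columns=tree.gene_ids))
        original = pd.Series(rng.choice(tree.node_ids, 15), index=expr.cell_ids)
        pv1 = lm.random_panel_validation(expr, tree, original, 4, 10, seed=9)
        pv2 = lm.random_panel_validation(expr, tree, original, 4, 10, seed=9)
        assert pv1.panels == pv2.panels
        assert pv1.mean_exact == pv2.mean_exact
        assert pv1.mean_within == pv2.mean_within

    def test_oversized_panel_rejected(self, rng):
        tree = random_tree(rng, 4, 3)
        expr = lm.ExpressionMatrix(pd.DataFrame(
            rng.uniform(0, 10, size=(4, 3)),
            index=[f"c{i}" for i in range(4)], columns=tree.gene_ids))
        original = pd.Series(tree.node_ids, index=expr.cell_ids)
        with pytest.raises(ValueError, match="panel_size"):
            lm.random_panel_validation(expr, tree, original, panel_size=10)

    def test_zero_noise_centroid_cells_always_perfect(self, rng):
        tree = random_tree(rng, 7, 6)
        expr = lm.ExpressionMatrix(tree.centroids.copy().set_axis(
            [f"c{i}" for i in range(7)]))
        original = pd.Series(tree.node_ids, index=expr.cell_ids)
        for size in (1, 3, 6):
            pv = lm.random_panel_validation(expr, tree, original, panel_size=size,
                                            n_lists=5, seed=1)
            # a panel may leave ties (resolved to the lowest node id), so
            # exactness is only guaranteed when centroids differ on the panel
            if size == 6:
                assert pv.mean_exact == 1.0


class TestSubtypesAndCrosstab:
    def test_subtype_follows_branch_of_assigned_node(self, chain_tree):
        df = pd.DataFrame({"node_id": [0, 1, 2, 1], "distance": 0.0},
                          index=list("abcd"))
        st = lm.assign_subtypes(lm.MappingResult(assignments=df), chain_tree)
        assert list(st) == ["hsc", "gmp", "dc", "gmp"]

    def test_missing_branch_label_rejected_with_node_list(self, chain_tree):
        df = pd.DataFrame({"node_id": [0, 2], "distance": 0.0}, index=["a", "b"])
        with pytest.raises(ValueError, match="2"):
            lm.assign_subtypes(lm.MappingResult(assignments=df), chain_tree,
                               branch_map={0: "hsc", 1: "gmp"})

    def test_crosstab_direct_count(self):
        st = pd.Series({"c1": "S1", "c2": "S1", "c3": "S2", "c4": "S2"})
        ph = pd.Series({"c1": "P1", "c2": "P1", "c3": "P1", "c4": "P2"})
        res = lm.phenotype_crosstab(st, ph)
        assert res.counts.loc["P1", "S1"] == 2
        assert res.row_proportions.loc["P1", "S1"] == pytest.approx(2 / 3)
        assert res.col_proportions.loc["P2", "S2"] == pytest.approx(1 / 2)

    def test_crosstab_matches_brute_force_contingency(self, rng):
        cells = [f"c{i}" for i in range(60)]
        st = pd.Series(rng.choice(["S1", "S2", "S3"], 60), index=cells)
        ph = pd.Series(rng.choice(["P1", "P2"], 60), index=cells)
        res = lm.phenotype_crosstab(st, ph)
        for p in ["P1", "P2"]:
            for s in ["S1", "S2", "S3"]:
                want = sum((ph[c] == p) and (st[c] == s) for c in cells)
                assert res.counts.loc[p, s] == want

    def test_mismatched_cell_sets_rejected(self):
        st = pd.Series({"c1": "S1"})
        ph = pd.Series({"c2": "P1"})
        with pytest.raises(ValueError, match="different cells"):
            lm.phenotype_crosstab(st, ph)
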