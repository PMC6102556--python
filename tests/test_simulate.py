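"""Synthetic trees, disc ranges, endemism injection, null datasets."""

import numpy as np
import pytest

import phylogrid as pg
from phylogrid.tree import counted_nodes, tip_labels


class TestSimulateTree:
    def test_single_taxon_degenerate_tree(self):
        tree = pg.simulate_tree(1, seed=0)
        assert len(tip_labels(tree)) == 1
        assert pg.total_branch_length(tree) > 0

    def test_seeded_determinism_bit_identical_newick(self):
        a = pg.write_tree(pg.simulate_tree(64, seed=7))
        b = pg.write_tree(pg.simulate_tree(64, seed=7))
        assert a == b

    def test_bifurcating_tree_counts(self):
        tree = pg.simulate_tree(64, seed=7)
        assert len(tip_labels(tree)) == 64
        internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        assert len(internal) == 63
        assert all(
            (nd.edge.length or 0) > 0 for nd in counted_nodes(tree)
        )

    def test_invalid_parameters(self):
        with pytest.raises(pg.InvalidParameterError):
            pg.simulate_tree(0, seed=1)
        with pytest.raises(pg.InvalidParameterError):
            pg.simulate_tree(5, birth_rate=0.0, seed=1)


class TestSimulateOccurrences:
    def test_every_taxon_occupies_a_cell(self):
        tree = pg.simulate_tree(64, seed=1)
        m = pg.simulate_occurrences(tree, pg.RangeModel(), seed=1)
        assert (m.ranges >= 1).all()
        assert sorted(m.taxa) == sorted(tip_labels(tree))

    def test_tiny_radius_forces_single_cell_ranges(self):
        tree = pg.simulate_tree(20, seed=4)
        model = pg.RangeModel(
            range_radius_log_mean=np.log(1e-6), range_radius_log_sd=0.0
        )
        m = pg.simulate_occurrences(tree, model, seed=4)
        assert (m.ranges == 1).all()

    def test_seeded_determinism(self):
        tree = pg.simulate_tree(64, seed=2)
        model = pg.RangeModel(n_cells_x=20, n_cells_y=10)
        a = pg.simulate_occurrences(tree, model, seed=3)
        b = pg.simulate_occurrences(tree, model, seed=3)
        assert a.data.equals(b.data)

    def test_clustered_centers_still_valid(self):
        tree = pg.simulate_tree(30, seed=5)
        m = pg.simulate_occurrences(
            tree, pg.RangeModel(center_clustering=2.0), seed=5
        )
        assert (m.richness >= 1).all() and (m.ranges >= 1).all()

    def test_model_validation(self):
        with pytest.raises(pg.InvalidParameterError):
            pg.RangeModel(n_cells_x=0)
        with pytest.raises(pg.InvalidParameterError):
            pg.RangeModel(range_radius_log_sd=-1)


class TestInjectEndemismScenario:
    @pytest.fixture
    def base(self):
        tree = pg.simulate_tree(32, seed=6)
        matrix = pg.simulate_occurrences(tree, pg.RangeModel(), seed=6)
        return tree, matrix

    def test_paleo_injection_contract(self, base):
        tree, matrix = base
        target = matrix.cell_ids[10]
        scenario = pg.EndemismScenario(
            kind="paleo", target_cells=frozenset([target]),
            n_taxa=1, branch_scale=10.0, range_cells=1,
        )
        tree2, matrix2 = pg.inject_endemism_scenario(tree, matrix, scenario, 1)
        new = [t for t in matrix2.taxa if t.startswith("paleo")]
        assert len(new) == 1
        assert matrix2.ranges[new[0]] == 1
        assert matrix2.data.loc[target, new[0]]
        # base dataset untouched
        assert sorted(tip_labels(tree)) == sorted(
            t for t in tip_labels(tree2) if not t.startswith("paleo")
        )
        assert new[0] not in matrix.taxa

    def test_neo_injection_adds_sister_tips_near_target(self, base):
        tree, matrix = base
        target = matrix.cell_ids[5]
        scenario = pg.EndemismScenario(
            kind="neo", target_cells=frozenset([target]),
            n_taxa=5, branch_scale=0.1, range_cells=2,
        )
        tree2, matrix2 = pg.inject_endemism_scenario(tree, matrix, scenario, 2)
        new = [t for t in matrix2.taxa if t.startswith("neo")]
        assert len(new) == 5
        for t in new:
            assert matrix2.ranges[t] == 2
            assert matrix2.data.loc[target, t]
        # the five tips are sisters: they share their parent node
        tips = [
            lf for lf in tree2.leaf_node_iter()
            if lf.taxon.label.startswith("neo")
        ]
        assert len({id(t.parent_node) for t in tips}) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_paleo_tip_lands_in_top_length_decile(self, base, seed):
        tree, matrix = base
        scenario = pg.EndemismScenario(
            kind="paleo", target_cells=frozenset([matrix.cell_ids[0]]),
            branch_scale=10.0, range_cells=1,
        )
        tree2, _ = pg.inject_endemism_scenario(tree, matrix, scenario, seed)
        lengths = np.array([nd.edge.length for nd in counted_nodes(tree2)])
        injected = next(
            lf.edge.length for lf in tree2.leaf_node_iter()
            if lf.taxon.label.startswith("paleo")
        )
        assert injected >= np.quantile(lengths, 0.9)

    def test_unknown_target_cell_rejected(self, base):
        tree, matrix = base
        scenario = pg.EndemismScenario(
            kind="paleo", target_cells=frozenset(["999_999"]), range_cells=1
        )
        with pytest.raises(pg.InvalidScenarioError):
            pg.inject_endemism_scenario(tree, matrix, scenario, 0)


class TestSimulateNullDataset:
    def test_margins_match_inputs_for_every_seed(self):
        richness = {"c1": 2, "c2": 1, "c3": 3}
        ranges = {"A": 2, "B": 1, "C": 2, "D": 1}
        for seed in range(10):
            m = pg.simulate_null_dataset(richness, ranges, seed)
            assert m.richness.to_dict() == richness
            assert m.ranges.to_dict() == ranges

    def test_two_cell_case_enumerates_both_permutations(self):
        seen = set()
        for seed in range(200):
            m = pg.simulate_null_dataset(
                {"c1": 1, "c2": 1}, {"A": 1, "B": 1}, seed
            )
            seen.add(tuple(m.values.flatten().tolist()))
        assert seen == {
            (True, False, False, True),
            (False, True, True, False),
        }

    def test_forced_unique_matrix(self):
        m = pg.simulate_null_dataset({"c1": 2}, {"A": 1, "B": 1}, 0)
        assert m.values.all()

    def test_sum_mismatch_is_infeasible(self):
        with pytest.raises(pg.InfeasibleMarginsError):
            pg.simulate_null_dataset({"c1": 1}, {"A": 1, "B": 1}, 0)

    def test_gale_ryser_violation_is_infeasible(self):
        # 2 cells cannot host a taxon with range 3
        with pytest.raises(pg.InfeasibleMarginsError):
            pg.simulate_null_dataset({"c1": 2, "c2": 1}, {"A": 3}, 0)
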