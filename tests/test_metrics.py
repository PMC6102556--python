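"""Observed diversity/endemism surfaces and their invariants."""

import numpy as np
import pandas as pd
import pytest
from conftest import THREE_CELLS, build_matrix

import phylogrid as pg


@pytest.fixture
def fixture_incidence(four_tip_tree_newick, three_cell_matrix):
    tree = pg.read_tree(four_tip_tree_newick)
    return pg.branch_incidence(tree, three_cell_matrix)


class TestObservedValues:
    def test_taxon_richness(self, three_cell_matrix):
        tr = pg.taxon_richness(three_cell_matrix)
        assert tr.values.to_dict() == {"c1": 2.0, "c2": 1.0, "c3": 3.0}

    def test_weighted_endemism(self, three_cell_matrix):
        we = pg.weighted_endemism(three_cell_matrix)
        assert we.values.to_dict() == pytest.approx(
            {"c1": 1.5, "c2": 0.5, "c3": 2.0}
        )

    def test_phylogenetic_diversity(self, fixture_incidence):
        pd_ = pg.phylogenetic_diversity(fixture_incidence)
        assert pd_.values.to_dict() == pytest.approx(
            {"c1": 3.0, "c2": 2.0, "c3": 5.0}
        )

    def test_single_taxon_cell_pd_is_root_path(self, four_tip_tree_newick):
        inc = pg.branch_incidence(
            pg.read_tree(four_tip_tree_newick), build_matrix({"c": {"A"}})
        )
        assert pg.phylogenetic_diversity(inc).values.loc["c"] == pytest.approx(2.0)

    def test_full_cell_pd_is_total_length(self, four_tip_tree_newick):
        inc = pg.branch_incidence(
            pg.read_tree(four_tip_tree_newick),
            build_matrix({"c": {"A", "B", "C", "D"}, "d": {"A"}}),
        )
        assert pg.phylogenetic_diversity(inc).values.loc["c"] == pytest.approx(6.0)

    def test_phylogenetic_endemism(self, fixture_incidence):
        pe = pg.phylogenetic_endemism(fixture_incidence)
        assert pe.values.to_dict() == pytest.approx(
            {"c1": 2.0, "c2": 1.0, "c3": 3.0}
        )

    def test_relative_pd_from_equalized_tree(self):
        # total length 9 over 6 branches -> equalized branch 1.5;
        # cell {A,B}: PD_actual = 6, PD_equalized = 4.5 -> RPD = 4/3
        tree = pg.read_tree("((A:4,B:1):1,(C:1,D:1):1);")
        matrix = build_matrix(THREE_CELLS)
        inc = pg.branch_incidence(tree, matrix)
        inc_eq = pg.branch_incidence(pg.equalize_branch_lengths(tree), matrix)
        rpd = pg.relative_metric(
            pg.phylogenetic_diversity(inc), pg.phylogenetic_diversity(inc_eq)
        )
        assert rpd.metric == "RPD"
        assert rpd.values.loc["c1"] == pytest.approx(6.0 / 4.5)

    def test_rpd_is_one_on_equal_length_tree(self, four_tip_tree_newick,
                                             three_cell_matrix):
        tree = pg.read_tree(four_tip_tree_newick)
        inc = pg.branch_incidence(tree, three_cell_matrix)
        inc_eq = pg.branch_incidence(
            pg.equalize_branch_lengths(tree), three_cell_matrix
        )
        rpd = pg.relative_metric(
            pg.phylogenetic_diversity(inc), pg.phylogenetic_diversity(inc_eq)
        )
        assert np.allclose(rpd.values, 1.0)

    def test_rpd_invariant_to_global_rescaling(self, three_cell_matrix):
        def rpd_for(newick):
            tree = pg.read_tree(newick)
            inc = pg.branch_incidence(tree, three_cell_matrix)
            inc_eq = pg.branch_incidence(
                pg.equalize_branch_lengths(tree), three_cell_matrix
            )
            return pg.relative_metric(
                pg.phylogenetic_diversity(inc),
                pg.phylogenetic_diversity(inc_eq),
            ).values

        a = rpd_for("((A:4,B:1):1,(C:1,D:1):1);")
        b = rpd_for("((A:20,B:5):5,(C:5,D:5):5);")
        assert np.allclose(a, b)

    def test_zero_comparison_cell_is_undefined(self, three_cell_matrix):
        obs = pg.taxon_richness(three_cell_matrix)
        comp = pg.DiversitySurface(
            "TR", pd.Series({"c1": 1.0, "c2": 0.0, "c3": 2.0})
        )
        with pytest.raises(pg.UndefinedCellError) as err:
            pg.relative_metric(obs, comp)
        assert err.value.cells == ["c2"]


class TestInvariants:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_conservation_identities(self, seed):
        """Sum WE = number of taxa; sum PE = total counted tree length."""
        tree = pg.simulate_tree(40, seed=seed)
        matrix = pg.simulate_occurrences(tree, pg.RangeModel(), seed=seed)
        inc = pg.branch_incidence(tree, matrix)
        assert pg.weighted_endemism(matrix).values.sum() == pytest.approx(
            len(matrix.taxa), rel=1e-9
        )
        assert pg.phylogenetic_endemism(inc).values.sum() == pytest.approx(
            pg.total_branch_length(tree), rel=1e-9
        )

    def test_adding_taxon_never_decreases_metrics(self, four_tip_tree_newick):
        tree = pg.read_tree(four_tip_tree_newick)
        base = {"c1": {"A"}, "c2": {"B", "C", "D"}}
        grown = {"c1": {"A", "D"}, "c2": {"B", "C", "D"}}
        taxa = {"A", "B", "C", "D"}
        m0, m1 = build_matrix(base, taxa), build_matrix(grown, taxa)
        for metric, args in (
            (pg.taxon_richness, "matrix"),
            (pg.weighted_endemism, "matrix"),
            (pg.phylogenetic_diversity, "incidence"),
            (pg.phylogenetic_endemism, "incidence"),
        ):
            if args == "matrix":
                v0, v1 = metric(m0).values, metric(m1).values
            else:
                v0 = metric(pg.branch_incidence(tree, m0)).values
                v1 = metric(pg.branch_incidence(tree, m1)).values
            assert (v1.loc["c1"] >= v0.loc["c1"] - 1e-12)

    @pytest.mark.parametrize("seed", [11, 12])
    def test_pe_dominated_by_pd_and_we_by_tr(self, seed):
        tree = pg.simulate_tree(25, seed=seed)
        matrix = pg.simulate_occurrences(tree, pg.RangeModel(), seed=seed)
        inc = pg.branch_incidence(tree, matrix)
        assert (
            pg.phylogenetic_endemism(inc).values
            <= pg.phylogenetic_diversity(inc).values + 1e-12
        ).all()
        assert (
            pg.weighted_endemism(matrix).values
            <= pg.taxon_richness(matrix).values + 1e-12
        ).all()

    def test_star_tree_reduction_under_crown_convention(self):
        """On a unit star tree, PD = TR and PE = WE (crown convention)."""
        star = pg.read_tree("(A:1,B:1,C:1,D:1);")
        matrix = build_matrix(THREE_CELLS)
        inc = pg.branch_incidence(star, matrix, convention="crown")
        assert np.allclose(
            pg.phylogenetic_diversity(inc).values,
            pg.taxon_richness(matrix).values,
        )
        assert np.allclose(
            pg.phylogenetic_endemism(inc).values,
            pg.weighted_endemism(matrix).values,
        )
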