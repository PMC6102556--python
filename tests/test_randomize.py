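"""Fixed-margin randomization, rank significance, and CANAPE categories."""

import numpy as np
import pandas as pd
import pytest
from conftest import build_matrix

import phylogrid as pg
from phylogrid.canape import (
    CATEGORIES,
    NullEnsemble,
    build_null_ensemble,
    canape_classify,
    significance_ranks,
)


class TestRandomizeMatrix:
    def test_margins_preserved_exactly(self):
        tree = pg.simulate_tree(30, seed=2)
        matrix = pg.simulate_occurrences(tree, pg.RangeModel(), seed=2)
        for seed in range(5):
            r = pg.randomize_matrix(matrix, seed)
            assert (r.richness == matrix.richness).all()
            assert (r.ranges == matrix.ranges).all()

    def test_two_by_two_reaches_both_states(self):
        matrix = build_matrix({"c1": {"A"}, "c2": {"B"}})
        seen = set()
        for seed in range(200):
            r = pg.randomize_matrix(matrix, seed)
            seen.add(tuple(r.values.flatten().tolist()))
        assert seen == {
            (True, False, False, True),
            (False, True, True, False),
        }

    def test_all_ones_matrix_is_fixed(self):
        matrix = build_matrix({"c1": {"A", "B"}, "c2": {"A", "B"}})
        r = pg.randomize_matrix(matrix, 123)
        assert (r.values == matrix.values).all()

    def test_seeded_determinism(self):
        tree = pg.simulate_tree(20, seed=9)
        matrix = pg.simulate_occurrences(tree, pg.RangeModel(), seed=9)
        a = pg.randomize_matrix(matrix, 7)
        b = pg.randomize_matrix(matrix, 7)
        assert (a.values == b.values).all()


class TestRandomizationConfig:
    def test_alpha_ordering_enforced(self):
        with pytest.raises(pg.InvalidParameterError):
            pg.RandomizationConfig(alpha_two_tailed=0.01, alpha_super=0.05)


@pytest.fixture(scope="module")
def small_ensemble():
    tree = pg.simulate_tree(16, seed=3)
    matrix = pg.simulate_occurrences(
        tree, pg.RangeModel(n_cells_x=8, n_cells_y=5), seed=3
    )
    cfg = pg.RandomizationConfig(n_reps=199, seed=42)
    return build_null_ensemble(matrix, tree, cfg), cfg


class TestNullEnsemble:
    def test_reproducible_per_seed(self, small_ensemble):
        ens, cfg = small_ensemble
        tree = pg.simulate_tree(16, seed=3)
        matrix = pg.simulate_occurrences(
            tree, pg.RangeModel(n_cells_x=8, n_cells_y=5), seed=3
        )
        again = build_null_ensemble(matrix, tree, cfg)
        for m in ens.observed:
            assert (ens.n_ge[m] == again.n_ge[m]).all()
            assert (ens.n_le[m] == again.n_le[m]).all()

    def test_null_tr_equals_observed(self, small_ensemble):
        ens, _ = small_ensemble
        assert np.allclose(ens.null_mean("TR"), ens.observed["TR"])

    def test_counts_total_n_reps(self, small_ensemble):
        ens, cfg = small_ensemble
        # every null value is >= or <= the observed (or both, at a tie)
        for m in ens.observed:
            assert (ens.n_ge[m] + ens.n_le[m] >= cfg.n_reps).all()

    def test_unknown_metric_lookup(self, small_ensemble):
        ens, _ = small_ensemble
        with pytest.raises(pg.UnknownMetricError):
            significance_ranks(ens, "nope")


def make_ensemble(cells, n_reps, n_ge, n_le, metric="PD"):
    n = len(cells)
    return NullEnsemble(
        cells=pd.Index(cells),
        n_reps=n_reps,
        observed={metric: np.zeros(n)},
        n_ge={metric: np.asarray(n_ge)},
        n_le={metric: np.asarray(n_le)},
        null_sum={metric: np.zeros(n)},
    )


class TestSignificanceRanks:
    def test_extreme_high_observation(self):
        ens = make_ensemble(["c"], 999, [0], [999])
        sig = significance_ranks(ens, "PD", "two", 0.05)
        assert sig.p_high.loc["c"] == pytest.approx(0.001)
        assert sig.flag.loc["c"] == "sig-high"

    def test_extreme_low_observation(self):
        ens = make_ensemble(["c"], 999, [999], [0])
        sig = significance_ranks(ens, "PD", "two", 0.05)
        assert sig.p_low.loc["c"] == pytest.approx(0.001)
        assert sig.flag.loc["c"] == "sig-low"

    def test_median_observation_is_ns(self):
        ens = make_ensemble(["c"], 999, [500], [499])
        sig = significance_ranks(ens, "PD", "two", 0.05)
        assert sig.flag.loc["c"] == "ns"

    def test_one_tailed_threshold(self):
        ens = make_ensemble(["a", "b"], 999, [49, 50], [950, 949])
        sig = significance_ranks(ens, "PD", "high", 0.05)
        assert sig.flag.loc["a"] == "sig-high"  # p = 50/1000
        assert sig.flag.loc["b"] == "ns"  # p = 51/1000

    def test_rank_duality_with_ties(self, small_ensemble):
        """p_high + p_low >= 1 + 1/(n_reps + 1) cell-wise."""
        ens, cfg = small_ensemble
        for m in ens.observed:
            sig = significance_ranks(ens, m, "two", 0.05)
            floor = 1 + 1 / (cfg.n_reps + 1)
            assert (sig.p_high + sig.p_low >= floor - 1e-12).all()


def classify(step1_p, rpe_p_high, rpe_p_low, either=False, step1_eq_p=1.0):
    cells = pd.Index(["c"])
    cfg = pg.RandomizationConfig(n_reps=999, seed=0)

    def surf(metric, tail, p_hi, p_lo):
        from phylogrid.canape import SignificanceSurface

        flag = pd.Series("ns", index=cells)
        return SignificanceSurface(
            metric, tail, 0.05,
            pd.Series([p_hi], index=cells), pd.Series([p_lo], index=cells),
            flag,
        )

    cmap = canape_classify(
        surf("PE_actual", "high", step1_p, 1.0),
        surf("PE_equalized", "high", step1_eq_p, 1.0),
        surf("RPE", "two", rpe_p_high, rpe_p_low),
        cfg,
        either_tree=either,
    )
    return cmap.categories.loc["c"]


class TestCanapeClassify:
    def test_high_rpe_is_paleo(self):
        assert classify(0.03, 0.01, 0.99) == "paleo"

    def test_low_rpe_is_neo(self):
        assert classify(0.03, 0.99, 0.01) == "neo"

    def test_nonsignificant_rpe_is_mixed(self):
        assert classify(0.03, 0.5, 0.5) == "mixed"

    def test_strict_step_one_upgrades_to_super(self):
        assert classify(0.004, 0.5, 0.5) == "super"

    def test_step_one_failure_wins_regardless_of_rpe(self):
        assert classify(0.30, 0.001, 0.99) == "not-significant"

    def test_either_tree_rule_uses_comparison_tree(self):
        assert classify(0.30, 0.99, 0.01, either=True, step1_eq_p=0.02) == "neo"
        assert classify(0.30, 0.99, 0.01, either=False, step1_eq_p=0.02) == (
            "not-significant"
        )

    def test_categories_exclusive_and_exhaustive(self, small_ensemble):
        ens, cfg = small_ensemble
        a = cfg.alpha_two_tailed
        cmap = canape_classify(
            significance_ranks(ens, "PE_actual", "high", a),
            significance_ranks(ens, "PE_equalized", "high", a),
            significance_ranks(ens, "RPE", "two", a),
            cfg,
        )
        assert set(cmap.categories) <= set(CATEGORIES)
        assert cmap.counts().sum() == len(ens.cells)
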