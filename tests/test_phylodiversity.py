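"""Faith PD, its null-model effect size, and fair-proportion ED."""

import numpy as np
import pytest

from herpatlas.gridding import build_grid
from herpatlas.phylodiversity import (
    NullModelConfig,
    PhyloIndex,
    ed_map,
    fair_proportion_ed,
    faith_pd,
    pd_map,
    pd_richness_correlation,
    pd_ses,
    prune_tree,
)
from herpatlas.synthetic import simulate_tree
from herpatlas.tree import Tree, TreeError


def brute_force_pd(tree: Tree, species: set) -> float:
    """Independent oracle: explicitly accumulate the branch union."""
    by_name = {t.name: t for t in tree.tips()}
    branches = set()
    for sp in species:
        node = by_name[sp]
        while node.parent is not None:
            branches.add(id(node))
            node = node.parent
    return sum(n.length for n in tree.preorder() if id(n) in branches)


class TestPrune:
    def test_path_lengths_conserved(self, caterpillar_tree):
        pruned = prune_tree(caterpillar_tree, {"A", "C"})
        assert sorted(pruned.tip_labels) == ["A", "C"]
        depths = pruned.tip_depths()
        assert depths["A"] == pytest.approx(2.0)
        assert depths["C"] == pytest.approx(2.0)
        assert pruned.total_branch_length == pytest.approx(4.0)

    def test_keep_all_is_identity(self, balanced_tree):
        pruned = prune_tree(balanced_tree, balanced_tree.tip_labels)
        assert pruned.patristic_distances() == balanced_tree.patristic_distances()
        assert pruned.total_branch_length == balanced_tree.total_branch_length

    def test_ultrametric_depth_preserved(self):
        tree = simulate_tree(12, 0.1, seed=4)
        depth = max(tree.tip_depths().values())
        pruned = prune_tree(tree, tree.tip_labels[:5])
        for d in pruned.tip_depths().values():
            assert d == pytest.approx(depth, rel=1e-9)

    def test_patristic_distances_preserved_exactly(self):
        tree = simulate_tree(16, 0.08, seed=9)
        keep = tree.tip_labels[::2]
        pruned = prune_tree(tree, keep)
        full = tree.patristic_distances()
        for pair, d in pruned.patristic_distances().items():
            assert d == pytest.approx(full[pair], rel=1e-9)

    def test_empty_and_unknown_keep_error(self, balanced_tree):
        with pytest.raises(TreeError):
            prune_tree(balanced_tree, set())
        with pytest.raises(TreeError, match="ghost"):
            prune_tree(balanced_tree, {"A", "ghost"})


class TestFaithPD:
    def test_single_tip_is_root_path(self, balanced_tree):
        assert faith_pd(balanced_tree, {"A"}) == pytest.approx(2.0)

    def test_all_tips_is_total_length(self, balanced_tree):
        assert faith_pd(balanced_tree, {"A", "B", "C", "D"}) == pytest.approx(6.0)

    def test_two_distant_tips_union(self, balanced_tree):
        assert faith_pd(balanced_tree, {"A", "C"}) == pytest.approx(4.0)

    def test_empty_set_errors(self, balanced_tree):
        with pytest.raises(ValueError):
            faith_pd(balanced_tree, set())

    def test_monotone_under_set_inclusion(self):
        tree = simulate_tree(10, 0.1, seed=2)
        index = PhyloIndex(tree)
        rng = np.random.default_rng(0)
        labels = tree.tip_labels
        for _ in range(50):
            small = set(rng.choice(labels, size=3, replace=False))
            big = small | set(rng.choice(labels, size=4, replace=False))
            assert index.pd(big) >= index.pd(small) - 1e-12

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for seed in range(20):
            tree = simulate_tree(16, 0.1, seed=seed)
            index = PhyloIndex(tree)
            for _ in range(20):
                k = int(rng.integers(1, 17))
                sub = set(rng.choice(tree.tip_labels, size=k, replace=False))
                assert index.pd(sub) == pytest.approx(
                    brute_force_pd(tree, sub), rel=1e-12)


class TestPDMap:
    def test_cells_score_their_communities(self, balanced_tree):
        grid = build_grid((0, 2, 0, 2), 1.0)
        ranges = {"A": {(0, 0), (0, 1)}, "B": {(0, 0)}, "C": {(1, 1)},
                  "D": {(0, 0)}}
        m = pd_map(ranges, balanced_tree, grid)
        assert m.values[(0, 0)] == pytest.approx(
            brute_force_pd(balanced_tree, {"A", "B", "D"}))
        assert m.values[(1, 1)] == pytest.approx(2.0)  # single species
        assert (1, 0) not in m.values

    def test_superset_ranges_dominate(self, balanced_tree):
        grid = build_grid((0, 2, 0, 2), 1.0)
        occ = {"A": {(0, 0)}, "B": {(1, 1)}}
        sdm = {"A": {(0, 0), (1, 1)}, "B": {(0, 0), (1, 1)}}
        m_occ = pd_map(occ, balanced_tree, grid)
        m_sdm = pd_map(sdm, balanced_tree, grid)
        for cell, v in m_occ.values.items():
            assert m_sdm.values[cell] >= v

    def test_unknown_species_error(self, balanced_tree):
        grid = build_grid((0, 1, 0, 1), 1.0)
        with pytest.raises(TreeError, match="zz"):
            pd_map({"zz": {(0, 0)}}, balanced_tree, grid)


class TestPDSES:
    def test_whole_pool_is_degenerate(self, balanced_tree):
        ses, p, flag = pd_ses(balanced_tree, {"A", "B", "C", "D"},
                              ["A", "B", "C", "D"])
        assert (ses, p, flag) == (0.0, 1.0, False)

    def test_null_calibration_quick(self):
        """Communities drawn from the null are flagged at ~alpha rate."""
        tree = simulate_tree(20, 0.08, seed=3)
        index = PhyloIndex(tree)
        pool = tree.tip_labels
        rng = np.random.default_rng(10)
        hits = 0
        trials = 200
        for i in range(trials):
            comm = set(rng.choice(pool, size=6, replace=False))
            _, _, flag = pd_ses(index, comm, pool,
                                NullModelConfig(n_draws=300, seed=i))
            hits += flag
        # binomial(200, 0.05): 99% interval roughly [2, 19]
        assert 1 <= hits <= 20

    def test_clustered_subset_flags_negative(self):
        # two well-separated clades: picking one clade only is clustered
        tree = Tree.from_newick(
            "((A:1,B:1,C:1,D:1,E:1,F:1):99,"
            "(G:1,H:1,I:1,J:1,K:1,L:1):99);")
        ses, p, flag = pd_ses(tree, {"A", "B", "C", "D", "E", "F"},
                              tree.tip_labels, NullModelConfig(2000, seed=0))
        assert ses < 0
        assert flag and p <= 0.05


class TestFairProportionED:
    def test_worked_example(self, caterpillar_tree):
        ed = fair_proportion_ed(caterpillar_tree).set_index("species")["ed"]
        assert ed["A"] == pytest.approx(1.5)
        assert ed["B"] == pytest.approx(1.5)
        assert ed["C"] == pytest.approx(2.0)

    def test_star_tree_symmetry(self):
        tree = Tree.from_newick("(A:3,B:3,C:3,D:3);")
        ed = fair_proportion_ed(tree)
        np.testing.assert_allclose(ed["ed"], 3.0)

    def test_ed_sums_to_total_branch_length(self):
        for seed in range(30):
            tree = simulate_tree(int(5 + seed % 20), 0.1, seed=seed)
            ed = fair_proportion_ed(tree)
            assert ed["ed"].sum() == pytest.approx(
                tree.total_branch_length, rel=1e-6)

    def test_categories_boundaries_belong_to_medium(self):
        from herpatlas.phylodiversity import ed_category

        assert ed_category(47.999) == "low"
        assert ed_category(48.0) == "medium"
        assert ed_category(96.0) == "medium"
        assert ed_category(96.001) == "high"


class TestEDMap:
    def test_cell_mean(self, caterpillar_tree):
        grid = build_grid((0, 2, 0, 2), 1.0)
        ed = fair_proportion_ed(caterpillar_tree)
        m = ed_map({"A": {(0, 0)}, "C": {(0, 0)}, "B": {(1, 1)}}, ed, grid)
        assert m.values[(0, 0)] == pytest.approx((1.5 + 2.0) / 2)
        # single-species cell carries that species' own ED
        assert m.values[(1, 1)] == pytest.approx(1.5)

    def test_cell_with_all_species_is_global_mean(self, balanced_tree):
        grid = build_grid((0, 1, 0, 1), 1.0)
        ed = fair_proportion_ed(balanced_tree)
        m = ed_map({sp: {(0, 0)} for sp in balanced_tree.tip_labels}, ed, grid)
        assert m.values[(0, 0)] == pytest.approx(ed["ed"].mean())


class TestCorrelation:
    def grid(self):
        return build_grid((0, 10, 0, 1), 1.0)

    def test_identical_maps_r_one(self):
        from herpatlas.gridding import CellMetricMap

        vals = {(0, c): float(c) for c in range(5)}
        a = CellMetricMap(self.grid(), vals, "PD")
        b = CellMetricMap(self.grid(), dict(vals), "richness")
        assert pd_richness_correlation(a, b) == pytest.approx(1.0)

    def test_linear_with_vanishing_noise(self):
        from herpatlas.gridding import CellMetricMap

        rng = np.random.default_rng(0)
        rich = {(0, c): float(c + 1) for c in range(10)}
        for sigma, bound in [(1.0, 0.9), (1e-6, 1 - 1e-9)]:
            pd_vals = {k: 2 * v + sigma * rng.standard_normal()
                       for k, v in rich.items()}
            r = pd_richness_correlation(
                CellMetricMap(self.grid(), pd_vals, "PD"),
                CellMetricMap(self.grid(), rich, "richness"))
            assert r > bound

    def test_anti_ordered_maps_negative(self):
        from herpatlas.gridding import CellMetricMap

        rich = {(0, c): float(c) for c in range(5)}
        pd_vals = {(0, c): float(-c) for c in range(5)}
        r = pd_richness_correlation(
            CellMetricMap(self.grid(), pd_vals, "PD"),
            CellMetricMap(self.grid(), rich, "richness"))
        assert r == pytest.approx(-1.0)
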