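"""Fitch scoring, exact/heuristic search, CI/RI, bootstrap and consensus."""

import numpy as np
import pytest

from karyophylo.coding import MISSING, CharacterDef, CharacterMatrix
from karyophylo.parsimony import (
    SearchError,
    bootstrap,
    canonical_newick,
    char_max_steps,
    char_min_steps,
    ci_ri,
    fitch_length,
    majority_consensus,
    rf_distance,
    search_branch_and_bound,
    search_exhaustive,
    search_heuristic,
    strict_consensus,
    tree_splits,
)

from conftest import (
    brute_force_parsimony,
    matrix_from_rows,
    quartet_tree,
    random_binary_tree,
    random_matrix,
)

ABCD = ["A", "B", "C", "D"]


class TestFitchLength:
    def test_congruent_quartet_pattern_needs_one_step(self):
        tree = quartet_tree("((A,B),(C,D));", ABCD)
        m = matrix_from_rows(ABCD, ["0", "0", "1", "1"])
        assert fitch_length(tree, m) == (1, [1])

    def test_incongruent_quartet_pattern_needs_two_steps(self):
        tree = quartet_tree("((A,B),(C,D));", ABCD)
        m = matrix_from_rows(ABCD, ["0", "1", "0", "1"])
        assert fitch_length(tree, m) == (2, [2])

    def test_all_missing_column_costs_nothing(self):
        tree = quartet_tree("((A,B),(C,D));", ABCD)
        m = matrix_from_rows(ABCD, ["?", "?", "?", "?"])
        assert fitch_length(tree, m) == (0, [0])

    def test_length_invariant_under_rerooting_and_leaf_order(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, 6, 8)
        t1 = quartet_tree("(((T0,T1),(T2,T3)),(T4,T5));", m.taxa)
        t2 = quartet_tree("((T4,T5),((T3,T2),(T1,T0)));", m.taxa)
        assert fitch_length(t1, m)[0] == fitch_length(t2, m)[0]

    def test_leaf_mismatch_raises(self):
        tree = quartet_tree("((A,B),(C,D));", ABCD)
        m = matrix_from_rows(["A", "B", "C", "E"], ["0", "0", "1", "1"])
        with pytest.raises(SearchError, match="match"):
            fitch_length(tree, m)

    def test_matches_brute_force_on_small_trees(self):
        rng = np.random.default_rng(12)
        for n in (4, 5, 6):
            taxa = [f"T{i}" for i in range(n)]
            for _ in range(10):
                tree = random_binary_tree(rng, taxa)
                m = random_matrix(rng, n, 5, missing_frac=0.15)
                L, steps = fitch_length(tree, m)
                expect = [
                    brute_force_parsimony(tree, m.cells[:, j], taxa)
                    for j in range(m.n_characters)
                ]
                assert steps == expect
                assert L == sum(expect)


class TestStepBounds:
    @pytest.mark.parametrize(
        "col,lo,hi",
        [
            ("0011", 1, 2),
            ("0000", 0, 0),
            ("0111111", 1, 1),
            ("??01", 1, 1),
            ("????", 0, 0),
        ],
    )
    def test_min_max_steps(self, col, lo, hi):
        code = {"0": 0, "1": 1, "?": MISSING}
        arr = np.array([code[c] for c in col], dtype=np.int8)
        assert char_min_steps(arr) == lo
        assert char_max_steps(arr) == hi


class TestCiRi:
    def test_perfectly_congruent_matrix(self):
        tree = quartet_tree("((A,B),(C,D));", ABCD)
        m = matrix_from_rows(ABCD, ["00", "00", "11", "11"])
        assert ci_ri(tree, m) == (1.0, 1.0)

    def test_single_homoplastic_character(self):
        # the 0011 pattern needs 2 steps on the ((A,C),(B,D)) tree:
        # M=1, L=2, G=2 ⇒ CI=0.5, RI=0
        tree = quartet_tree("((A,C),(B,D));", ABCD)
        m = matrix_from_rows(ABCD, ["0", "0", "1", "1"])
        ci, ri = ci_ri(tree, m)
        assert (ci, ri) == (0.5, 0.0)

    def test_zero_length_defines_ci_as_one(self):
        tree = quartet_tree("((A,B),(C,D));", ABCD)
        m = matrix_from_rows(ABCD, ["0", "0", "0", "0"])
        assert ci_ri(tree, m, exclude_uninformative=False) == (1.0, 1.0)


class TestExactSearch:
    def test_four_taxon_enumeration_has_three_topologies(self):
        m = matrix_from_rows(ABCD, ["00", "00", "11", "11"])
        res = search_exhaustive(m)
        assert res.n_topologies_examined == 3
        assert res.length == 2
        assert res.n_optimal == 1

    def test_six_taxon_enumeration_has_105_topologies(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng, 6, 6)
        res = search_exhaustive(m)
        assert res.n_topologies_examined == 105

    def test_over_limit_points_to_branch_and_bound(self):
        rng = np.random.default_rng(2)
        m = random_matrix(rng, 12, 4)
        with pytest.raises(SearchError, match="branch_and_bound"):
            search_exhaustive(m)

    def test_branch_and_bound_matches_exhaustive(self):
        rng = np.random.default_rng(3)
        for trial in range(8):
            m = random_matrix(rng, 7, 12)
            e = search_exhaustive(m)
            b = search_branch_and_bound(m)
            assert e.length == b.length
            assert {tree_splits(t) for t in e.optimal_trees} == {
                tree_splits(t) for t in b.optimal_trees
            }

    def test_congruent_matrix_recovers_generating_tree(self):
        # characters exactly the splits of a 7-taxon caterpillar
        taxa = [f"T{i}" for i in range(7)]
        rows = {t: "" for t in taxa}
        for k in range(2, 6):
            for i, t in enumerate(taxa):
                rows[t] += "1" if i < k else "0"
        m = matrix_from_rows(taxa, [rows[t] for t in taxa])
        res = search_branch_and_bound(m)
        assert res.length == 4  # one step per character
        assert res.n_optimal == 1
        truth = quartet_tree("((((((T0,T1),T2),T3),T4),T5),T6);", taxa)
        assert tree_splits(res.optimal_trees[0]) == tree_splits(truth)

    def test_uninformative_character_does_not_change_optima(self):
        rng = np.random.default_rng(4)
        m = random_matrix(rng, 6, 8, missing_frac=0)
        base = search_branch_and_bound(m)
        cells = np.hstack(
            [m.cells, np.array([[1], [0], [0], [0], [0], [0]], dtype=np.int8)]
        )
        chars = list(m.characters) + [CharacterDef(99, "autapo")]
        m2 = CharacterMatrix(list(m.taxa), chars, cells)
        res = search_branch_and_bound(m2)
        assert res.length == base.length + 1
        assert {tree_splits(t) for t in res.optimal_trees} == {
            tree_splits(t) for t in base.optimal_trees
        }


class TestHeuristicSearch:
    def test_never_beats_exact_and_usually_matches(self):
        rng = np.random.default_rng(6)
        hits = 0
        for trial in range(20):
            m = random_matrix(rng, 8, 14)
            h = search_heuristic(m, n_starts=10, seed=trial)
            b = search_branch_and_bound(m)
            assert h.length >= b.length
            hits += h.length == b.length
        assert hits >= 19  # ≥95 % of random matrices

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(8)
        m = random_matrix(rng, 8, 10)
        r1 = search_heuristic(m, n_starts=1, seed=123)
        r2 = search_heuristic(m, n_starts=1, seed=123)
        assert r1.length == r2.length
        assert [canonical_newick(t) for t in r1.optimal_trees] == [
            canonical_newick(t) for t in r2.optimal_trees
        ]

    def test_congruent_matrix_reaches_zero_homoplasy_bound(self):
        taxa = [f"T{i}" for i in range(6)]
        m = matrix_from_rows(
            taxa, ["11", "11", "10", "00", "00", "00"]
        )
        res = search_heuristic(m, n_starts=5, seed=0)
        min_total = sum(
            char_min_steps(m.cells[:, j]) for j in range(m.n_characters)
        )
        assert res.length == min_total


class TestConsensusAndBootstrap:
    def test_consensus_of_identical_trees_is_that_tree(self):
        t = quartet_tree("((A,B),(C,D));", ABCD)
        for cons in (strict_consensus, majority_consensus):
            c = cons([t, t, t])
            assert tree_splits(c) == tree_splits(t)

    def test_consensus_of_all_quartets_is_star(self):
        trees = [
            quartet_tree(nwk, ABCD)
            for nwk in ["((A,B),(C,D));", "((A,C),(B,D));", "((A,D),(B,C));"]
        ]
        assert tree_splits(strict_consensus(trees)) == frozenset()
        assert tree_splits(majority_consensus(trees)) == frozenset()

    def test_majority_keeps_two_thirds_clades(self):
        taxa = ["A", "B", "C", "D", "E"]
        t1 = quartet_tree("(((A,B),C),(D,E));", taxa)
        t2 = quartet_tree("(((A,C),B),(D,E));", taxa)
        c = majority_consensus([t1, t1, t2], threshold=0.5)
        splits = tree_splits(c)

        def norm(labels):  # splits are stored on the side not containing "A"
            side = frozenset(labels)
            return side if "A" not in side else frozenset(taxa) - side

        assert norm({"A", "B"}) in splits  # 2/3 of trees
        assert norm({"D", "E"}) in splits  # 3/3
        supports = {
            frozenset(lf.taxon.label for lf in nd.leaf_iter()): nd.support
            for nd in c.preorder_internal_node_iter()
            if nd.parent_node is not None
        }
        assert supports[norm({"D", "E"})] == pytest.approx(100.0)
        assert supports[norm({"A", "B"})] == pytest.approx(100 * 2 / 3)

    def test_leaf_set_mismatch_raises(self):
        t1 = quartet_tree("((A,B),(C,D));", ABCD)
        t2 = quartet_tree("((A,B),(C,E));", ["A", "B", "C", "E"])
        with pytest.raises(SearchError, match="leaf"):
            strict_consensus([t1, t2])

    def test_perfect_clade_gets_full_support(self):
        taxa = ["A", "B", "C", "D", "E"]
        m = matrix_from_rows(taxa, ["11", "11", "00", "00", "00"])
        tree = bootstrap(m, replicates=30, seed=5, search="bnb")
        supports = {
            frozenset(lf.taxon.label for lf in nd.leaf_iter()): nd.support
            for nd in tree.preorder_internal_node_iter()
            if nd.parent_node is not None
        }
        # the A,B clade is stored on its complement side (A-free convention)
        assert supports[frozenset({"C", "D", "E"})] == pytest.approx(100.0)
        for s in supports.values():
            assert 0 <= s <= 100

    def test_bootstrap_requires_seed(self):
        m = matrix_from_rows(ABCD, ["00", "01", "10", "11"])
        with pytest.raises(SearchError, match="seed"):
            bootstrap(m, replicates=2)


def test_rf_distance_basics():
    t1 = quartet_tree("((A,B),(C,D));", ABCD)
    t2 = quartet_tree("((A,C),(B,D));", ABCD)
    assert rf_distance(t1, t1) == 0
    assert rf_distance(t1, t2) == 2
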