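"""Sankoff scoring, tree search, fit indices, bootstrap, consensus."""

import itertools

import numpy as np
import pytest

from tipchron.parsimony import (bootstrap_support, consistency_indices,
                                enumerate_topologies, exhaustive_search,
                                heuristic_search, majority_rule_allcompat,
                                root_on_outgroup, sankoff_score,
                                strict_consensus)
from tipchron.matrix import build_step_matrix
from tipchron.trees import Tree, bipartitions
from conftest import make_matrix, random_raw_matrix
from tipchron.matrix import recode_polymorphisms


def brute_force_score(tree, matrix, scheme="equal"):
    """Independent oracle: enumerate every internal-state assignment."""
    total = 0.0
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    taxon_row = {t: i for i, t in enumerate(matrix.taxa)}
    for j, meta in enumerate(matrix.char_meta):
        cost = build_step_matrix(meta, scheme).cost
        k = meta.n_states
        best = np.inf
        leaf_sets = {}
        for n in nodes:
            if n.is_leaf:
                cell = matrix.recoded[taxon_row[n.label]][j]
                if cell is None:
                    leaf_sets[id(n)] = list(range(k))
                elif isinstance(cell, frozenset):
                    leaf_sets[id(n)] = sorted(cell)
                else:
                    leaf_sets[id(n)] = [cell]
        leaf_choices = [leaf_sets[id(n)] for n in nodes if n.is_leaf]
        leaves = [n for n in nodes if n.is_leaf]
        for internal_states in itertools.product(range(k), repeat=len(internal)):
            assign = {id(n): s for n, s in zip(internal, internal_states)}
            for leaf_states in itertools.product(*leaf_choices):
                for n, s in zip(leaves, leaf_states):
                    assign[id(n)] = s
                steps = sum(cost[assign[id(n)], assign[id(n.parent)]]
                            for n in nodes if n.parent is not None)
                best = min(best, steps)
        total += best
    return total


class TestSankoff:
    def test_constant_character_zero_steps(self, quartet_tree):
        m = make_matrix("ABCD", [[1, 1, 1, 1]], [False])
        assert sankoff_score(quartet_tree, m) == 0.0

    def test_ordered_quartet_equals_brute_force(self, four_taxon_ordered,
                                                quartet_tree):
        got = sankoff_score(quartet_tree, four_taxon_ordered)
        assert got == 2.0
        assert got == brute_force_score(quartet_tree, four_taxon_ordered)

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("scheme", ["equal", "half_step"])
    def test_random_matrices_match_brute_force(self, seed, scheme):
        rng = np.random.default_rng(seed)
        m = recode_polymorphisms(random_raw_matrix(rng, n_taxa=5, n_char=4))
        tree = Tree.from_newick("((T0,T1),(T2,(T3,T4)));")
        assert sankoff_score(tree, m, scheme) == pytest.approx(
            brute_force_score(tree, m, scheme), abs=1e-9)

    def test_rerooting_invariance(self):
        rng = np.random.default_rng(7)
        m = recode_polymorphisms(random_raw_matrix(rng, n_taxa=5, n_char=6))
        t1 = Tree.from_newick("((T0,T1),(T2,(T3,T4)));")
        t2 = Tree.from_newick("(((T2,(T3,T4)),T1),T0);")  # same unrooted tree
        assert bipartitions(t1) == bipartitions(t2)
        for scheme in ("equal", "half_step"):
            assert sankoff_score(t1, m, scheme) == pytest.approx(
                sankoff_score(t2, m, scheme))

    def test_half_step_never_exceeds_equal(self):
        rng = np.random.default_rng(13)
        for seed in range(5):
            m = recode_polymorphisms(random_raw_matrix(
                np.random.default_rng(seed), n_taxa=6, n_char=10))
            tree = Tree.from_newick("((T0,T1),((T2,T3),(T4,T5)));")
            assert (sankoff_score(tree, m, "half_step")
                    <= sankoff_score(tree, m, "equal") + 1e-12)

    def test_taxon_mismatch_reported(self, four_taxon_ordered):
        tree = Tree.from_newick("((A,B),(C,X));")
        with pytest.raises(ValueError, match="X"):
            sankoff_score(tree, four_taxon_ordered)


class TestSearch:
    def test_topology_count(self):
        trees = list(enumerate_topologies(list("ABCDE")))
        keys = {frozenset(bipartitions(t)) for t in trees}
        assert len(keys) == 15

    def test_search_matches_exhaustive_minimum(self, four_taxon_ordered):
        res = heuristic_search(four_taxon_ordered, n_reps=3, seed=0)
        ex = exhaustive_search(four_taxon_ordered)
        assert res.best_score == pytest.approx(ex.best_score)
        assert res.best_score == 2.0

    def test_all_constant_scores_zero(self):
        m = make_matrix("ABCDE", [[0] * 5, [1] * 5], [False, False])
        res = heuristic_search(m, n_reps=2, seed=1)
        assert res.best_score == 0.0

    def test_invalid_reps(self, four_taxon_ordered):
        with pytest.raises(ValueError):
            heuristic_search(four_taxon_ordered, n_reps=0)

    def test_never_below_exhaustive_and_usually_equal(self):
        hits = 0
        n = 20
        for seed in range(n):
            rng = np.random.default_rng(1000 + seed)
            m = recode_polymorphisms(random_raw_matrix(rng, n_taxa=6,
                                                       n_char=20))
            ex = exhaustive_search(m)
            res = heuristic_search(m, n_reps=5, seed=seed)
            assert res.best_score >= ex.best_score - 1e-9
            hits += abs(res.best_score - ex.best_score) < 1e-9
        assert hits >= 0.95 * n

    def test_root_on_outgroup(self):
        t = Tree.from_newick("((A,B),(C,D),E);")
        rooted = root_on_outgroup(t, "E")
        assert rooted.root.children[0].label == "E"
        assert sorted(rooted.leaf_labels()) == list("ABCDE")
        assert bipartitions(rooted) == bipartitions(t)


class TestIndices:
    def test_perfect_matrix_ceiling(self):
        m = make_matrix("ABCD", [[0, 0, 1, 1], [1, 1, 0, 0]], [False, False])
        tree = Tree.from_newick("((A,B),(C,D));")
        idx = consistency_indices(m, tree)
        assert idx["CI_excl"] == pytest.approx(1.0)
        assert idx["RI"] == pytest.approx(1.0)

    def test_single_character_hand_arithmetic(self):
        # 0,0,0,1,1,1 arranged so the character changes twice on the tree:
        # s=2 (verified by brute force), m=1, g=3 -> CI=0.5, RI=0.5
        m = make_matrix("ABCDEF", [[0, 0, 0, 1, 1, 1]], [False])
        tree = Tree.from_newick("(((A,B),D),((E,F),C));")
        s = brute_force_score(tree, m)
        assert s == 2.0
        idx = consistency_indices(m, tree)
        assert idx["CI_excl"] == pytest.approx(1.0 / s)
        assert idx["RI"] == pytest.approx((3.0 - s) / (3.0 - 1.0))
        assert idx["tree_length"] == pytest.approx(s)

    def test_all_constant_undefined(self):
        m = make_matrix("ABCD", [[0, 0, 0, 0]], [False])
        tree = Tree.from_newick("((A,B),(C,D));")
        idx = consistency_indices(m, tree)
        assert idx["CI_excl"] is None


class TestBootstrap:
    def test_uncontradicted_signal_near_full_support(self):
        cols = [[0, 0, 1, 1]] * 10
        m = make_matrix("ABCD", cols, [False] * 10)
        support = bootstrap_support(m, n_pseudoreplicates=30, seed=4,
                                    n_reps_per_replicate=3)
        key = frozenset({"A", "B"})
        # canonical split key excludes the reference taxon A
        keys = {k for k in support}
        target = [k for k in keys if k in (frozenset({"C", "D"}),
                                           frozenset({"A", "B"}))]
        assert target and support[target[0]] >= 90.0

    def test_uninformative_matrix_low_support(self):
        m = make_matrix("ABCD", [[0, 1, 2, 3], [3, 2, 1, 0]], [False, False])
        support = bootstrap_support(m, n_pseudoreplicates=30, seed=5,
                                    n_reps_per_replicate=3)
        assert all(v <= 60.0 for v in support.values())


class TestConsensus:
    def test_allcompat_example(self):
        t1 = Tree.from_newick("((A,B),(C,D));")
        t2 = Tree.from_newick("((A,C),(B,D));")
        cons, freqs = majority_rule_allcompat([t1, t1, t2])
        assert bipartitions(cons) == bipartitions(t1)
        ab_key = [k for k in freqs if k in (frozenset({"C", "D"}),
                                            frozenset({"B", "C", "D"}))]
        assert any(abs(v - 2 / 3) < 1e-9 for v in freqs.values())

    def test_identical_inputs_identity(self):
        t = Tree.from_newick("((A,B),((C,D),E));")
        assert bipartitions(strict_consensus([t, t, t])) == bipartitions(t)
        cons, _ = majority_rule_allcompat([t, t])
        assert bipartitions(cons) == bipartitions(t)

    def test_conflict_gives_star(self):
        t1 = Tree.from_newick("((A,B),(C,D));")
        t2 = Tree.from_newick("((A,C),(B,D));")
        t3 = Tree.from_newick("((A,D),(B,C));")
        assert bipartitions(strict_consensus([t1, t2, t3])) == set()

    def test_leafset_mismatch_rejected(self):
        t1 = Tree.from_newick("((A,B),(C,D));")
        t2 = Tree.from_newick("((A,B),(C,E));")
        with pytest.raises(ValueError):
            strict_consensus([t1, t2])

    @pytest.mark.parametrize("seed", range(5))
    def test_allcompat_refines_majority(self, seed):
        rng = np.random.default_rng(seed)
        labels = list("ABCDEF")
        trees = []
        for _ in range(7):
            t = next(iter(_random_topology(labels, rng)))
            trees.append(t)
        cons, freqs = majority_rule_allcompat(trees)
        majority = {c for c, f in freqs.items() if f > 0.5}
        assert majority <= bipartitions(cons)


def _random_topology(labels, rng):
    from tipchron.parsimony import enumerate_topologies
    all_t = list(enumerate_topologies(labels[:5]))
    t = all_t[int(rng.integers(len(all_t)))]
    # attach remaining labels randomly by simple insertion
    from tipchron.parsimony import _copy_with_map, _edges, _insert_on_edge
    for lab in labels[5:]:
        t, mapping = _copy_with_map(t)
        edges = _edges(t)
        _insert_on_edge(edges[int(rng.integers(len(edges)))], lab)
    yield t
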