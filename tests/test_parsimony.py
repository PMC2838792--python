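"""Parsimony scoring, ratchet/SPR search, consensus, and change mapping."""

import numpy as np
import pandas as pd
import pytest

from cladelink.io import TraitMatrix
from cladelink.parsimony import (PhenoTree, TreeSet, majority_consensus,
                                 map_trait_changes, parsimony_score,
                                 ratchet_search, spr_refine)
from cladelink.reference import exhaustive_parsimony


def _chain_tree(labels):
    """Caterpillar tree over the given leaf labels."""
    n = len(labels)
    adj = {}
    lab = {}
    for i, l in enumerate(labels):
        lab[i] = l
    internals = list(range(n, 2 * n - 2))
    adj[internals[0]] = [0, 1, internals[1] if len(internals) > 1 else 2]
    for j in range(1, len(internals)):
        prev = internals[j - 1]
        nxt = internals[j + 1] if j + 1 < len(internals) else n - 1
        adj[internals[j]] = [prev, j + 1, nxt]
    if len(internals) == 1:
        adj[internals[0]] = [0, 1, 2]
    for i in range(n):
        # attach each leaf to whichever internal lists it
        owner = next(v for v in internals if i in adj[v])
        adj[i] = [owner]
    return PhenoTree(adj, lab)


class TestScore:
    def test_identical_rows_score_zero(self):
        m = TraitMatrix(pd.DataFrame(np.ones((5, 4)),
                                     index=[f"I:{k}" for k in range(5)],
                                     columns=list("abcd")))
        tree = _chain_tree(m.individual_ids)
        assert parsimony_score(tree, m) == 0

    def test_single_differing_leaf_scores_one(self):
        arr = np.zeros((5, 3))
        arr[2, 1] = 1
        m = TraitMatrix(pd.DataFrame(arr, index=[f"I:{k}" for k in range(5)],
                                     columns=list("abc")))
        assert parsimony_score(_chain_tree(m.individual_ids), m) == 1

    def test_matches_exhaustive_minimum_on_random_instance(self, random_matrix):
        m = random_matrix(6, 12, seed=17)
        best = exhaustive_parsimony(m)
        ts = ratchet_search(m, n_iterations=30, seed=3)
        assert ts.score == best
        for t in ts.trees:
            assert parsimony_score(t, m) == best

    def test_score_invariant_under_leaf_relabeling(self, random_matrix):
        m = random_matrix(7, 9, seed=4, missing=0.1)
        ts = ratchet_search(m, n_iterations=10, seed=0)
        tree = ts.trees[0]
        s = parsimony_score(tree, m)
        # permute which node carries which label; score depends only on data
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.individual_ids)
        mapping = dict(zip(m.individual_ids, perm))
        relabeled = PhenoTree(tree.adj, {u: mapping[l] for u, l in tree.labels.items()})
        frame = m.frame.rename(index=mapping)
        assert parsimony_score(relabeled, TraitMatrix(frame, m.trait_kinds)) == s

    def test_wagner_at_least_fitch(self):
        rng = np.random.default_rng(11)
        arr = rng.integers(0, 4, size=(6, 5)).astype(float)
        idx = [f"I:{k}" for k in range(6)]
        cols = [f"t{j}" for j in range(5)]
        m_ord = TraitMatrix(pd.DataFrame(arr, index=idx, columns=cols))
        assert all(k == "ordinal4" for k in m_ord.trait_kinds.values())
        tree = _chain_tree(idx)
        wagner = parsimony_score(tree, m_ord, ordered_ordinal=True)
        fitch = parsimony_score(tree, m_ord, ordered_ordinal=False)
        assert wagner >= fitch

    def test_missing_states_are_free(self):
        arr = np.array([[0.0], [np.nan], [1.0], [np.nan]])
        m = TraitMatrix(pd.DataFrame(arr, index=[f"I:{k}" for k in range(4)],
                                     columns=["a"]))
        assert parsimony_score(_chain_tree(m.individual_ids), m) == 1


class TestRatchet:
    def test_perfect_phylogeny_score_is_variable_character_count(self, toy):
        matrix, expected = toy
        ts = ratchet_search(matrix, n_iterations=10, seed=0)
        assert ts.score == expected["score"]

    def test_deterministic_under_seed(self, random_matrix):
        m = random_matrix(7, 10, seed=8)
        a = ratchet_search(m, n_iterations=15, seed=5)
        b = ratchet_search(m, n_iterations=15, seed=5)
        assert a.score == b.score
        assert [t.bipartitions() for t in a.trees] == \
            [t.bipartitions() for t in b.trees]

    def test_small_input_returns_trivial_topology(self, random_matrix):
        m = random_matrix(3, 5, seed=1)
        ts = ratchet_search(m, seed=0)
        assert len(ts.trees) == 1
        assert ts.trees[0].leaf_labels == frozenset(m.individual_ids)
        assert ts.score == parsimony_score(ts.trees[0], m)

    def test_equal_trees_share_leafset_and_score(self, random_matrix):
        m = random_matrix(7, 6, seed=21)
        ts = ratchet_search(m, n_iterations=20, seed=2)
        for t in ts.trees:
            assert parsimony_score(t, m) == ts.score


class TestSPRRefine:
    def test_optimal_input_unchanged_score(self, random_matrix):
        m = random_matrix(6, 10, seed=33)
        ts = ratchet_search(m, n_iterations=30, seed=1)
        refined = spr_refine(ts, m, seed=1)
        assert refined.score == ts.score == exhaustive_parsimony(m)

    def test_suboptimal_start_reaches_exhaustive_optimum(self, random_matrix):
        m = random_matrix(6, 12, seed=42)
        # deliberately poor start: caterpillar in index order
        start = _chain_tree(m.individual_ids)
        bad = TreeSet([start], parsimony_score(start, m))
        refined = spr_refine(bad, m, seed=0)
        assert refined.score == exhaustive_parsimony(m)
        assert refined.score <= bad.score

    def test_all_identical_members_star_and_zero(self):
        m = TraitMatrix(pd.DataFrame(np.zeros((5, 4)),
                                     index=[f"I:{k}" for k in range(5)],
                                     columns=list("abcd")))
        ts = ratchet_search(m, n_iterations=5, seed=0)
        assert ts.score == 0
        # identical profiles collapse to one leaf and re-expand as a star
        tree = ts.trees[0]
        hub = [u for u in tree.adj if u not in tree.labels]
        assert len(hub) == 1 and tree.degree(hub[0]) == 5


class TestConsensus:
    def test_identical_inputs_reproduced(self, random_matrix):
        m = random_matrix(7, 12, seed=3)
        ts = ratchet_search(m, n_iterations=10, seed=1)
        one = TreeSet([ts.trees[0], ts.trees[0].copy()], ts.score)
        cons = majority_consensus(one)
        assert cons.bipartitions() == ts.trees[0].bipartitions()

    def test_disjoint_trees_give_star(self):
        labels = [f"I:{k}" for k in range(6)]
        a = _chain_tree(labels)
        b = _chain_tree([labels[i] for i in (0, 2, 4, 1, 3, 5)])
        assert not a.bipartitions() & b.bipartitions()
        cons = majority_consensus(TreeSet([a, b], 0))
        assert cons.bipartitions() == set()
        hub = [u for u in cons.adj if u not in cons.labels]
        assert len(hub) == 1 and cons.degree(hub[0]) == 6

    def test_two_of_three_retained(self):
        labels = [f"I:{k}" for k in range(6)]
        a = _chain_tree(labels)
        b = _chain_tree(labels)
        c = _chain_tree([labels[i] for i in (2, 4, 0, 3, 1, 5)])
        cons = majority_consensus(TreeSet([a, b, c], 0), threshold=0.51)
        for bp in a.bipartitions():
            count = sum(bp in t.bipartitions() for t in (a, b, c))
            assert (bp in cons.bipartitions()) == (count / 3 > 0.51)

    def test_agrees_with_dendropy(self, random_matrix):
        import dendropy

        m = random_matrix(7, 7, seed=55)
        ts = ratchet_search(m, n_iterations=25, seed=9)
        if len(ts.trees) < 2:
            pytest.skip("needs several equally parsimonious trees")
        cons = majority_consensus(ts, threshold=0.51)
        taxa = dendropy.TaxonNamespace()
        dlist = dendropy.TreeList(
            [dendropy.Tree.get(data=t.to_newick(), schema="newick",
                               taxon_namespace=taxa) for t in ts.trees])
        dcons = dlist.consensus(min_freq=0.511)
        ours = PhenoTree.from_newick(dcons.as_string(schema="newick"))
        assert ours.bipartitions() == cons.bipartitions()


class TestChangeMapping:
    def test_invariant_character_no_changes(self):
        m = TraitMatrix(pd.DataFrame(np.ones((4, 2)),
                                     index=[f"I:{k}" for k in range(4)],
                                     columns=["a", "b"]))
        assert map_trait_changes(_chain_tree(m.individual_ids), m) == []

    def test_single_difference_on_pendant_edge(self):
        arr = np.zeros((5, 1))
        arr[3, 0] = 1
        m = TraitMatrix(pd.DataFrame(arr, index=[f"I:{k}" for k in range(5)],
                                     columns=["a"]))
        tree = _chain_tree(m.individual_ids)
        changes = map_trait_changes(tree, m)
        assert len(changes) == 1
        ch = changes[0]
        assert tree.labels.get(ch.child_node) == "I:3"
        assert ch.direction == "gain" and ch.steps == 1

    def test_total_steps_equal_parsimony_score(self, random_matrix):
        m = random_matrix(7, 10, seed=77, missing=0.1)
        ts = ratchet_search(m, n_iterations=15, seed=2)
        tree = ts.trees[0]
        changes = map_trait_changes(tree, m)
        assert sum(c.steps for c in changes) == parsimony_score(tree, m)
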