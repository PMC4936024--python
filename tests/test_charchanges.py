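"""Parsimony MPR sets and unambiguous change counting."""

import itertools

import numpy as np
import pytest

import paleorates as pr
from paleorates.io import CharacterMatrix, ValidationError
from oracles import all_rooted_binary_topologies, brute_branch_minima


def _matrix(labels, column, ordered=False, weight=1.0):
    return CharacterMatrix(labels, [[frozenset([s])] for s in column],
                           ordered=[ordered], weights=[weight])


def _counts_by_child_label(tree, cm):
    return {b.label or tuple(sorted(l.label for l in tree.subtree_nodes(b) if l.is_leaf)): c
            for b, c in zip(cm.branch_nodes, cm.changes)}


def test_balanced_four_tip_mpr_sets(balanced4):
    tips = {"A": frozenset({0}), "B": frozenset({0}),
            "C": frozenset({1}), "D": frozenset({1})}
    sets = pr.mpr_state_sets(balanced4, tips, ordered=False)
    by = {}
    for node in balanced4.nodes:
        if node.is_leaf:
            continue
        key = tuple(sorted(l.label for l in balanced4.subtree_nodes(node) if l.is_leaf))
        by[key] = sets[node.index]
    assert by[("A", "B")] == frozenset({0})
    assert by[("C", "D")] == frozenset({1})
    assert by[("A", "B", "C", "D")] == frozenset({0, 1})


def test_balanced_four_tip_unambiguous_counts(balanced4):
    """The single change sits on the unrooted internal edge; rooted, it can
    fall on either basal branch, so no single branch carries it in every
    MPR and all per-branch minima are zero — while the tree length is 1."""
    m = _matrix(["A", "B", "C", "D"], [0, 0, 1, 1])
    cm = pr.count_unambiguous_changes(balanced4, m)
    assert cm.tree_length == 1.0
    counts = _counts_by_child_label(balanced4, cm)
    assert counts["A"] == counts["B"] == counts["C"] == counts["D"] == 0
    assert counts[("A", "B")] == 0 and counts[("C", "D")] == 0
    assert cm.total <= cm.tree_length


def test_invariant_character_counts_nothing(balanced4):
    m = _matrix(["A", "B", "C", "D"], [0, 0, 0, 0])
    cm = pr.count_unambiguous_changes(balanced4, m)
    assert cm.total == 0.0
    sets = pr.mpr_state_sets(balanced4, {t: frozenset({0}) for t in "ABCD"})
    assert all(s == frozenset({0}) for s in sets.values())


def test_single_derived_tip_with_weight_two(balanced4):
    m = _matrix(["A", "B", "C", "D"], [0, 0, 0, 1], weight=2.0)
    cm = pr.count_unambiguous_changes(balanced4, m)
    counts = _counts_by_child_label(balanced4, cm)
    assert counts["D"] == 2.0
    assert cm.total == 2.0


def test_ordered_two_tip_spanning_states():
    tree = pr.cherry("A", "B", root_age=5.0)
    tips = {"A": frozenset({0}), "B": frozenset({2})}
    sets = pr.mpr_state_sets(tree, tips, ordered=True)
    assert sets[tree.root.index] == frozenset({0, 1, 2})
    m = CharacterMatrix(["A", "B"], [[frozenset({0})], [frozenset({2})]],
                        ordered=[True])
    cm = pr.count_unambiguous_changes(tree, m)
    assert cm.tree_length == 2.0


def test_uninformative_character_gives_full_ambiguity(balanced4):
    tips = {"A": frozenset({0}), "B": frozenset({0, 1}),
            "C": frozenset({0, 1}), "D": frozenset({0, 1})}
    sets = pr.mpr_state_sets(balanced4, tips, ordered=False,
                             state_space=[0, 1])
    # fewer than two fixed observations... the observed union is {0,1} but a
    # change is never forced anywhere:
    m = CharacterMatrix(["A", "B", "C", "D"],
                        [[frozenset({0})], [None], [None], [None]])
    cm = pr.count_unambiguous_changes(balanced4, m)
    assert cm.total == 0.0


def test_taxon_mismatch_raises(balanced4):
    m = _matrix(["A", "B", "C", "E"], [0, 0, 1, 1])
    with pytest.raises(ValidationError, match="E"):
        pr.count_unambiguous_changes(balanced4, m)


def test_counts_invariant_to_tip_order_and_child_swaps(balanced4):
    m = _matrix(["A", "B", "C", "D"], [0, 1, 0, 1])
    ref = _counts_by_child_label(balanced4, pr.count_unambiguous_changes(balanced4, m))
    # permute matrix rows
    m2 = _matrix(["D", "B", "A", "C"], [1, 1, 0, 0])
    assert _counts_by_child_label(
        balanced4, pr.count_unambiguous_changes(balanced4, m2)) == ref
    # swap children everywhere
    swapped = balanced4.copy()
    for n in swapped.nodes:
        n.children = n.children[::-1]
    swapped.reindex()
    assert _counts_by_child_label(
        swapped, pr.count_unambiguous_changes(swapped, m)) == ref


@pytest.mark.parametrize("ordered", [False, True])
def test_random_cases_match_enumeration_oracle(ordered, rng):
    """Spot-check five-tip trees against full MPR enumeration."""
    labels = list("ABCDE")
    topos = all_rooted_binary_topologies(labels)
    for _ in range(60):
        tree = topos[rng.integers(len(topos))]
        k = int(rng.integers(2, 4))
        column = [int(s) for s in rng.integers(0, k, size=5)]
        space = list(range(max(column) + 1)) if ordered else sorted(set(column))
        if len(set(column)) < 2:
            continue
        tips = {l: frozenset([s]) for l, s in zip(labels, column)}
        minima, sets, best = brute_branch_minima(tree, tips, space, ordered)
        m = _matrix(labels, column, ordered=ordered)
        cm = pr.count_unambiguous_changes(tree, m, require_ages=False)
        impl = {b.index: c for b, c in zip(cm.branch_nodes, cm.changes)}
        assert impl == {k_: float(v) for k_, v in minima.items()}
        assert cm.tree_length == best
        impl_sets = pr.mpr_state_sets(tree, tips, ordered)
        for idx, s in sets.items():
            assert impl_sets[idx] == s


def test_total_below_weighted_tree_length(record_with_matrix):
    _, rec, matrix, _ = record_with_matrix
    cm = pr.count_unambiguous_changes(rec.observed_tree, matrix)
    assert cm.total <= cm.tree_length + 1e-9
    assert len(cm.branch_nodes) == len(rec.observed_tree.branches())
    assert np.all(cm.changes >= 0)
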