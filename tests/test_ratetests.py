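"""Randomization null: conservation, calibration shape, flag logic."""

import numpy as np
import pytest

import paleorates as pr
from paleorates.charchanges import ChangeMap
from paleorates.io import TimeBin
from paleorates.ratetests import NullConfig, null_branch_counts
from paleorates.trees import Node, Tree


def test_null_counts_conserve_total_and_scale_with_duration(rng):
    durations = np.array([1.0, 9.0])
    null = null_branch_counts(durations, 10, 2000, rng)
    assert null.shape == (2000, 2)
    assert (null.sum(axis=1) == 10).all()
    assert null[:, 1].mean() == pytest.approx(9.0, rel=0.05)  # N * 9/10


def test_short_branch_with_all_changes_flagged_high():
    # two tips: durations 1 and 9 Myr, all 10 observed changes on the short
    # one; P(null puts >= 10 there) = 0.1^10
    root = Node(age=10.0)
    a = Node("short", 9.0)
    b = Node("long", 1.0)
    root.add_child(a)
    root.add_child(b)
    tree = Tree(root)
    branches = tree.branches()
    ch = np.array([10.0 if br.label == "short" else 0.0 for br in branches])
    durs = np.array([tree.duration(br) for br in branches])
    cm = ChangeMap(tree, branches, ch, durs, 10.0)
    res = pr.branch_rate_test(tree, cm, NullConfig(seed=0))
    flags = res.flags
    short_idx = [br.index for br in branches if br.label == "short"][0]
    long_idx = [br.index for br in branches if br.label == "long"][0]
    assert flags[short_idx] == "high"
    assert flags[long_idx] == "low"


def test_single_branch_tree_never_flagged():
    root = Node(age=10.0)
    root.add_child(Node("only", 0.0))
    tree = Tree(root)
    branches = tree.branches()
    cm = ChangeMap(tree, branches, np.array([7.0]), np.array([10.0]), 7.0)
    res = pr.branch_rate_test(tree, cm, NullConfig(seed=0))
    assert (res.table["flag"] == "none").all()  # observed always ties the null


def test_zero_changes_warns_and_flags_nothing(balanced4):
    branches = balanced4.branches()
    cm = ChangeMap(balanced4, branches, np.zeros(len(branches)),
                   np.array([balanced4.duration(b) for b in branches]), 0.0)
    with pytest.warns(UserWarning, match="no character changes"):
        res = pr.branch_rate_test(balanced4, cm, NullConfig(seed=0))
    assert (res.table["flag"] == "none").all()


def test_threshold_monotonicity(record_with_matrix, rng):
    _, rec, matrix, _ = record_with_matrix
    cm = pr.count_unambiguous_changes(rec.observed_tree, matrix)
    flags = {}
    for thr in (0.9, 0.95, 0.99):
        res = pr.branch_rate_test(rec.observed_tree, cm,
                                  NullConfig(threshold=thr, seed=1))
        flags[thr] = set(res.table.loc[res.table["flag"] != "none", "branch"])
    assert flags[0.99] <= flags[0.95] <= flags[0.9]


def test_clade_with_concentrated_changes_flagged_high(balanced4):
    # the (A,B) cherry holds 90% of the changes but a small share of time
    branches = balanced4.branches()
    durs = np.array([balanced4.duration(b) for b in branches])
    ch = np.zeros(len(branches))
    for i, b in enumerate(branches):
        if b.label in ("A", "B"):
            ch[i] = 45.0
        elif b.label in ("C", "D"):
            ch[i] = 5.0
    cm = ChangeMap(balanced4, branches, ch, durs, float(ch.sum()))
    shifts = pr.clade_shift_test(balanced4, cm, config=NullConfig(seed=0))
    by_tips = {}
    for _, row in shifts.iterrows():
        node = balanced4.nodes[int(row["node"])]
        key = tuple(sorted(l.label for l in balanced4.subtree_nodes(node) if l.is_leaf))
        by_tips[key] = row["flag"]
    assert by_tips[("A", "B")] == "high"
    assert by_tips[("C", "D")] == "low"
    assert ("A", "B", "C", "D") not in by_tips  # root excluded


def test_root_excluded_from_clade_test(balanced4):
    branches = balanced4.branches()
    cm = ChangeMap(balanced4, branches, np.ones(len(branches)),
                   np.array([balanced4.duration(b) for b in branches]),
                   float(len(branches)))
    shifts = pr.clade_shift_test(balanced4, cm, config=NullConfig(seed=0))
    assert len(shifts) == 2  # two cherry nodes only


def test_ties_support_neither_tail():
    # all mass forced onto one branch in every replication -> observed ties
    root = Node(age=1.0)
    root.add_child(Node("a", 0.0))
    root.add_child(Node("b", 1.0 - 1e-12))
    tree = Tree(root)
    branches = tree.branches()
    durs = np.array([tree.duration(b) for b in branches])
    ch = np.array([3.0 if b.label == "a" else 0.0 for b in branches])
    cm = ChangeMap(tree, branches, ch, durs, 3.0)
    res = pr.branch_rate_test(tree, cm, NullConfig(seed=0))
    a_row = res.table[res.table["child_label"] == "a"].iloc[0]
    assert a_row["flag"] == "none" and a_row["p_high"] == 0.0


def test_branch_spanning_two_bins_contributes_to_both(balanced4):
    bins = pr.BinTable([TimeBin("old", 12.0, 6.0), TimeBin("young", 6.0, 0.0)])
    m = pr.CharacterMatrix(["A", "B", "C", "D"],
                           [[frozenset({0})], [frozenset({0})],
                            [frozenset({0})], [frozenset({1})]])
    cm = pr.count_unambiguous_changes(balanced4, m)
    series = pr.bin_rate_series([(balanced4, cm)], bins, NullConfig(seed=0))
    t = series.table.set_index("bin")
    # cherry branches span 5-0 (young); basal branches span 10-5, crossing 6
    assert t.loc["old", "n_branches"] == 2
    assert t.loc["young", "n_branches"] == 6


def test_empty_bin_warns_and_is_skipped(balanced4):
    bins = pr.BinTable([TimeBin("ancient", 40.0, 20.0),
                        TimeBin("span", 20.0, 0.0)])
    m = pr.CharacterMatrix(["A", "B", "C", "D"],
                           [[frozenset({0})], [frozenset({0})],
                            [frozenset({0})], [frozenset({1})]])
    cm = pr.count_unambiguous_changes(balanced4, m)
    with pytest.warns(UserWarning, match="no branches overlap"):
        series = pr.bin_rate_series([(balanced4, cm)], bins, NullConfig(seed=0))
    assert list(series.table["bin"]) == ["span"]


def test_null_config_validation():
    with pytest.raises(ValueError):
        NullConfig(replications=0)
    with pytest.raises(ValueError):
        NullConfig(threshold=0.4)
    with pytest.raises(ValueError):
        NullConfig(threshold=1.0)
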