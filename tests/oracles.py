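"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive: exhaustive enumeration over ancestral
state assignments and over labelled tree topologies.  The implementations
under test must agree with these on small instances.
"""

from __future__ import annotations

import itertools

import numpy as np

from paleorates.trees import Node, Tree


def step_cost(a: int, b: int, ordered: bool) -> int:
    return abs(a - b) if ordered else int(a != b)


def enumerate_mprs(tree: Tree, tip_sets: dict, space: list, ordered: bool):
    """Yield (assignment, total_cost) for every minimum-cost full assignment.

    ``assignment`` maps node index -> state; tips range over their allowed
    sets (ambiguous tips are assigned too, as in any full reconstruction).
    """
    nodes = list(tree.postorder())
    choices = []
    for n in nodes:
        if n.is_leaf:
            choices.append(sorted(tip_sets[n.label]))
        else:
            choices.append(list(space))
    best = None
    optima = []
    for combo in itertools.product(*choices):
        assign = {n.index: s for n, s in zip(nodes, combo)}
        cost = sum(step_cost(assign[n.parent.index], assign[n.index], ordered)
                   for n in nodes if n.parent is not None)
        if best is None or cost < best:
            best = cost
            optima = [assign]
        elif cost == best:
            optima.append(assign)
    return optima, best


def brute_branch_minima(tree: Tree, tip_sets: dict, space: list, ordered: bool):
    """Per-branch minimum step count over all most-parsimonious
    reconstructions, plus the per-node MPR state sets and the tree length."""
    optima, best = enumerate_mprs(tree, tip_sets, space, ordered)
    minima = {}
    for n in tree.branches():
        minima[n.index] = min(
            step_cost(a[n.parent.index], a[n.index], ordered) for a in optima
        )
    sets = {n.index: frozenset(a[n.index] for a in optima) for n in tree.nodes}
    return minima, sets, best


def all_rooted_binary_topologies(labels: list) -> list:
    """Every labelled rooted binary tree on the given tips ((2n-3)!! trees)."""
    out = []

    def insert_all(tree_root: Node, leaf_label: str):
        # return new trees with `leaf_label` inserted on every edge incl. root
        results = []
        # collect edges as (parent, child); plus the root edge (None, root)
        edges = [(None, tree_root)]
        stack = [tree_root]
        while stack:
            n = stack.pop()
            for c in n.children:
                edges.append((n, c))
                stack.append(c)
        for k in range(len(edges)):
            clone_root = _clone(tree_root)
            cedges = [(None, clone_root)]
            cstack = [clone_root]
            while cstack:
                n = cstack.pop()
                for c in n.children:
                    cedges.append((n, c))
                    cstack.append(c)
            parent, child = cedges[k]
            joint = Node()
            leaf = Node(leaf_label)
            if parent is None:
                joint.add_child(child)
                joint.add_child(leaf)
                results.append(joint)
            else:
                parent.children[parent.children.index(child)] = joint
                joint.parent = parent
                joint.add_child(child)
                joint.add_child(leaf)
                results.append(clone_root)
        return results

    def _clone(node: Node) -> Node:
        new = Node(node.label)
        for c in node.children:
            new.add_child(_clone(c))
        return new

    roots = [Node(labels[0])]
    for lab in labels[1:]:
        roots = [r2 for r in roots for r2 in insert_all(r, lab)]
    return [Tree(r) for r in roots]


def brute_branch_minima_all(tree: Tree, k: int, ordered: bool):
    """Vectorised enumeration oracle over ALL tip-state assignments.

    For a fixed topology and a k-state character, enumerates every internal
    assignment against every tip assignment and returns, per tip
    assignment, the per-branch minimum step count over all most-
    parsimonious reconstructions plus the tree length.

    Returns ``(tip_combos, minima, lengths, branch_order)`` where
    ``tip_combos`` is (n_combos, n_tips) in ``tree.leaves`` order,
    ``minima`` is (n_combos, n_branches) in ``branch_order`` (postorder
    child indices), and ``lengths`` is (n_combos,).
    """
    leaves = tree.leaves
    internals = [n for n in tree.nodes if not n.is_leaf]
    li = {n.index: i for i, n in enumerate(leaves)}
    ii = {n.index: i for i, n in enumerate(internals)}
    n_t, n_i = len(leaves), len(internals)
    states = np.arange(k)
    tip_combos = np.array(np.meshgrid(*[states] * n_t, indexing="ij")
                          ).reshape(n_t, -1).T          # (T, n_t)
    int_combos = np.array(np.meshgrid(*[states] * n_i, indexing="ij")
                          ).reshape(n_i, -1).T          # (I, n_i)
    costmat = (np.abs(states[:, None] - states[None, :]) if ordered
               else (states[:, None] != states[None, :]).astype(int))
    T, I = len(tip_combos), len(int_combos)
    branches = tree.branches()
    edge_costs = []
    total = np.zeros((T, I), dtype=np.int64)
    for b in branches:
        p = ii[b.parent.index]
        if b.is_leaf:
            ec = costmat[int_combos[:, p][None, :], tip_combos[:, li[b.index]][:, None]]
        else:
            ec = np.broadcast_to(
                costmat[int_combos[:, p], int_combos[:, ii[b.index]]][None, :],
                (T, I))
        edge_costs.append(ec)
        total = total + ec
    lengths = total.min(axis=1)
    mask = total == lengths[:, None]
    BIG = 10 ** 6
    minima = np.stack(
        [np.where(mask, ec, BIG).min(axis=1) for ec in edge_costs], axis=1)
    return tip_combos, minima, lengths, [b.index for b in branches]


def brute_unsampled_history(p: float, q: float, r: float, rng, max_duration: float) -> float:
    """Waiting time to the first sampling event in a birth-death-sampling
    clade, by a deliberately different event-by-event scheme: every lineage
    carries its own independently drawn next-event time in a priority list.
    Rejection on extinction or overrunning ``max_duration``."""
    while True:
        # each entry: (event_time, event_kind) for one lineage, kind drawn now
        lineages = [_lineage_event(0.0, p, q, r, rng)]
        ok = None
        while lineages:
            lineages.sort(key=lambda e: e[0])
            t, kind = lineages.pop(0)
            if t >= max_duration:
                # this lineage idles past the window; drop it
                continue
            if kind == "sample":
                ok = t
                break
            if kind == "birth":
                lineages.append(_lineage_event(t, p, q, r, rng))
                lineages.append(_lineage_event(t, p, q, r, rng))
            # death: lineage simply disappears
        if ok is not None:
            return ok


def _lineage_event(t0: float, p: float, q: float, r: float, rng):
    waits = {
        "birth": rng.exponential(1 / p) if p > 0 else np.inf,
        "death": rng.exponential(1 / q) if q > 0 else np.inf,
        "sample": rng.exponential(1 / r),
    }
    kind = min(waits, key=waits.get)
    return (t0 + waits[kind], kind)


def brute_lineage_count(node_intervals: list, horizon: float) -> int:
    """Count intervals (old, young) strictly bracketing the horizon."""
    return sum(1 for old, young in node_intervals if young < horizon < old)
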