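"""Parsimony optimisation and unambiguous change counting.

Rates of discrete-character evolution need a per-branch count of state
changes, but parsimony reconstructions are usually not unique, and the
conventional tie-breakers (ACCTRAN/DELTRAN) pile ambiguous changes onto
stemward or crownward branches.  This module instead counts, for every
branch, the *minimum* number of steps that branch carries over *all*
most-parsimonious reconstructions (MPRs): a change is counted only when
every MPR implies it.

Both unordered (Fitch-type) and ordered (linear step-cost, Sankoff-type)
characters run through the same generalised dynamic programme:

* a postorder pass computes, per node and state, the minimal cost of the
  subtree below;
* a preorder pass computes the complementary cost of the rest of the tree;
* per node, the states attaining the global minimum total form its MPR set;
* per branch, the minimum of ``cost(parent_state, child_state)`` over all
  (parent, child) state pairs that attain the global minimum is the
  unambiguous step count — exactly the minimum over enumerated MPRs.

Missing and inapplicable tip cells carry the full state set and therefore
can never force a change onto their own pendant branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import CharacterMatrix, ValidationError
from .trees import Node, Tree

INF = 10 ** 9  # effectively infinite integer cost


def _cost_matrix(k: int, ordered: bool) -> np.ndarray:
    idx = np.arange(k)
    if ordered:
        return np.abs(idx[:, None] - idx[None, :])
    return (idx[:, None] != idx[None, :]).astype(np.int64)


def _passes(tree: Tree, tip_sets: dict, space: Sequence[int], ordered: bool):
    """Down (subtree cost) and up (rest-of-tree cost) Sankoff passes.

    Returns ``(S, U, D)``: per-node subtree cost vectors, rest-of-tree cost
    vectors, and per-node child contributions ``D[child] (s) =
    min_t cost[s, t] + S[child][t]`` used to exclude one child at a time.
    """
    k = len(space)
    pos = {s: i for i, s in enumerate(space)}
    cost = _cost_matrix(k, ordered)
    n = len(tree.nodes)
    S = np.zeros((n, k), dtype=np.int64)
    D = np.zeros((n, k), dtype=np.int64)  # contribution of node's edge to its parent
    for node in tree.postorder():
        i = node.index
        if node.is_leaf:
            allowed = tip_sets[node.label]
            S[i] = INF
            for s in allowed:
                if s in pos:
                    S[i, pos[s]] = 0
        else:
            S[i] = 0
            for c in node.children:
                S[i] += D[c.index]
        # D = min over this node's state t of cost(s, t) + S (clipped to INF)
        D[i] = np.min(cost + np.minimum(S[i], INF)[None, :], axis=1)
        np.minimum(D[i], INF, out=D[i])
    U = np.zeros((n, k), dtype=np.int64)
    for node in tree.preorder():
        i = node.index
        for c in node.children:
            excl = S[i] - D[c.index]
            A = np.minimum(U[i] + excl, INF)
            U[c.index] = np.min(A[:, None] + cost, axis=0)
    return S, U, D, cost, pos


def mpr_state_sets(tree: Tree, tip_states: dict, ordered: bool = False,
                   state_space: Optional[Sequence[int]] = None) -> dict:
    """Per-node MPR state sets for one character.

    ``tip_states`` maps tip label to a set of allowed states (full ambiguity
    for missing data).  Returns ``{node_index: frozenset}``.  Characters
    with fewer than two observed states carry no information: every node
    gets the full state set.
    """
    observed = sorted(set().union(*[set(v) for v in tip_states.values()]))
    if state_space is None:
        if ordered and observed:
            state_space = list(range(observed[0], observed[-1] + 1))
        else:
            state_space = observed
    if len(observed) < 2:
        full = frozenset(state_space)
        return {node.index: full for node in tree.nodes}
    S, U, D, cost, pos = _passes(tree, tip_states, state_space, ordered)
    total = np.minimum(S + U, INF)
    best = int(total.min(axis=None))
    out = {}
    for node in tree.nodes:
        sel = total[node.index] == total[node.index].min()
        out[node.index] = frozenset(s for s, i in pos.items() if sel[i])
    return out


def character_branch_steps(tree: Tree, tip_sets: dict, ordered: bool = False,
                           state_space: Optional[Sequence[int]] = None
                           ) -> tuple[np.ndarray, int]:
    """Unambiguous step counts per branch for a single character.

    Returns ``(steps, tree_length)`` with ``steps`` aligned to
    ``tree.branches()``.  Characters with fewer than two observed states
    carry no information and return zeros.
    """
    observed = sorted(set().union(*[set(v) for v in tip_sets.values()]))
    branches = tree.branches()
    steps = np.zeros(len(branches), dtype=np.int64)
    if len(observed) < 2:
        return steps, 0
    if state_space is None:
        state_space = (list(range(observed[0], observed[-1] + 1))
                       if ordered else observed)
    S, U, D, cost, pos = _passes(tree, tip_sets, state_space, ordered)
    best = int(S[tree.root.index].min())
    for bi, b in enumerate(branches):
        u = b.parent.index
        excl = S[u] - D[b.index]
        A = np.minimum(U[u] + excl, INF)
        M = A[:, None] + cost + np.minimum(S[b.index], INF)[None, :]
        mask = M == best
        steps[bi] = int(cost[mask].min())
    return steps, best


@dataclass
class ChangeMap:
    """Per-branch weighted unambiguous change counts on one dated tree.

    Branches are identified by the child node's postorder index in
    ``tree``.  ``total`` is the tree-wide weighted sum.
    """

    tree: Tree
    branch_nodes: list          # child Node objects, one per branch
    changes: np.ndarray         # weighted counts, aligned with branch_nodes
    durations: np.ndarray       # Myr, aligned; NaN-free (ages required)
    tree_length: float          # weighted parsimony length (sum of minima)

    @property
    def total(self) -> float:
        return float(self.changes.sum())

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for node, ch, d in zip(self.branch_nodes, self.changes, self.durations):
            rows.append({
                "branch": node.index,
                "child_label": node.label or "",
                "parent_age": node.parent.age,
                "child_age": node.age,
                "duration": d,
                "changes": ch,
            })
        return pd.DataFrame(rows)


def count_unambiguous_changes(tree: Tree, matrix: CharacterMatrix,
                              require_ages: bool = True) -> ChangeMap:
    """Weighted unambiguous change counts per branch of a dated tree.

    For each character the count on a branch is the minimum step count over
    all MPRs (see module docstring) times the character weight; branch
    totals sum over characters.
    """
    matrix.check_taxa_match(tree.leaf_labels)
    branches = tree.branches()
    changes = np.zeros(len(branches))
    tree_length = 0.0

    for j in range(matrix.nchar):
        if len(matrix.observed_states(j)) < 2:
            continue  # invariant or uninformative: zero everywhere
        tip_sets = {t: matrix.tip_state_set(t, j) for t in matrix.taxa}
        steps, length = character_branch_steps(
            tree, tip_sets, matrix.ordered[j], matrix.state_space(j))
        tree_length += length * matrix.weights[j]
        changes += steps * matrix.weights[j]

    if require_ages:
        durations = np.array([tree.duration(b) for b in branches])
    else:
        durations = np.full(len(branches), np.nan)
    return ChangeMap(tree, branches, changes, durations, tree_length)
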