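"""Minimal figures: flag-coloured dated trees and rate-through-time series.

Branches/nodes with significantly high rates draw red, low blue, everything
else grey, mirroring the usual presentation of randomization-test results
on fossil timescales.
"""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import pandas as pd

from .trees import Tree

_COLORS = {"high": "crimson", "low": "royalblue", "none": "0.4"}


def plot_flagged_tree(tree: Tree, branch_flags: Optional[dict] = None,
                      node_flags: Optional[dict] = None, ax=None):
    """Rectangular dated-tree plot; ``*_flags`` map node index -> flag."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.25 * len(tree.leaves) + 1))
    branch_flags = branch_flags or {}
    node_flags = node_flags or {}
    ys: dict[int, float] = {}
    for i, leaf in enumerate(tree.leaves):
        ys[leaf.index] = i
    for node in tree.postorder():
        if not node.is_leaf:
            ys[node.index] = sum(ys[c.index] for c in node.children) / len(node.children)
    for node in tree.postorder():
        y = ys[node.index]
        if node.parent is not None:
            color = _COLORS.get(branch_flags.get(node.index, "none"), "0.4")
            ax.plot([node.parent.age, node.age], [y, y], color=color, lw=1.5)
            ax.plot([node.parent.age, node.parent.age],
                    [ys[node.parent.index], y], color="0.7", lw=0.8)
        if not node.is_leaf and node.index in node_flags:
            ax.plot([node.age], [y], "o", ms=5,
                    color=_COLORS.get(node_flags[node.index], "0.4"))
        if node.is_leaf:
            ax.text(node.age - 0.3, y, node.label, fontsize=6, va="center")
    ax.invert_xaxis()
    ax.set_xlabel("age (Ma)")
    ax.set_yticks([])
    return ax


def plot_bin_series(table: pd.DataFrame, ax=None, boundary: Optional[float] = None):
    """Median rate per time bin with MAD error bars (bin midpoints on x)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    mid = 0.5 * (table["older"] + table["younger"])
    ax.errorbar(mid, table["median"], yerr=table["mad"].fillna(0.0),
                fmt="o-", color="0.2", capsize=3)
    for _, row in table.iterrows():
        if row["flag"] != "none":
            ax.plot([0.5 * (row["older"] + row["younger"])], [row["median"]],
                    "o", ms=9, mfc="none", mec=_COLORS[row["flag"]], mew=2)
    if boundary is not None:
        ax.axvline(boundary, color="0.6", ls="--", lw=1)
    ax.invert_xaxis()
    ax.set_xlabel("age (Ma)")
    ax.set_ylabel("median rate (changes / LMY)")
    return ax
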