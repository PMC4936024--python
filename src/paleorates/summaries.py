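"""Divergence-date distributions, boundary-crossing lineage counts, and
per-bin origination/extinction rates.

These summaries consume samples of dated trees (typically many stochastic
dating replicates of the same cladogram) and condense them into the
quantities usually reported for a fossil timescale: the median and central
95% interval of a clade's origin age, the share of dating draws older than
a stated horizon (e.g. the K–Pg boundary at 66 Ma), the number of lineages
crossing that horizon, and per-capita origination/extinction rates per
time bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import BinTable, RangeTable
from .trees import Node, Tree


def clade_node(tree: Tree, taxa: Iterable[str]) -> Node:
    """Most recent common ancestor of the named tips."""
    return tree.mrca(taxa)


@dataclass
class DivergenceSummary:
    """Distribution of one clade's origin age over dated-tree replicates.

    ``percent_older`` uses a strict inequality: an age drawn exactly at the
    horizon counts as younger.
    """

    clade: str
    samples: np.ndarray
    horizon: float

    @property
    def median(self) -> float:
        return float(np.median(self.samples))

    @property
    def interval95(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.samples, [2.5, 97.5])
        return float(lo), float(hi)

    @property
    def percent_older(self) -> float:
        return float((self.samples > self.horizon).mean() * 100.0)

    def as_row(self) -> dict:
        lo, hi = self.interval95
        return {
            "clade": self.clade,
            "median": self.median,
            "q2.5": lo,
            "q97.5": hi,
            "percent_older": self.percent_older,
            "n": len(self.samples),
        }


def divergence_summary(trees: Sequence[Tree], taxa: Iterable[str],
                       horizon: float, clade: str = "clade") -> DivergenceSummary:
    """Collect a clade's MRCA age across dated replicates and summarise."""
    taxa = list(taxa)
    if len(trees) < 2:
        raise ValueError("need at least two dated trees for a distribution")
    ages = np.array([t.mrca(taxa).age for t in trees], dtype=float)
    return DivergenceSummary(clade, ages, horizon)


def lineages_through_horizon(tree: Tree, horizon: float,
                             clade_taxa: Optional[Iterable[str]] = None,
                             include_stem: bool = True) -> int:
    """Number of branches whose age interval strictly brackets the horizon.

    Restricted to the clade spanned by ``clade_taxa`` (plus its stem branch
    when ``include_stem``); the whole tree when omitted.  A horizon older
    than the root returns 0 with a warning.
    """
    if horizon > tree.root.age:
        warnings.warn(f"horizon {horizon} Ma is older than the root "
                      f"({tree.root.age} Ma); no lineages cross it")
        return 0
    if clade_taxa is None:
        top = tree.root
    else:
        top = tree.mrca(clade_taxa)
    count = 0
    for node in tree.subtree_nodes(top):
        if node is top:
            if not include_stem or node.parent is None:
                continue
        if node.age < horizon < node.parent.age:
            count += 1
    return count


def per_capita_bin_rates(tree: Tree, bins: BinTable,
                         ranges: Optional[RangeTable] = None) -> pd.DataFrame:
    """Per-bin origination and extinction rates per lineage-Myr.

    Lineage-Myr per bin is the summed overlap of branch age intervals with
    the bin.  Origination events are branching nodes whose age falls in the
    bin; extinction events are tip ages in the bin — or, when a range table
    is supplied, taxa whose LAD bin is the bin (a better proxy for observed
    extinction than tree tip ages).  Bins with no lineage-Myr are skipped.
    """
    rows = []
    tips = tree.leaves
    internals = [n for n in tree.internal_nodes]
    youngest_tip = min(t.age for t in tips)
    for tbin in bins:
        lmy = 0.0
        for b in tree.branches():
            lmy += max(0.0, min(b.parent.age, tbin.older) - max(b.age, tbin.younger))
        if lmy <= 0:
            continue
        n_orig = sum(1 for n in internals if tbin.contains(n.age))
        if ranges is not None:
            n_ext = sum(1 for r in ranges if r.lad_bin == tbin.name)
        else:
            # tips at the youngest sampled age are censored, not extinctions
            n_ext = sum(1 for t in tips
                        if tbin.contains(t.age) and t.age > youngest_tip)
        rows.append({
            "bin": tbin.name,
            "older": tbin.older,
            "younger": tbin.younger,
            "lineage_myr": lmy,
            "n_origination": n_orig,
            "n_extinction": n_ext,
            "origination_rate": n_orig / lmy,
            "extinction_rate": n_ext / lmy,
        })
    return pd.DataFrame(rows)


def summary_table(trees: Sequence[Tree], clades: dict, horizon: float) -> pd.DataFrame:
    """Divergence summaries for several clades (label -> taxon list)."""
    rows = []
    for label, taxa in clades.items():
        rows.append(divergence_summary(trees, taxa, horizon, clade=label).as_row())
    return pd.DataFrame(rows)


def read_clades(path: str) -> dict:
    """Clade definitions from a CSV with columns (clade, taxon)."""
    df = pd.read_csv(path)
    need = {"clade", "taxon"}
    if not need <= set(df.columns):
        raise ValueError(f"clade table needs columns {sorted(need)}")
    out: dict[str, list[str]] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["clade"]), []).append(str(r["taxon"]))
    return out
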