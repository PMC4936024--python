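"""Randomization tests localising rate shifts on branches, clades and bins.

The null model is a uniform rate of character change per lineage-Myr: the
summed branch duration of a dated tree is treated as a 0-1 continuum, each
branch owning a share proportional to its duration, and the observed total
number of changes ``N`` is scattered uniformly over that continuum.  Each
of ``replications`` such scatters yields a null per-branch change count
(equivalently one multinomial draw of ``N`` changes with duration-
proportional probabilities).  A branch is flagged *high* when its observed
count strictly exceeds its null count in at least ``threshold`` of the
replications, *low* when strictly below; ties support neither tail.  The
same replication set feeds the clade-level and time-bin-level tests, so one
randomization procedure serves all three summaries.

Per-bin rate series report the median and the median absolute deviation of
the rates (changes / duration) of the branches whose age interval overlaps
each bin — medians because the stochastic dating produces occasional very
short branches whose rates are extreme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .charchanges import ChangeMap
from .io import BinTable
from .trees import Node, Tree


@dataclass
class NullConfig:
    """Shape of the randomization null.

    ``duration_floor`` (Myr) excludes near-zero-duration branches from rate
    medians (they still receive null counts); ``apportion`` switches the
    bin series from whole-branch rates to length-apportioned aggregation.
    """

    replications: int = 1000
    threshold: float = 0.95
    seed: Optional[int] = None
    duration_floor: float = 0.01
    apportion: bool = False

    def __post_init__(self):
        if self.replications < 1:
            raise ValueError("need at least one replication")
        if not 0.5 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0.5, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _flag(p_high: float, p_low: float, threshold: float) -> str:
    if p_high >= threshold:
        return "high"
    if p_low >= threshold:
        return "low"
    return "none"


def null_branch_counts(durations: np.ndarray, n_changes: int, reps: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Null change counts, shape (reps, n_branches).

    Equivalent to dropping ``n_changes`` uniform points on the duration
    continuum per replication; every row sums exactly to ``n_changes``.
    """
    total = durations.sum()
    if total <= 0:
        raise ValueError("total tree duration must be positive")
    probs = durations / total
    return rng.multinomial(n_changes, probs, size=reps)


@dataclass
class BranchRateResult:
    """Branch-level rates, null exceedance proportions and flags."""

    tree: Tree
    table: pd.DataFrame           # branch, duration, observed, rate, p_high, p_low, flag
    null_counts: np.ndarray       # (reps, n_branches), reused by clade/bin tests
    config: NullConfig

    @property
    def flags(self) -> pd.Series:
        return self.table.set_index("branch")["flag"]


def branch_rate_test(tree: Tree, change_map: ChangeMap,
                     config: Optional[NullConfig] = None,
                     rng: Optional[np.random.Generator] = None) -> BranchRateResult:
    """Test every branch against the duration-proportional null."""
    config = config or NullConfig()
    rng = config.rng() if rng is None else rng
    durations = change_map.durations
    observed = change_map.changes
    n_changes = int(round(change_map.total))
    reps = config.replications
    if n_changes == 0:
        warnings.warn("no character changes on the tree; nothing can be flagged")
        null = np.zeros((reps, len(durations)), dtype=int)
    else:
        null = null_branch_counts(durations, n_changes, reps, rng)
    p_high = (observed[None, :] > null).mean(axis=0)
    p_low = (observed[None, :] < null).mean(axis=0)
    rows = []
    for bi, node in enumerate(change_map.branch_nodes):
        dur = durations[bi]
        rate = observed[bi] / dur if dur >= config.duration_floor else np.nan
        rows.append({
            "branch": node.index,
            "child_label": node.label or "",
            "duration": dur,
            "observed": observed[bi],
            "rate": rate,
            "p_high": p_high[bi] if n_changes else 0.0,
            "p_low": p_low[bi] if n_changes else 0.0,
            "flag": _flag(p_high[bi], p_low[bi], config.threshold) if n_changes else "none",
        })
    return BranchRateResult(tree, pd.DataFrame(rows), null, config)


def clade_shift_test(tree: Tree, change_map: ChangeMap,
                     null: Optional[BranchRateResult] = None,
                     config: Optional[NullConfig] = None,
                     rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Detect nodes whose clade departs from the uniform-rate null.

    For each internal node except the root, observed changes summed over
    the branches inside the clade (the node's descendant edges) are
    compared with the same sum under each null replication; the two-sided
    threshold rule then assigns high/low/none.  Shares the branch test's
    replication set when one is supplied.
    """
    if null is None:
        null = branch_rate_test(tree, change_map, config, rng)
    config = null.config
    branch_pos = {node.index: bi for bi, node in enumerate(change_map.branch_nodes)}
    observed = change_map.changes
    rows = []
    for node in tree.internal_nodes:
        if node.parent is None:
            continue  # the whole tree has no complement to compare against
        crown = [branch_pos[n.index] for n in tree.subtree_nodes(node)
                 if n.index != node.index]
        obs_sum = observed[crown].sum()
        null_sum = null.null_counts[:, crown].sum(axis=1)
        p_high = float((obs_sum > null_sum).mean())
        p_low = float((obs_sum < null_sum).mean())
        rows.append({
            "node": node.index,
            "n_tips": sum(1 for n in tree.subtree_nodes(node) if n.is_leaf),
            "observed": obs_sum,
            "expected": float(null_sum.mean()),
            "p_high": p_high,
            "p_low": p_low,
            "flag": _flag(p_high, p_low, config.threshold),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# time-bin series
# ---------------------------------------------------------------------------
@dataclass
class BinRateSeries:
    """Per-bin median rates with dispersion and significance flags."""

    table: pd.DataFrame  # bin, older, younger, n_branches, median, mad, p_high, p_low, flag

    def median(self, bin_name: str) -> float:
        row = self.table[self.table["bin"] == bin_name]
        return float(row["median"].iloc[0]) if len(row) else np.nan

    def flag(self, bin_name: str) -> str:
        row = self.table[self.table["bin"] == bin_name]
        return str(row["flag"].iloc[0]) if len(row) else "none"


def _branch_bin_overlap(parent_age: float, child_age: float, tbin) -> float:
    return max(0.0, min(parent_age, tbin.older) - max(child_age, tbin.younger))


def bin_rate_series(items: Sequence[tuple[Tree, ChangeMap]], bins: BinTable,
                    config: Optional[NullConfig] = None,
                    nulls: Optional[Sequence[BranchRateResult]] = None,
                    rng: Optional[np.random.Generator] = None) -> BinRateSeries:
    """Median rate per time bin, pooled over a sample of dated trees.

    Each branch contributes its whole-branch rate to every bin its age
    interval overlaps (default), or, with ``config.apportion``, bins
    aggregate length-apportioned changes over lineage-Myr.  Significance
    compares the observed per-bin statistic against the same statistic
    recomputed under each replication of the branch-level null.
    """
    config = config or NullConfig()
    rng = config.rng() if rng is None else rng
    if nulls is not None and len(nulls) != len(items):
        raise ValueError("need one null result per (tree, change_map) pair")

    reps = config.replications
    obs_rates_all: list[np.ndarray] = []
    null_rates_all: list[np.ndarray] = []
    overlaps_all: list[np.ndarray] = []   # (n_branches, n_bins) overlap durations
    durations_all: list[np.ndarray] = []

    for k, (tree, cm) in enumerate(items):
        if nulls is not None:
            null_counts = nulls[k].null_counts
            if null_counts.shape[0] != reps:
                raise ValueError("replication count mismatch with supplied nulls")
        else:
            n_changes = int(round(cm.total))
            null_counts = (np.zeros((reps, len(cm.durations)), dtype=int)
                           if n_changes == 0 else
                           null_branch_counts(cm.durations, n_changes, reps, rng))
        durs = cm.durations
        with np.errstate(divide="ignore", invalid="ignore"):
            obs_rates = np.where(durs > 0, cm.changes / durs, np.nan)
            null_rates = np.where(durs[None, :] > 0, null_counts / durs[None, :], np.nan)
        ov = np.zeros((len(durs), len(bins)))
        for bi, node in enumerate(cm.branch_nodes):
            for gi, tbin in enumerate(bins):
                ov[bi, gi] = _branch_bin_overlap(node.parent.age, node.age, tbin)
        obs_rates_all.append(obs_rates)
        null_rates_all.append(null_rates)
        overlaps_all.append(ov)
        durations_all.append(durs)

    obs_rates = np.concatenate(obs_rates_all)
    null_rates = np.concatenate(null_rates_all, axis=1)
    overlaps = np.concatenate(overlaps_all, axis=0)
    durations = np.concatenate(durations_all)
    usable = durations >= config.duration_floor

    rows = []
    for gi, tbin in enumerate(bins):
        touch = (overlaps[:, gi] > 0) & usable
        n_br = int(touch.sum())
        if n_br == 0:
            warnings.warn(f"bin {tbin.name!r}: no branches overlap; skipped")
            continue
        if config.apportion:
            lmy = overlaps[touch, gi].sum()
            frac = overlaps[touch, gi] / durations[touch]
            obs_stat = (obs_rates[touch] * durations[touch] * frac).sum() / lmy
            null_stat = (null_rates[:, touch] * (durations[touch] * frac)[None, :]).sum(axis=1) / lmy
            med = obs_stat
            mad = np.nan
        else:
            med = float(np.median(obs_rates[touch]))
            mad = float(median_abs_deviation(obs_rates[touch]))
            obs_stat = med
            null_stat = np.median(null_rates[:, touch], axis=1)
        p_high = float((obs_stat > null_stat).mean())
        p_low = float((obs_stat < null_stat).mean())
        rows.append({
            "bin": tbin.name,
            "older": tbin.older,
            "younger": tbin.younger,
            "n_branches": n_br,
            "median": med,
            "mad": mad,
            "p_high": p_high,
            "p_low": p_low,
            "flag": _flag(p_high, p_low, config.threshold),
        })
    return BinRateSeries(pd.DataFrame(rows))
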