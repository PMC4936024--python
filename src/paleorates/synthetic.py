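"""Synthetic fossil records and character matrices with known ground truth.

The generator produces exactly the inputs the rest of the pipeline consumes
— a cladogram of binned fossil taxa, a taxon range table, and a discrete
character matrix — from a forward birth–death–sampling simulation, keeping
the true dated tree and the true per-branch change history so that every
downstream stage can be checked against ground truth.

Model
-----
* Lineages originate at rate ``p`` and go extinct at rate ``q`` (both per
  lineage-Myr); fossil sampling events occur at rate ``r`` per lineage-Myr.
* Speciation is bifurcating: each branching ends the parent taxon and
  founds two new ones, so a taxon is one tree segment between branching
  (or origin) and extinction/branching/censoring.  A terminal segment with
  at least one sampling event becomes an observed taxon; its FAD/LAD are
  the bins containing its first/last sampling event.  Samples falling on
  internal segments would be sampled ancestors, which the pipeline does not
  represent; they are discarded (see the methods note).
* Each character evolves as a symmetric continuous-time Markov chain (2 or
  3 states; ordered characters step +/-1 only) whose instantaneous change
  rate on any branch segment is ``base_char_rate`` times the rate
  multiplier of the time bin containing that segment.  A multiplier > 1 in
  a designated post-boundary bin emulates an episode of elevated
  morphological evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import BinTable, CharacterMatrix, RangeTable, TaxonRange, TimeBin
from .trees import Node, Tree


def default_synthetic_bins() -> BinTable:
    """Five stage-like bins spanning 96-56 Ma with a boundary at 66 Ma.

    Widths (~5-10 Myr) match typical Late Cretaceous stages and pooled
    early-Cenozoic land-mammal ages.  ``post1`` (66-61 Ma) is the designated
    first post-boundary bin used by the rate-shift experiments.
    """
    return BinTable([
        TimeBin("pre3", 96.0, 86.0),
        TimeBin("pre2", 86.0, 76.0),
        TimeBin("pre1", 76.0, 66.0),
        TimeBin("post1", 66.0, 61.0),
        TimeBin("post2", 61.0, 56.0),
    ])


@dataclass
class SimulationConfig:
    """Parameters of the synthetic fossil record and character process.

    Rates are per lineage-Myr.  ``rate_multipliers`` maps bin names to
    positive multipliers of the character change rate (bins not listed get
    1.0).  ``min_taxa`` conditions the record on a minimum clade size by
    rejection, up to ``max_retries`` attempts.
    """

    p: float = 0.15
    q: float = 0.05
    r: float = 0.2
    n_chars: int = 100
    bin_table: BinTable = field(default_factory=default_synthetic_bins)
    rate_multipliers: dict = field(default_factory=dict)
    base_char_rate: float = 0.005
    seed: Optional[int] = None
    min_taxa: int = 25
    max_taxa: int = 80
    max_retries: int = 2000
    three_state_fraction: float = 0.3
    ordered_fraction: float = 0.2

    def __post_init__(self):
        if min(self.p, self.q, self.r) < 0:
            raise ValueError("rates p, q, r must be non-negative")
        if any(m <= 0 for m in self.rate_multipliers.values()):
            raise ValueError("rate multipliers must be positive")
        unknown = [b for b in self.rate_multipliers if b not in self.bin_table]
        if unknown:
            raise ValueError(f"multipliers refer to unknown bins: {unknown}")
        if self.base_char_rate < 0:
            raise ValueError("base_char_rate must be non-negative")

    def multiplier(self, bin_name: str) -> float:
        return self.rate_multipliers.get(bin_name, 1.0)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class FossilRecord:
    """A simulated record: truth plus exactly what an observer would see."""

    true_tree: Tree          # complete tree; tip ages = extinction/censoring ages
    observed_tree: Tree      # pruned to sampled taxa; true node ages retained
    ranges: RangeTable       # binned FAD/LAD per observed taxon
    fad_ages: dict           # taxon -> exact age of first sampling event (Ma)
    lad_ages: dict           # taxon -> exact age of last sampling event (Ma)
    attempts: int = 1

    @property
    def taxa(self) -> list:
        return self.observed_tree.leaf_labels


class SimulationFailed(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# fossil record
# ---------------------------------------------------------------------------
def simulate_fossil_record(config: SimulationConfig,
                           rng: Optional[np.random.Generator] = None) -> FossilRecord:
    """Forward-simulate one fossil record over the span of the bin table.

    A single lineage starts at the oldest bin bound; the process runs to the
    youngest bound (survivors are censored there).  Records with fewer than
    ``config.min_taxa`` sampled taxa (or more than ``config.max_taxa``) are
    rejected and redrawn, up to ``config.max_retries`` attempts.
    """
    rng = config.rng() if rng is None else rng
    for attempt in range(1, config.max_retries + 1):
        rec = _simulate_once(config, rng)
        if rec is not None and config.min_taxa <= len(rec.taxa) <= config.max_taxa:
            rec.attempts = attempt
            return rec
    raise SimulationFailed(
        f"no record with {config.min_taxa}-{config.max_taxa} sampled taxa in "
        f"{config.max_retries} attempts; raise r or the retry cap"
    )


def _simulate_once(config: SimulationConfig, rng) -> Optional[FossilRecord]:
    t_start = config.bin_table.oldest
    t_end = config.bin_table.youngest
    p, q, r = config.p, config.q, config.r
    total = p + q + r
    if total == 0:
        raise ValueError("p = q = r = 0: nothing can ever happen")

    root = Node(age=None)  # placeholder; will take first branching age
    # each work item: (node to decorate, birth age, taxon samples list)
    # budding: the taxon identity continues through the left child.
    samples_of: dict[int, list[float]] = {}
    taxon_seq = [0]

    def new_taxon() -> int:
        taxon_seq[0] += 1
        samples_of[taxon_seq[0]] = []
        return taxon_seq[0]

    stack = [(root, t_start, new_taxon())]
    n_events = 0
    while stack:
        node, age, taxon = stack.pop()
        while True:
            n_events += 1
            if n_events > 2_000_000:
                return None  # runaway clade; reject
            age -= rng.exponential(1.0 / total)
            if age <= t_end:  # survived to the end of the window: censored
                node.label = f"t{taxon}"
                node.age = t_end
                node.children = []
                break
            u = rng.random() * total
            if u < p:  # branching: node becomes internal at this age
                node.age = age
                left = Node()
                right = Node()
                node.children = []
                node.add_child(left)
                node.add_child(right)
                stack.append((right, age, new_taxon()))
                # bifurcating speciation: the parent taxon ends here; any of
                # its samples are sampled ancestors and are discarded
                samples_of[taxon] = []
                node, taxon = left, new_taxon()
            elif u < p + q:  # extinction
                node.label = f"t{taxon}"
                node.age = age
                node.children = []
                break
            else:  # sampling event on the current taxon
                samples_of[taxon].append(age)

    # relabel leaves by taxon id; taxon ids follow pendant identity, but the
    # budding identity path means a taxon's samples may predate its leaf's
    # parent node.  Collect sampled taxa.
    sampled = {f"t{tid}": evs for tid, evs in samples_of.items() if evs}
    tree = Tree(root)
    leaf_labels = set(tree.leaf_labels)
    sampled = {name: evs for name, evs in sampled.items() if name in leaf_labels}
    if len(sampled) < 2:
        return None

    fad_ages = {name: max(evs) for name, evs in sampled.items()}
    lad_ages = {name: min(evs) for name, evs in sampled.items()}
    observed = tree.prune_to(sampled)
    bins = config.bin_table
    ranges = RangeTable(
        (TaxonRange(name,
                    bins.bin_containing(fad_ages[name]).name,
                    bins.bin_containing(lad_ages[name]).name)
         for name in sorted(sampled, key=lambda s: int(s[1:]))),
        bins,
    )
    return FossilRecord(tree, observed, ranges, fad_ages, lad_ages)


# ---------------------------------------------------------------------------
# character evolution
# ---------------------------------------------------------------------------
@dataclass
class CharacterTruth:
    """Ground truth from :func:`simulate_characters`.

    ``events`` holds one ``(branch_child_index, char_index, age)`` triple per
    realised state change on the tree used for simulation.
    """

    events: list
    branch_changes: np.ndarray  # per branch child-index, summed over characters

    def changes_in_bin(self, tbin: TimeBin) -> int:
        return sum(1 for (_, _, a) in self.events if tbin.contains(a))


def simulate_characters(tree: Tree, config: SimulationConfig,
                        rng: Optional[np.random.Generator] = None
                        ) -> tuple[CharacterMatrix, CharacterTruth]:
    """Evolve ``config.n_chars`` discrete characters along a dated tree.

    The change rate on a branch segment is ``base_char_rate`` times the
    multiplier of the bin containing the segment.  Returns the tip matrix
    and the true change history (counts and event ages per branch).
    """
    for n in tree.nodes:
        if n.age is None:
            raise ValueError("tree must be dated (every node needs an age)")
    if all(abs(n.parent.age - n.age) < 1e-12 for n in tree.branches()):
        raise ValueError("zero-duration tree: no time for characters to evolve")
    rng = config.rng() if rng is None else rng
    nchar = config.n_chars
    k_states = np.where(rng.random(nchar) < config.three_state_fraction, 3, 2)
    ordered = rng.random(nchar) < config.ordered_fraction
    # binary characters: ordered flag is cosmetic (identical process)
    root_states = np.array([rng.integers(k) for k in k_states])

    states_at: dict[int, np.ndarray] = {tree.root.index: root_states}
    events: list = []
    nbr = len(tree.nodes)
    branch_changes = np.zeros(nbr, dtype=int)

    for node in tree.preorder():
        if node.parent is None:
            continue
        cur = states_at[node.parent.index].copy()
        for older, younger, mult in _segments(node.parent.age, node.age, config):
            lam = config.base_char_rate * mult
            dur = older - younger
            if lam <= 0 or dur <= 0:
                continue
            counts = rng.poisson(lam * dur, size=nchar)
            for j in np.nonzero(counts)[0]:
                ages = older - rng.random(counts[j]) * dur
                ages.sort()
                for a in ages[::-1]:  # old -> young
                    cur[j] = _step(cur[j], int(k_states[j]), bool(ordered[j]), rng)
                    events.append((node.index, int(j), float(a)))
                    branch_changes[node.index] += 1
        states_at[node.index] = cur

    taxa = tree.leaf_labels
    leafmap = tree.leaf_map()
    rows = []
    for t in taxa:
        st = states_at[leafmap[t].index]
        rows.append([frozenset([int(s)]) for s in st])
    matrix = CharacterMatrix(taxa, rows, ordered=list(map(bool, ordered)))
    return matrix, CharacterTruth(events, branch_changes)


def _segments(older: float, younger: float, config: SimulationConfig):
    """Split an age interval at bin boundaries; yield (older, younger, mult).

    Ages outside the bin table evolve at multiplier 1.
    """
    bins = config.bin_table
    bounds = sorted({b.older for b in bins} | {b.younger for b in bins},
                    reverse=True)
    cuts = [older] + [x for x in bounds if younger < x < older] + [younger]
    for hi, lo in zip(cuts, cuts[1:]):
        mid = 0.5 * (hi + lo)
        try:
            name = bins.bin_containing(mid).name
        except Exception:
            yield hi, lo, 1.0
            continue
        yield hi, lo, config.multiplier(name)


def _step(state: int, k: int, ordered: bool, rng) -> int:
    if k == 2:
        return 1 - state
    if ordered:
        if state == 0:
            return 1
        if state == k - 1:
            return k - 2
        return state + (1 if rng.random() < 0.5 else -1)
    # unordered: jump to a uniformly chosen other state
    s = rng.integers(k - 1)
    return s if s < state else s + 1


# write record to disk via io module ---------------------------------------
def write_record(record: FossilRecord, matrix: CharacterMatrix, outdir) -> dict:
    """Write observed tree / ranges / bins / matrix in pipeline formats."""
    import os

    from . import io as pio

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "trees": os.path.join(outdir, "observed_trees.nwk"),
        "bins": os.path.join(outdir, "bins.csv"),
        "ranges": os.path.join(outdir, "ranges.csv"),
        "matrix": os.path.join(outdir, "matrix.nex"),
        "true_tree": os.path.join(outdir, "true_tree.nwk"),
    }
    pio.write_trees([record.observed_tree], paths["trees"])
    pio.write_trees([record.true_tree], paths["true_tree"])
    pio.write_bins(record.ranges.bins, paths["bins"])
    pio.write_ranges(record.ranges, paths["ranges"])
    pio.write_nexus_matrix(matrix, paths["matrix"])
    return paths
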