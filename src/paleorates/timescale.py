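"""Stochastic time-scaling of cladograms of binned fossil taxa.

The dating model is a birth–death–sampling process: taxa originate at rate
``p``, go extinct at rate ``q`` and are fossil-sampled at rate ``r`` (all
per lineage-Myr).  A tip's age is drawn uniformly within its
first-appearance bin; each internal node is then placed older than both of
its children by a waiting time drawn from the distribution of the span
between a lineage's true origin and its first sampled appearance under the
(p, q, r) process.  Repeated draws give a distribution of dated trees that
propagates both stratigraphic (bin-level) and process uncertainty into
every downstream rate and divergence estimate.

The waiting-time density is realised by conditioned forward simulation of
the birth–death–sampling process rather than in closed form; with
``p = q = 0`` it reduces exactly to an Exponential(r) truncated at the
allowed maximum, which the tests exploit as an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import BinTable, RangeTable, ValidationError
from .trees import Node, Tree


class DatingError(RuntimeError):
    pass


@dataclass(frozen=True)
class RateParams:
    """Origination, extinction and sampling rates, per lineage-Myr."""

    p: float
    q: float
    r: float

    def __post_init__(self):
        if min(self.p, self.q, self.r) < 0:
            raise ValueError("rates must be non-negative")
        if self.r == 0:
            raise ValueError("sampling rate r must be positive to date a tree")


# ---------------------------------------------------------------------------
# polytomy resolution
# ---------------------------------------------------------------------------
def resolve_polytomies(tree: Tree, rng: np.random.Generator) -> Tree:
    """Replace every polytomy by a uniformly random binary resolution.

    Uniform over all labelled rooted binary arrangements of the polytomy's
    child subtrees ((2k-3)!! of them for k children), by sequential random
    edge insertion.  Binary trees come back topologically unchanged.
    """
    out = tree.copy()
    changed = False
    for node in list(out.nodes):
        if len(node.children) > 2:
            _resolve_node(node, rng)
            changed = True
    if changed:
        out.reindex()
    return out


def _resolve_node(node: Node, rng: np.random.Generator) -> None:
    children = node.children
    local_root = children[0]
    local_root.parent = None
    # edge list: each entry is a node standing for the edge above it
    edges = [local_root]
    for child in children[1:]:
        target = edges[rng.integers(len(edges))]
        joint = Node()
        parent = target.parent
        if parent is None:
            local_root = joint
        else:
            parent.children[parent.children.index(target)] = joint
            joint.parent = parent
        joint.children = []
        joint.add_child(target)
        child.parent = None
        joint.add_child(child)
        edges.append(child)
        edges.append(joint)
    node.children = []
    for c in local_root.children:
        node.add_child(c)


# ---------------------------------------------------------------------------
# rate estimation from range data
# ---------------------------------------------------------------------------
class EstimatorUndefined(ValidationError):
    pass


def estimate_sampling_rate(ranges: RangeTable, bins: Optional[BinTable] = None,
                           max_prob: float = 0.999) -> float:
    """Per-Myr sampling rate from the taxon duration-frequency distribution.

    Uses the frequency-ratio estimator of per-bin sampling probability,
    ``R = f2^2 / (f1 * f3)`` where ``f_k`` is the number of taxa whose range
    spans exactly ``k`` bins, then converts to a continuous rate with the
    mean bin length: ``r = -ln(1 - R) / meanBinLength``.  ``R`` is capped at
    ``max_prob`` so the conversion stays finite.
    """
    bins = ranges.bins if bins is None else bins
    counts: dict[int, int] = {}
    for taxon in ranges.taxa:
        k = ranges.duration_bins(taxon)
        counts[k] = counts.get(k, 0) + 1
    f1, f2, f3 = counts.get(1, 0), counts.get(2, 0), counts.get(3, 0)
    if 0 in (f1, f2, f3):
        raise EstimatorUndefined(
            f"frequency-ratio estimator undefined (f1={f1}, f2={f2}, f3={f3}); "
            "supply a sampling rate r explicitly (e.g. a fixed per-Myr value "
            "or a per-bin probability converted with sampling_prob_to_rate)"
        )
    R = min(f2 * f2 / (f1 * f3), max_prob)
    return sampling_prob_to_rate(R, bins.mean_length)


def sampling_prob_to_rate(prob_per_bin: float, bin_length: float) -> float:
    """Convert a per-bin sampling probability to a per-Myr Poisson rate."""
    if not 0 < prob_per_bin < 1:
        raise ValueError("per-bin sampling probability must be in (0, 1)")
    return -math.log(1.0 - prob_per_bin) / bin_length


def estimate_extinction_rate(ranges: RangeTable, bins: Optional[BinTable] = None) -> float:
    """Extinction rate from the decay of the duration-frequency distribution.

    Under exponential lifetimes the frequency of taxa with duration ``k``
    bins falls off geometrically; a least-squares fit of ``ln f_k`` against
    ``k`` (survivorship analysis) gives slope ``-q * meanBinLength``.
    """
    bins = ranges.bins if bins is None else bins
    counts: dict[int, int] = {}
    for taxon in ranges.taxa:
        k = ranges.duration_bins(taxon)
        counts[k] = counts.get(k, 0) + 1
    ks = sorted(k for k, n in counts.items() if n > 0)
    if len(ks) < 2:
        raise EstimatorUndefined(
            "need at least two distinct range durations to fit a survivorship "
            "slope; supply extinction rate q explicitly"
        )
    x = np.array(ks, dtype=float)
    y = np.log([counts[k] for k in ks])
    slope = np.polyfit(x, y, 1)[0]
    q = max(-slope, 0.0) / bins.mean_length
    if q == 0.0:
        raise EstimatorUndefined(
            "duration-frequency distribution does not decay; supply q explicitly"
        )
    return q


def estimate_rates(ranges: RangeTable, bins: Optional[BinTable] = None,
                   r: Optional[float] = None) -> RateParams:
    """Full (p, q, r) under the zero-net-diversification null (p = q).

    Net diversification cannot be estimated from a non-ultrametric fossil
    tree without extra assumptions, so origination is set equal to
    extinction; extinction comes from survivorship decay of the observed
    durations and sampling from the frequency-ratio estimator unless given.
    """
    q = estimate_extinction_rate(ranges, bins)
    if r is None:
        r = estimate_sampling_rate(ranges, bins)
    return RateParams(p=q, q=q, r=r)


# ---------------------------------------------------------------------------
# unsampled-history sampler
# ---------------------------------------------------------------------------
def draw_unsampled_history(params: RateParams, rng: np.random.Generator,
                           max_duration: float = math.inf,
                           max_attempts: int = 10_000) -> float:
    """One draw of the gap between a lineage's origin and its first sampled
    appearance under the (p, q, r) birth–death–sampling process.

    Forward event simulation with rejection: the clade descending from the
    origin grows at ``p``, prunes at ``q``, and the first sampling event
    anywhere in it (at total rate ``n * r``) ends the draw.  Histories in
    which the clade dies or exceeds ``max_duration`` unsampled are rejected,
    so the return value is conditioned on a sampling event occurring before
    ``max_duration``.  With ``p = q = 0`` this is Exponential(r) truncated
    at ``max_duration``.
    """
    p, q, r = params.p, params.q, params.r
    # Narrow window: birth/death events are negligible before max_duration,
    # so the conditional law is exactly Exponential(r) truncated there.
    # Rejection would be needlessly slow (acceptance ~ r * max_duration).
    if max_duration * (p + q + r) < 0.05:
        u = rng.random()
        return -math.log1p(-u * (1.0 - math.exp(-r * max_duration))) / r
    exp = rng.exponential
    uni = rng.random
    for _ in range(max_attempts):
        t = 0.0
        n = 1
        while True:
            total = n * (p + q + r)
            t += exp(1.0 / total)
            if t >= max_duration:
                break  # reject: no sampling in the allowed window
            u = uni() * (p + q + r)
            if u < r:
                return t
            if u < r + p:
                n += 1
            else:
                n -= 1
                if n == 0:
                    break  # clade extinct unsampled: reject
    raise DatingError(
        f"no accepted unsampled-history draw in {max_attempts} attempts "
        f"(p={p}, q={q}, r={r}, max_duration={max_duration}); increase "
        "max_duration or the sampling rate"
    )


# ---------------------------------------------------------------------------
# node dating
# ---------------------------------------------------------------------------
def cal3_date(tree: Tree, ranges: RangeTable, bins: Optional[BinTable] = None,
              params: Optional[RateParams] = None,
              rng: Optional[np.random.Generator] = None,
              max_gap: float = 30.0,
              max_attempts: int = 10_000) -> Tree:
    """Date one binary cladogram: returns a new tree with node ages in Ma.

    Tip ages are uniform draws within each taxon's FAD bin.  Each internal
    node is anchored to its clade's first appearance ``F`` (the oldest
    drawn tip age in its subtree): its age is ``F + w`` where ``w`` is an
    unsampled-history draw — the waiting time from a divergence to the
    first sampled fossil anywhere in the descendant clade.  Ages are
    assigned root-to-tips so each ``w`` is simply truncated above by the
    parent's already-drawn age (the root by ``max_gap``), which guarantees
    age monotonicity and FAD-bin containment on every output.  Call
    repeatedly (or use :func:`date_replicates`) for a distribution of
    dated trees.
    """
    if rng is None:
        rng = np.random.default_rng()
    if params is None:
        params = estimate_rates(ranges, bins)
    bins = ranges.bins if bins is None else bins
    if not tree.is_binary:
        raise ValidationError("tree has polytomies; resolve_polytomies() first")
    ranges.check_covers(tree.leaf_labels)

    dated = tree.copy()
    oldest_tip: dict[int, float] = {}
    for node in dated.postorder():  # tips first: they set the anchors
        if node.is_leaf:
            fad = bins[ranges[node.label].fad_bin]
            node.age = fad.younger + rng.random() * fad.length
            oldest_tip[node.index] = node.age
        else:
            oldest_tip[node.index] = max(oldest_tip[c.index] for c in node.children)
    for node in dated.preorder():
        if node.is_leaf:
            continue
        first_appearance = oldest_tip[node.index]
        cap = max_gap if node.parent is None else node.parent.age - first_appearance
        try:
            w = draw_unsampled_history(params, rng, max_duration=cap,
                                       max_attempts=max_attempts)
        except DatingError as exc:
            tips = sorted(l.label for l in dated.subtree_nodes(node) if l.is_leaf)
            raise DatingError(
                f"dating failed at the node above tips {tips[:4]}: {exc}"
            ) from exc
        node.age = first_appearance + w
    dated.validate_ages()
    _check_fad_containment(dated, ranges, bins)
    return dated


def _check_fad_containment(tree: Tree, ranges: RangeTable, bins: BinTable) -> None:
    for leaf in tree.leaves:
        fad = bins[ranges[leaf.label].fad_bin]
        if not (fad.younger <= leaf.age <= fad.older):
            raise DatingError(
                f"tip {leaf.label!r} age {leaf.age} outside its FAD bin {fad.name}"
            )


def date_replicates(tree: Tree, ranges: RangeTable, params: RateParams,
                    rng: np.random.Generator, n: int,
                    bins: Optional[BinTable] = None,
                    max_gap: float = 30.0) -> list[Tree]:
    """A sample of ``n`` independently dated trees from one cladogram."""
    return [cal3_date(tree, ranges, bins, params, rng, max_gap=max_gap)
            for _ in range(n)]
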