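"""Polytomy resolution, rate estimators and the stochastic dating model."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats

import paleorates as pr
from paleorates.io import TimeBin, TaxonRange
from paleorates.timescale import DatingError, EstimatorUndefined
from oracles import brute_unsampled_history


# ---------------------------------------------------------------------------
# polytomy resolution
# ---------------------------------------------------------------------------
def test_binary_tree_comes_back_unchanged(rng):
    t = pr.parse_newick("((A,B),(C,(D,E)));")
    out = pr.resolve_polytomies(t, rng)
    assert out.newick(lengths=False) == t.newick(lengths=False)


def test_trifurcation_resolutions_uniform(rng):
    t = pr.parse_newick("((A,B,C),D);")
    seen = Counter()
    for _ in range(3000):
        out = pr.resolve_polytomies(t, rng)
        assert out.is_binary
        seen[out.newick(lengths=False)] += 1
    assert len(seen) == 3
    for count in seen.values():
        # binomial(3000, 1/3): 5 sigma ~ 130
        assert abs(count - 1000) < 140


def test_four_way_polytomy_has_fifteen_uniform_resolutions(rng):
    t = pr.parse_newick("(A,B,C,D);")
    seen = Counter()
    n = 7500
    for _ in range(n):
        out = pr.resolve_polytomies(t, rng)
        assert out.is_binary
        assert set(out.leaf_labels) == {"A", "B", "C", "D"}
        # canonical form: sort children recursively
        seen[_canon(out)] += 1
    assert len(seen) == 15
    # chi-square goodness of fit against uniform
    chi2 = sum((c - n / 15) ** 2 / (n / 15) for c in seen.values())
    assert chi2 < stats.chi2.ppf(0.999, df=14)


def _canon(tree):
    def key(node):
        if node.is_leaf:
            return node.label
        return "(" + ",".join(sorted(key(c) for c in node.children)) + ")"

    return key(tree.root)


# ---------------------------------------------------------------------------
# sampling-rate estimation
# ---------------------------------------------------------------------------
def _ranges_with_duration_counts(f):
    """Build a RangeTable whose duration-frequency distribution is ``f``."""
    bins = pr.BinTable([TimeBin(f"b{i}", 50.0 - 5 * i, 45.0 - 5 * i)
                        for i in range(6)])
    rows = []
    k = 0
    for dur, count in f.items():
        for _ in range(count):
            rows.append(TaxonRange(f"t{k}", "b0", f"b{dur - 1}"))
            k += 1
    return pr.RangeTable(rows, bins), bins


@pytest.mark.parametrize("f,expected_R", [
    ({1: 40, 2: 20, 3: 10}, 0.999),      # 400/400 = 1.0, capped
    ({1: 50, 2: 10, 3: 2}, 0.999),       # 100/100 = 1.0, capped
    ({1: 50, 2: 10, 3: 4}, 0.5),         # 100/200
])
def test_frequency_ratio_estimator(f, expected_R):
    ranges, bins = _ranges_with_duration_counts(f)
    r = pr.estimate_sampling_rate(ranges)
    assert r == pytest.approx(-math.log(1 - expected_R) / bins.mean_length)


def test_estimator_undefined_without_all_three_frequencies():
    ranges, _ = _ranges_with_duration_counts({1: 50, 2: 10})
    with pytest.raises(EstimatorUndefined, match="supply"):
        pr.estimate_sampling_rate(ranges)


def test_sampling_prob_to_rate_accepts_published_scenarios():
    # e.g. a 0.5%-per-Myr scenario and a high 85%-per-bin scenario are both
    # user-specified conversions, not hard-coded truths
    assert pr.sampling_prob_to_rate(0.005, 1.0) == pytest.approx(0.005012, rel=1e-3)
    high = pr.sampling_prob_to_rate(0.85, 3.0)
    assert high == pytest.approx(-math.log(0.15) / 3.0)


def test_extinction_rate_from_survivorship_decay():
    # geometric decay with per-bin survival 0.5 over 5-Myr bins
    f = {1: 160, 2: 80, 3: 40, 4: 20}
    ranges, bins = _ranges_with_duration_counts(f)
    q = pr.estimate_extinction_rate(ranges)
    assert q == pytest.approx(math.log(2) / 5.0, rel=1e-6)
    params = pr.estimate_rates(ranges)
    assert params.p == params.q  # zero net diversification null


# ---------------------------------------------------------------------------
# unsampled-history sampler
# ---------------------------------------------------------------------------
def test_pure_sampling_limit_is_exponential(rng):
    params = pr.RateParams(0.0, 0.0, 0.5)
    draws = np.array([pr.draw_unsampled_history(params, rng)
                      for _ in range(10_000)])
    assert draws.mean() == pytest.approx(2.0, rel=0.05)
    assert stats.kstest(draws, "expon", args=(0, 2.0)).pvalue > 0.01


def test_truncated_exponential_matches_closed_form(rng):
    params = pr.RateParams(0.0, 0.0, 0.5)
    draws = np.array([pr.draw_unsampled_history(params, rng, max_duration=1.0)
                      for _ in range(10_000)])
    assert draws.max() < 1.0
    r = 0.5
    closed = 1 / r - 1.0 * math.exp(-r) / (1 - math.exp(-r))
    assert draws.mean() == pytest.approx(closed, rel=0.05)


def test_birth_death_sampler_matches_independent_simulator(rng):
    params = pr.RateParams(0.1, 0.1, 0.2)
    mine = np.array([pr.draw_unsampled_history(params, rng, max_duration=50.0)
                     for _ in range(10_000)])
    other = np.array([brute_unsampled_history(0.1, 0.1, 0.2, rng, 50.0)
                      for _ in range(10_000)])
    assert stats.ks_2samp(mine, other).pvalue > 0.01


def test_sampler_error_when_acceptance_hopeless(rng):
    params = pr.RateParams(0.0, 5.0, 0.001)
    with pytest.raises(DatingError, match="max_duration"):
        pr.draw_unsampled_history(params, rng, max_duration=0.5,
                                  max_attempts=50)


# ---------------------------------------------------------------------------
# cal3 dating
# ---------------------------------------------------------------------------
def _two_tip_setup():
    bins = pr.BinTable([TimeBin("Puercan", 66.0, 63.3),
                        TimeBin("Torrejonian", 63.3, 60.2)])
    ranges = pr.RangeTable([TaxonRange("A", "Puercan", "Puercan"),
                            TaxonRange("B", "Puercan", "Torrejonian")], bins)
    tree = pr.parse_newick("(A,B);")
    return tree, ranges, bins


def test_two_tip_dated_tree_invariants(rng):
    tree, ranges, bins = _two_tip_setup()
    params = pr.RateParams(0.1, 0.1, 0.2)
    roots = []
    for _ in range(1000):
        d = pr.cal3_date(tree, ranges, bins, params, rng)
        assert d.root.age > max(l.age for l in d.leaves)
        for leaf in d.leaves:
            assert 63.3 <= leaf.age <= 66.0
        roots.append(d.root.age)
    assert min(roots) >= 63.3


def test_high_sampling_rate_collapses_gaps(rng):
    tree, ranges, bins = _two_tip_setup()
    params = pr.RateParams(0.1, 0.1, 10.0)
    gaps = []
    for _ in range(300):
        d = pr.cal3_date(tree, ranges, bins, params, rng)
        gaps.append(d.root.age - max(l.age for l in d.leaves))
    assert np.median(gaps) < 0.2


def test_larger_sampling_rate_never_older_nodes(record, rng):
    """Stochastic dominance: more sampling -> younger inferred ages."""
    cfg, rec = record
    topo = rec.observed_tree.copy()
    for n in topo.nodes:
        n.age = None
    medians = []
    for r in (0.05, 0.5):
        rng_r = np.random.default_rng(99)  # coupled seeds
        dated = pr.date_replicates(topo, rec.ranges,
                                   pr.RateParams(cfg.p, cfg.q, r), rng_r, 30)
        medians.append(np.median([d.root.age for d in dated]))
    assert medians[1] <= medians[0]


def test_dating_requires_binary_tree_and_full_ranges(rng):
    bins = pr.BinTable([TimeBin("Puercan", 66.0, 63.3)])
    ranges = pr.RangeTable([TaxonRange(t, "Puercan", "Puercan")
                            for t in "ABC"], bins)
    poly = pr.parse_newick("(A,B,C);")
    with pytest.raises(pr.ValidationError, match="polytom"):
        pr.cal3_date(poly, ranges, bins, pr.RateParams(0, 0, 0.5), rng)
    tree = pr.parse_newick("((A,B),(C,D));")
    with pytest.raises(pr.ValidationError, match="missing"):
        pr.cal3_date(tree, ranges, bins, pr.RateParams(0, 0, 0.5), rng)
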