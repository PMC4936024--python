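# Methods

`paleorates` implements a pipeline for asking, from fossil data alone,
whether and where rates of discrete morphological evolution shifted across
a phylogeny and across geological time: time-scale cladograms of binned
fossil taxa under a birth–death–sampling model, count unambiguous
parsimony character changes per branch, and compare branch/clade/bin rates
against a duration-proportional randomization null.  This note records the
models, the parameters that matter, the choices made where the design was
open, and what the synthetic experiments do and do not establish.

## Time-scaling model

Taxa originate at rate *p*, go extinct at rate *q* and are fossil-sampled
at rate *r*, each per lineage-Myr.  Inputs are a rooted (binary, after
random polytomy resolution) cladogram, a table of named time bins with
bounds in Ma, and each taxon's first/last-appearance bins.  Ages use Ma
before present (larger = older); bins are half-open `[older, younger)`, so
an event exactly on a boundary belongs to the younger bin.

One dating replicate is drawn as follows:

1. every tip's age is drawn uniformly within its first-appearance (FAD)
   bin — uniform being the maximum-entropy reading of bin-level resolution;
2. each internal node is anchored to its clade's *first appearance* `F`
   (the oldest drawn tip age in its subtree) and dated `F + w`, where `w`
   is the waiting time from a divergence to the first sampled fossil
   anywhere in the descendant clade under the (p, q, r) process;
3. nodes are processed root-to-tips, each `w` truncated above by the
   parent's already-drawn age (the root by `max_gap`, default 30 Myr), so
   every output satisfies age monotonicity and FAD containment by
   construction.

The waiting-time law is realised by forward event simulation of the
birth–death–sampling clade with rejection (extinct-unsampled or
over-window histories are discarded) rather than in closed form; with
`p = q = 0` it reduces exactly to a truncated Exponential(r), which the
tests use as an oracle, and an independent event-by-event simulator checks
the general case distributionally.  When the truncation window is narrow
(`(p+q+r)·window < 0.05`) birth and death are negligible before the bound
and the draw uses the exact narrow-window law, a truncated Exponential(r);
this is what keeps the nested-node regime (which otherwise produces
near-zero acceptance probabilities and the familiar zero-length-branch
behaviour of stochastic fossil dating) both exact and fast.

**Rate estimation.**  When not supplied, the per-bin sampling probability
comes from the frequency-ratio estimator `R = f2²/(f1·f3)` on the taxon
duration-frequency distribution (f_k = taxa spanning k bins), capped at
0.999 and converted by `r = −ln(1−R)/meanBinLength`; extinction comes from
the survivorship decay of the same distribution (OLS slope of ln f_k on
k); and origination is set equal to extinction, because net
diversification is not identifiable from a non-ultrametric fossil tree and
zero net diversification is the appropriate null.  Both estimators are
coarse when bins are long relative to typical ranges (most taxa then span
a single bin); the worked examples show the resulting over/under-shoot,
and fixed user-supplied rates are accepted everywhere, including
sensitivity scenarios such as a 0.5 %-per-Myr or an 85 %-per-bin sampling
regime.

**Polytomies** are resolved uniformly at random over all labelled binary
arrangements of the polytomy's children, by sequential random edge
insertion ((2k−3)!! resolutions for k children; the tests verify
uniformity by enumeration at k = 3 and 4).

Ancestor–descendant (sampled-ancestor) placement is not implemented: all
taxa are terminal.

## Unambiguous change counting

Parsimony reconstructions are rarely unique, and resolving ties
stemward (ACCTRAN) or crownward (DELTRAN) would manufacture rate structure
exactly where this pipeline looks for it.  A change is therefore counted
on a branch only when **every** most-parsimonious reconstruction implies
it: the count is the minimum, over all MPRs, of the steps on that branch.

Both unordered and ordered (linear step cost) characters run through one
generalised Sankoff dynamic programme: a postorder pass gives per-node,
per-state subtree costs; a preorder pass gives rest-of-tree costs; the
per-branch count is the minimum of `cost(s_parent, s_child)` over state
pairs attaining the global optimum, and per-node MPR state sets fall out
of the same quantities.  This is exactly the enumeration definition (the
acceptance suite checks every topology with ≤5 tips exhaustively and
6-tip trees at scale), not the weaker parent/child set-distance, though
the two usually coincide.  Multi-step ordered transitions count their full
step span.  Missing (`?`) and inapplicable (`-`) cells both carry the full
state set — they can never force a change onto their own pendant branch —
and character weights multiply counts.  On a rooted tree the single change
of a "cladistically ideal" character can sit on either basal branch, so
neither basal branch receives it; this is the correct unambiguous reading,
and it matters for the calibration caveat below.

## Randomization tests

The null is uniform change rate per lineage-Myr: the tree's summed branch
duration is a 0–1 continuum, each branch owns a duration-proportional
share, and the observed total `N` (rounded weighted unambiguous count) is
scattered uniformly — per replication, one multinomial draw of `N` over
branches.  Defaults: 1000 replications, threshold 0.95.  A branch flags
*high* when its observed count strictly exceeds its null count in ≥95 % of
replications, *low* symmetric; ties support neither tail; no
multiple-testing correction by default (a Bonferroni switch exists),
matching standard practice for this test.  The same replication set feeds:

* **clade shifts** — per internal node (root excluded), observed vs null
  changes summed over the branches strictly inside the clade (descendant
  edges; the subtending stem is left out so the statistic is about the
  clade's own regime);
* **bin series** — per bin, the median and MAD of whole-branch rates
  (changes/duration) over every branch whose age interval overlaps the
  bin, pooled across a sample of dated trees; significance compares the
  observed bin median against the medians recomputed under each null
  replication.  Branches shorter than `duration_floor` (0.01 Myr) are
  excluded from medians but still receive null counts.  An alternative
  that apportions changes along branch length sits behind
  `NullConfig.apportion`, off by default; the whole-branch reading of
  "branches passing through a bin" is the default because it is the
  literal one.

## Synthetic data

The generator produces exactly what the pipeline consumes, plus ground
truth.  A single lineage starts at the oldest bin bound (default bins:
three 10-Myr pre-boundary and two 5-Myr post-boundary stage-like bins,
96–56 Ma, boundary at 66 Ma) and evolves by bifurcating speciation
(p = 0.15), extinction (q = 0.05) and Poisson fossil sampling (r = 0.2,
all per lineage-Myr), survivors censored at the young window edge.  Under
the bifurcating species concept each tree segment is a taxon; terminal
segments with ≥1 sample become observed taxa (FAD/LAD = bins of their
first/last samples), and samples on internal segments — sampled ancestors
— are discarded, matching the terminal-taxa scope of the dating model.
Records are conditioned by rejection on 25–80 sampled taxa (typically
30–45, emulating a well-sampled radiating clade; the critical p = q case
from a single origin essentially never yields clades of that size, which
is why the defaults are supercritical).  Characters (default 100; 30 %
three-state, 20 % ordered) evolve as symmetric Markov jump processes at
`base_char_rate` (0.005 changes/character/LMY, i.e. ~2–3 changes per
character across a typical tree, a realistic homoplasy level for cladistic
matrices) times a per-bin multiplier; every change event is retained with
its branch and age.  Same seed, same outputs, bit for bit.

What the generator does **not** emulate: correlated characters, mosaic
rates across anatomy, missing data (supported in the formats, absent from
generated matrices), preservation regimes that vary by time or geography,
and sampled ancestors.  Passing tests therefore show the machinery is
correct and calibrated *under the stated model*, not that real matrices
satisfy that model.

## Known limitations (measured, not hypothetical)

The test suite and `scripts/acceptance.py` quantify two intrinsic
properties of unambiguous-change counting that a user should know:

* **Depth-dependent undercounting.**  Ambiguous changes concentrate on
  deep internal branches (fewer constraining tips, basal-edge ambiguity),
  so deep/old structures lose counted changes while pendant-rich shallow
  structures keep theirs.  Under fully homogeneous simulation the
  branch-level high-flag rate stays at the nominal ~3–4 %, but clade- and
  bin-level high flags run at roughly 6–10 % — feeding the *true*
  simulated counts through the identical tests restores ≤5 % everywhere,
  isolating the filter as the cause.  Old bins likewise accumulate excess
  *low* flags.
* **Dilution of episodes.**  A genuine 3× change-rate episode confined to
  a 5-Myr bin is recovered at a pooled post/pre median ratio of about 2
  (the bin still flags high in ~85–90 % of replicate datasets): branches
  overlapping the bin average their rate over their whole span, and the
  depth gradient depresses the pre-boundary baseline unevenly.

The dating sampler's sequential root-down construction ignores the extra
conditioning the full observed record would impose, leaving a small young
bias at deep nodes; central 95 % intervals cover true root ages for
roughly 80 % of simulated datasets at default settings.

## Reproducibility

Every stochastic entry point takes a `numpy.random.Generator` or a seed;
the pipeline spawns independent per-stage substreams from one global seed,
so full runs are bit-reproducible and stages can be replayed in isolation.
Experiment sizes in the tests (200 replicate datasets for calibration,
recovery and coverage; 10⁴ draws for distributional checks; exhaustive
enumeration to 5–6 tips) were chosen as the smallest scales at which the
Monte-Carlo error is clearly below the effects being asserted.
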