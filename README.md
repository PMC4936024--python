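# paleorates

Time-scale cladograms of fossil taxa and test where — on which branches,
in which clades, in which geological stages — rates of discrete
morphological evolution were significantly elevated or depressed.

Palaeontologists asking questions like *"did evolution accelerate after a
mass extinction?"* typically have: one or more cladograms of fossil taxa,
a cladistic character–taxon matrix, and stratigraphic ranges resolved only
to named time bins (stages, land-mammal ages).  `paleorates` turns those
three ingredients into dated phylogenies with honest uncertainty, per-
branch evolutionary rates, and permutation-based significance maps — plus
a synthetic fossil-record generator with full ground truth so every stage
of the pipeline can be validated before it touches real data.

## The model in brief

* **Dating.**  Taxa originate, go extinct and are fossil-sampled at rates
  *p*, *q*, *r* per lineage-Myr (estimated from the range table via the
  frequency-ratio estimator `R = f₂²/(f₁·f₃)` and survivorship decay, or
  supplied).  Tip ages are drawn uniformly within first-appearance bins;
  each node is placed older than its clade's first appearance by a waiting
  time drawn from the birth–death–sampling law of the gap between a
  divergence and the first fossil of the descendant clade.  Repeated draws
  give a distribution of dated trees.
* **Rates.**  On each dated tree, every discrete character is optimised
  under parsimony (Fitch/Sankoff; ordered characters use linear step
  costs) and a branch is credited only with *unambiguous* changes — the
  minimum steps implied by **every** most-parsimonious reconstruction.
  Branch rate = weighted changes / duration (per lineage-Myr, LMY).
* **Significance.**  The null scatters the observed total of N changes
  over branches in proportion to branch duration (1000 replications); a
  branch / clade / time bin flags *high* when it beats its null in ≥95 %
  of replications, *low* symmetrically.  Bin series report medians and
  median absolute deviations of branch rates pooled over a sample of
  dated trees.
* **Summaries.**  Divergence-date distributions (median, central 95 %
  interval, percent older than a horizon such as the 66 Ma K–Pg boundary),
  lineages crossing a horizon, and per-bin per-capita origination and
  extinction rates.

## Worked example

From `examples/04_rate_tests.py` — simulate a radiating clade whose
character change rate triples in the first post-boundary bin (66–61 Ma),
then ask the pipeline to find the episode:

```text
branch flags: {'none': 66, 'high': 3, 'low': 3}
bin  median_rate  MAD    flag
 pre3  0.000   0.000  low
 pre2  0.284   0.183  low
 pre1  0.638   0.242  none
post1  0.756   0.296  high
post2  0.624   0.278  none
```

`median_rate` is the median over branches crossing each bin of
changes per lineage-Myr; `post1` — the bin carrying the injected 3×
episode — is the one flagged `high`.  And from
`examples/05_summaries.py`, dating the same record 200 times:

```text
whole clade: median origin 84.51 Ma, 95% interval [78.20, 95.20] Ma
100.0% of dating draws place the origin before the 66 Ma boundary
lineages crossing 66 Ma: median 12 (range 10-17)
```

The other examples cover simulation (`01`), dating and rate estimation
(`02`) and change counting (`03`); each prints a few lines and says what
they mean.  A thin CLI wraps the same library calls
(`paleorates simulate | date | changes | rates | summarize | run`).

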