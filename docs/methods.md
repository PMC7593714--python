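# Methods

## Scope and design

The package implements a network-pharmacology screening chain as a set of
independently re-runnable stages over plain-text formats (TSV, SIF, GMT,
JSON). Every stage is a pure function of its inputs; the orchestration layer
only wires files together, so two runs on identical inputs produce
byte-identical artifacts (all output tables are deterministically sorted and
no timestamps are written).

## ADME screening

Compounds are filtered on oral bioavailability (percent scale; 30.7 means
30.7 %) and drug-likeness with **strict** inequalities (OB > 30, DL > 0.18):
the conventional phrasing of the cutoffs is "over 30 %" and "more than
0.18", and the packaged worked-example table is consistent with strictness
(its minimum retained OB is 30.7, minimum DL 0.20). Values of OB above 100
are suspicious but tolerated with a warning, since they occasionally appear
in database exports. The filter is idempotent and monotone in both
thresholds; both properties are tested.

## Target assembly

Symbol matching is exact string equality after normalisation (strip,
uppercase, deduplicate); hyphens and other punctuation are preserved, and no
alias or nomenclature resolution is attempted — disease-gene tables give no
basis for one. Published target grids often repeat entries (the packaged
disease table lists one symbol three times), so the table-entry count is
reported both raw (as publications count it) and deduplicated.

## Centrality panel

Definitions adopted (the screening literature names these five measures but
rarely writes them out):

- **DC**: plain degree.
- **BC**: exact shortest-path betweenness via Brandes accumulation
  (networkx), unnormalised, each unordered pair counted once, endpoints
  excluded, disconnected pairs contributing zero. Ties in shortest-path
  counts are handled exactly by path counting, never sampling.
- **CC**: closeness with the reachable-set correction
  (r/S)·(r/(N−1)). On disconnected graphs the plain reciprocal-distance
  closeness inflates nodes in tiny components; because the hub rule compares
  every node against a single global median, the corrected form is the only
  defensible choice here.
- **NC**: sum over incident edges of the edge clustering coefficient
  z/min(deg−1, deg−1), zero when the denominator vanishes. Bounded by DC.
- **LAC**: mean degree of the neighbours within the induced neighbour
  subgraph.

Only the orderings relative to each measure's median matter downstream, and
all five measures are invariant under node relabelling; both facts are
property-tested. Agreement with an independent brute-force oracle (all-pairs
BFS with explicit path counting; exhaustive triangle enumeration) is
verified to 1e-9 on hundreds of random graphs of up to 25 nodes plus
closed-form families (complete graphs, stars, paths).

## Hub rule

hub(v) ⇔ DC(v) > f·median(DC) and BC, CC, NC, LAC each > their median,
with f = 2.0 by default (exposed as a knob) and every inequality strict —
nodes exactly at a cutoff fail. Medians are taken over **all** nodes of the
analysed graph, including zero-centrality nodes, with the even-count median
defined as the mean of the middle two. Whether the four auxiliary medians
should instead be computed after discarding nodes that fail the degree
criterion is ambiguous in the screening literature; computing them on all
nodes is the simpler and stated-order reading, and it is what the planted
recovery guarantees are calibrated against. An empty hub set is a legal
outcome, distinct from an error.

## Synthetic data

One global seed fans out into named substreams (CRC-keyed
`SeedSequence([seed, stream])`), so outputs are bit-reproducible and adding
a generator does not disturb the others. Gene symbols are synthetic
uppercase tokens `G0001…`.

- **Compound tables**: OB and DL uniform on configurable ranges that
  straddle the screening thresholds (defaults 10–60 % and 0–0.5); the draw
  is deterministically repeated until both sides of each straddled threshold
  are populated, so the filter always has a non-trivial decision.
- **Target maps**: the intersection between the union of compound targets
  and the disease list is made *exactly* round(overlap_fraction·n_disease)
  by sampling the overlap from the disease list, excluding the rest of the
  disease list from the compound-target pool, and forcing unused overlap
  genes onto a random compound. A published disease table can be swapped in.
- **Interaction graph**: a background graph over sampled universe genes
  plus an m-clique planted hub module (default m = 5 over 100 background
  nodes), each hub additionally wired to its own disjoint set of
  ⌈2·median background degree⌉ + 2 background nodes. The default background
  is a **random 3-regular graph**; Erdős–Rényi (p = 0.03) and
  Barabási–Albert backgrounds are options. The regular default is
  deliberate: with a degree-concentrated background no background node can
  exceed twice the median degree, so the planted module is recovered with
  precision = recall = 1.0 by construction, whereas the heavy degree tail of
  a sparse ER background throws occasional background nodes over the degree
  cutoff (and, with median NC = LAC = 0, any of them sitting in a triangle
  becomes a false hub) — measured at roughly one false hub per ER instance.
  The family is therefore a clean recovery benchmark, not a realistic
  degree-distribution model; see Limitations.
- **Gene sets**: random terms of size 10–40 plus planted terms (default 3,
  size 10) whose membership is ≥ 80 % hub genes (the term shrinks if the hub
  list is small); categories cycle BP/MF/CC/KEGG. A planted term with 8 hub
  members from a 20-gene query against a 500-gene universe has a
  hypergeometric tail below 1e-6, so recovery at α = 0.05 is structural.
- **Expression**: per-gene baselines uniform on [5, 10] (log2-scale,
  microarray-like), planted genes shifted ±effect in the case group
  (default effect 4, noise sd 0.5), iid Gaussian noise. The emulated public
  series' real design is not documented, so the group size default (4 per
  group) follows the animal-experiment group size of the motivating study
  design; calibration tests use 5 per group and 2000 genes.

What the generator does **not** emulate: realistic scale-free PPI degree
distributions, correlated expression noise, probe-level artefacts, or
annotation-database term overlap structure. Passing the recovery tests shows
the screening logic is implemented correctly, not that the rule has perfect
precision on real interactomes — on databases with heavy-tailed degrees it
demonstrably does not (that is the point of the median rule being a screen,
not a test).

## Enrichment statistics

Exact hypergeometric upper tails via scipy's log-gamma implementation — no
normal approximation; agreement with an exact rational-arithmetic oracle is
verified over the full (N ≤ 30, K, n, k) grid, along with pmf normalisation
to 1e-12 and strict tail monotonicity in k. The default background is the
union of all GMT members ("auto"), which is reproducible where an annotation
server's background is a moving target; it can be overridden. Raw p < 0.05
(strict) is the default significance rule, matching common reporting
practice; BH adjustment and the EASE-style conservative tail (testing k−1)
are available but off by default.

## Expression statistics

The two-group comparison uses Welch's unequal-variance t-test, two-sided —
the series-comparison convention when the original test is unnamed —
with direction taken from the sign of (case − control). Zero variance in
both groups raises a degenerate-input error rather than returning a
meaningless statistic. Null calibration (2000 genes, effect 0) keeps the
rejection rate within 0.05 ± 0.02.

For qPCR, ΔCt = Ct_target − Ct_reference per sample, the calibrator is the
arithmetic mean ΔCt of the control group, and relative expression is
2^−(ΔCt − calibrator); consequently the geometric mean of control relative
expression is exactly 1, which is asserted in tests. Group summaries report
mean ± SEM, the convention of qPCR figures.

## Numerical and degenerate-input conventions

- Medians of even-length samples: mean of the middle two, everywhere.
- Closeness of an isolated node: 0. ECC with denominator ≤ 0: 0.
- Empty inputs raise explicit errors (empty graph, empty retained set,
  empty background) — never silent zeros; an empty *result* (no hubs, no
  significant terms) is valid output.
- Tie-breaks: hubs ordered by descending degree then symbol; enrichment by
  ascending p then term id; all written sets sorted lexicographically.

## Problem sizes

Defaults are desk-scale: 105-node graphs, 50-term databases, 500-gene
universes, 20-seed recovery sweeps, 2000-gene calibration — sizes at which
every guarantee can be re-verified exhaustively against brute-force oracles
in seconds. Full-scale literature networks (hundreds of nodes, thousands of
edges, snapshot-dependent databases) are out of scope: the rule is
implemented; particular database snapshots are not reproduced.

## Known limitations

- The five centrality definitions are the standard ones; tools in the wild
  differ in normalisation and disconnected-graph handling, so absolute
  values may differ across tools even when hub sets agree.
- No edge weights or interaction-confidence scores; no directed variants.
- No symbol alias resolution; identical proteins under different symbols
  are treated as distinct.
- The ER and preferential-attachment backgrounds are provided for realism
  experiments but carry no recovery guarantee.
- No expression preprocessing (normalisation, probe mapping); matrices are
  assumed log-scale and comparable.
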