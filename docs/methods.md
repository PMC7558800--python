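# Methods

## Scope and model

`netpharm` implements the compound→target→network→module→annotation chain
of network pharmacology as five composable stages. Each stage is a pure
function over explicit inputs; the pipeline orchestrator only wires files
to functions and records provenance. All rankings are deterministic: ties
break lexicographically by symbol (or by term id), so two runs on the same
inputs produce byte-identical report tables.

## ADME screen

A candidate compound passes when OB ≥ `ob_min` (default 30, percent),
Caco-2 > `caco2_min` (default −0.4, log-scale, **strict** bound) and
DL ≥ `dl_min` (default 0.18, dimensionless in [0, 1]). The operator mix —
two inclusive bounds and one strict — follows the rule as conventionally
printed; the boundary cases OB = 30 and DL = 0.18 pass while
Caco-2 = −0.4 fails. Whitelisted compounds (literature additions) bypass
the screen entirely but keep a `whitelist` provenance flag in every
report. A non-whitelist record missing any property is rejected with a
`missing:<property>` reason code rather than silently passed. Compound
identity is by `compound_id`; duplicate ids are an input error.

## Target space

Gene symbols are normalized by strip + uppercase only — no alias
resolution, which keeps the mapping deterministic and dependency-free at
the cost of treating unresolved synonyms as distinct genes. Mapping rows
for unscreened compounds or for a species other than the configured one
(default `Homo sapiens`) are dropped with a logged count. Disease genes
are deduplicated keeping the **maximum** relevance (database exports
repeat symbols), then filtered at relevance **strictly** greater than
`min_relevance` (default 2.5); a gene at exactly 2.5 is excluded. The
shared / drug-only / disease-only partition is a plain set algebra on the
two uppercase-normalized sets.

## Network construction

The reader accepts both confidence-score dialects found in interaction
TSV exports: probabilities on [0, 1] and integers on [0, 999]. Default
`scale="auto"` decides by the maximum observed score; `score_min`
(default 0.4, the usual "medium confidence" cut) is expressed on the unit
scale and rescaled when the integer dialect is detected. Reciprocal
duplicate rows collapse keeping the larger score; self-loops are dropped;
scores are stored as found in the file. With `restrict=True` (default)
only edges between categorized genes survive, but categorized genes
without surviving edges are kept as degree-0 nodes, so the node set always
equals the categorized gene space. Degree-0 nodes never seed module
detection: the MCODE degree cutoff assigns them weight 0. Hub analysis is
by degree only; no other centralities are computed.

## Module detection (MCODE)

Vertex weight of *v*: take the subgraph induced on the closed neighborhood
N[v], find its maximum core number k, and multiply k by the loop-free
density 2E/(N(N−1)) of that k-core. Nodes with degree < `degree_cutoff`
(default 2) get weight 0.

Complexes grow from the highest-weight unvisited seed by breadth-first,
depth-limited (`max_depth`, default 100) expansion. A neighbor is admitted
when its weight is at least `(1 − node_score_cutoff)` (default cutoff 0.2)
times the weight of the **node being expanded**. This local-gradient
admission rule is a deliberate design choice over the alternative of
comparing every candidate against the seed's weight: vertex weights inside
a dense block of edge probability p spread with the binomial degree
distribution, so a fixed band around the block's maximum weight captures
only the seed's immediate weight plateau, while the gradient rule follows
the weight decay outward and recovers whole planted blocks (measured on
the benchmark below: 18/20 replicates at Jaccard ≥ 0.8 versus 0/20 for
seed-anchored admission) without admitting the sparse background, whose
weights sit far below any member's band. Admitted nodes are marked
visited, so core members of different modules are disjoint.

Post-processing per candidate: discard it if it contains no
`k_core_filter`-core (default 2); with `haircut` (default on) iteratively
remove members with fewer than two in-module neighbors — equivalent to
keeping the candidate's 2-core; with `fluff` (default off) add outside
neighbors whose closed-neighborhood density exceeds `fluff_threshold`
(default 0.1). Fluffed nodes may repeat across modules; they are reported
separately and excluded from the score.

Module score = loop-free density × node count = 2E/(N−1), computed on the
core members after haircut and reported to 3 decimals. Output order is
score descending, ties by size descending then seed symbol.

## Over-representation analysis

For effective query size n (query ∩ universe), term size K and universe
size N, the overlap k is scored by the hypergeometric upper tail
P[X ≥ k]; the EASE variant recomputes the tail at k−1 (floored so k = 1
gives p = 1), which penalizes single-gene overlaps. The plain
hypergeometric is the package default because it is verifiable against
exhaustive enumeration; EASE is offered for comparability with annotation
servers that default to it. The universe defaults to the union of the
collection's term members — the natural stand-in when the real annotation
background is proprietary — and can be overridden (e.g. to all network
genes). FDR is Benjamini–Hochberg across the terms tested within one
collection, never pooled across collections. Ranking is ascending p, ties
by overlap count descending, then term id. Fold enrichment is
(k/n)/(K/N) ≥ 0 and is the x value of the bubble-chart export.

## Synthetic-data generator

The generator emulates, per stage:

* **Compound tables** — each record passes all three screen criteria with
  probability `frac_pass`; failing records violate a random non-empty
  subset of criteria with values sampled just outside the bound, so the
  screen's boundary semantics are actually exercised.
* **Interactomes** — a planted-partition model: designated blocks wired at
  `p_in`, all other pairs at `p_out` (defaults: one 20-node block at 0.6
  over a 200-node background at 0.02). Emission is in the STRING TSV
  dialect with confidence scores uniform on [0.4, 0.999], so the default
  reader threshold keeps every emitted edge and the parser path is
  covered by the same tests.
* **Annotations** — `n_terms` random term sets over the gene universe plus
  one designated term sharing `enriched_term_overlap` members (default
  15) with the first planted block.

All randomness derives from one seeded generator (per-table substreams of
the spec seed), so a seed reproduces byte-identical files. Truth labels
always accompany generated data and are never read by an analysis stage.

What the model does **not** emulate: real interactome degree
distributions (no degree correction, no hubs by construction),
literature/ascertainment bias, overlapping complexes, or correlated
annotation terms. Passing the planted-block benchmark therefore shows the
detector finds unambiguous dense regions at realistic sparsity — not that
it resolves overlapping or degree-heterogeneous complexes in real data.

## Numerical choices and degenerate inputs

* Density is always loop-free (2E/(N(N−1))); scores are rounded to 3
  decimals only at report time, never internally.
* Score recomputation from a stored module's induced N and E reproduces
  the stored score to 1e−9 (tested).
* Empty networks yield an empty module list; singleton member sets are a
  scoring error; an empty mapping table, an empty disease table, or a
  zero-edge interaction file abort the pipeline with a stage-named error.
* Benchmark problem sizes (200-gene background, 20–40 annotation terms,
  20 replicates) were chosen as the smallest instances at which the
  planted structure is unambiguous; they keep the full suite in seconds.

## Known limitations

* No alias/ortholog resolution for gene symbols.
* No weighted-edge or overlap-aware module detection; edge confidence
  is used only as a filter threshold.
* No annotation-graph topology (term ancestry, redundancy trimming).
* Study-scale quantities that depend on retired database versions (target
  and disease-gene list sizes, full-network edge counts, exact published
  module memberships, pathway counts) are carried as packaged fixtures
  where the source printed them, and are otherwise out of scope.
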