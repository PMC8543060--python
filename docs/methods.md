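# Methods

## The model

`agnet` treats a curated or literature-mined knowledge base as an
undirected heterogeneous multigraph. Vertices are typed (`gene`,
`protein`, `metabolite`, `microRNA`, `process`, `trait`, `disease`,
`other`); edges carry a free-text relation label and a provenance tag
(`literature` or `factual_database`). Any directionality a relation may
assert (e.g. up-regulation) is kept as a label only: the centrality
statistic below counts connections regardless of direction. Self-loops
are rejected at load time — a vertex's centrality is meant to reflect
connections with *other* vertices — and parallel edges between the same
pair (different relation or provenance) are retained in the graph but
collapse to a single neighbour in every degree computation, because the
statistic is defined over vertices, not edge multiplicities.

### Network reconstruction

The associative gene network of a seed process is the set of gene and
protein vertices directly adjacent to the seed (one hop; no multi-hop
expansion), together with all knowledge-graph edges among those members.
Only `gene` and `protein` vertices become members; processes, traits and
other factor vertices never do — they enter later as scored candidates.
The optional provenance filter restricts which seed links establish
membership; internal member–member edges are not filtered. A seed with no
adjacent gene/protein is an error (the M ≥ 1 invariant), not an empty
network.

Gene and protein vertices that refer to the same locus are deliberately
*not* merged: identifier mapping between gene and protein namespaces is
knowledge-base specific and no universal rule exists, so the reconstruction
takes the graph's identifiers at face value.

### Prioritization

For a network of M members, candidate process i gets

* N_i — the number of distinct members adjacent to i in the *whole*
  knowledge graph (member–process links are counted here, never in the
  network's internal edge set);
* CTC_i = N_i / M ∈ [0, 1];
* an upper-tail inclusive hypergeometric p-value P(X ≥ N_i) with
  X ~ Hypergeom(N_U, K_i, M), computed with `scipy.stats.hypergeom.sf`.

The sampling frame is a design choice the statistic's definition leaves
open; the defaults are: N_U = number of distinct gene/protein vertices
carrying at least one process annotation anywhere in the graph; K_i =
number of distinct gene/protein vertices annotated to candidate i anywhere
in the graph; draws = M. All three are overridable through `UniverseSpec`.
Candidates with K_i = 0 are skipped rather than scored at p = 1: a process
no gene is annotated to cannot be drawn from the frame at all.

p-values are adjusted across all scored candidates of one run with the
Benjamini–Yekutieli step-up procedure (valid under arbitrary dependence —
the tests share the same drawn network, so independence cannot be
assumed), delegated to `statsmodels.stats.multitest` behind the package's
own contract-checked surface and verified in the test suite against a
from-definition implementation. Ranking order is CTC descending, then
q-value ascending, then id lexicographic; the tie-break is a convention,
not a claim.

A candidate that *is* the seed of another network may legitimately score
high; the network's own seed always scores N_i = M and can be excluded
with `--exclude-seed` where that saturation is unwanted (the comparison
fixtures do so — a seed's significance in its own network is
tautological).

### Semantic similarity

Similarity between two ontology terms is the graph-based measure of Wang
et al.: S-values decay from the anchor along child→parent paths by a
per-relation weight (defaults w_is_a = 0.8, w_part_of = 0.6 — the
measure's standard constants, configurable), each ancestor taking the
maximum over paths, computed by dynamic programming over a topological
order of the ancestor subgraph (verified against exhaustive path
enumeration on small DAGs). Similarity is the shared ancestor mass
normalised by the two terms' total semantic values; it is symmetric,
bounded in [0, 1], and exactly 1 on the diagonal. Only `is_a` and
`part_of` relations contribute; other OBO relation types are ignored with
a logged count. Terms present in the knowledge graph but absent from the
ontology get similarity 0 to everything, with a warning, since dictionary
and ontology releases drift. Similarity is computed on the significant set
only, not on all candidate pairs.

### Clustering

The full weighted similarity matrix of the significant processes — no
hard threshold by default, since Wang similarities are already in [0, 1]
and a threshold would add an unstated parameter (`--sim-threshold`
exists, default 0 = off) — is clustered with the Markov Cluster
algorithm: unit self-loops, column normalisation, then alternating
expansion (power 2) and inflation (default 2.0) with pruning at 1e-5 and
column renormalisation, until the maximum element change falls below 1e-8
or 200 iterations elapse (non-convergence clusters the last iterate with
a warning). Rows retaining diagonal flow are attractors; overlapping
attractor systems merge (union–find); nodes reached by no attractor join
their highest-similarity neighbour's cluster, or become singletons.
Cluster labels are 1..n with no gaps. Higher inflation yields more,
smaller clusters; published cluster counts from any particular knowledge
base depend on this parameter and on the underlying network and are not
reference values.

### Comparison

Across ≥ 2 conditions, the significant set of each condition is its
q < α membership (α = 0.05 default). The comparison reports the
intersection of all sets (`common_all`), every pairwise intersection, and
per-condition *specific* sets — significant in exactly one of the compared
conditions. Matching is by term id. The report is a TSV membership table
from which all sets are re-derivable.

## Synthetic fixtures

Real knowledge-base content is not redistributable, so the generators
produce graphs with planted, known structure:

* `make_knowledge_graph(FixtureSpec)` — genes are annotated to each seed
  process by Bernoulli draws (`seed_process_fraction`, default 0.5);
  planted processes link to the first seed's members at their
  `planted_ctc` probability (so that value is their expected CTC) and to
  other genes at `background_link_prob` (default 0.05); decoys use the
  background rate everywhere; gene–gene edges are Bernoulli at 0.02.
* `make_ontology(FixtureSpec)` — a complete `is_a` tree (default depth 3,
  branching 3) whose leaves double as the knowledge-graph process ids,
  plus a fraction (default 0.1) of `part_of` cross-links that always point
  to strictly shallower non-ancestor terms, so acyclicity holds by
  construction.
* `make_three_condition_fixture(seed)` — the multi-condition design: a
  shared gene pool (24) and three private pools (32 each) from which three
  seed processes draw members at 0.8, plus 300 background genes that widen
  the hypergeometric universe; three planted processes link to every
  seed's members at 0.8 (the expected common core), one per-condition
  process links at 0.8 only to that seed's private members (the expected
  specific finds), and 18 decoys link everywhere at 0.02. The pool sizes
  were chosen to give the planted effects a comfortable power margin under
  the hypergeometric test at α = 0.05 while keeping the graphs small
  enough to simulate in milliseconds.

One integer seeds a single pseudo-random stream per generator; identical
seeds give byte-identical serialisations.

What the fixtures deliberately do **not** emulate: literature-mining noise
(mis-extracted relations, synonym collisions), the scale and degree
distribution of real curated knowledge bases, gene↔protein identifier
duplication, or realistic GO topology (depth, multiple inheritance
density). Passing tests therefore demonstrate correctness of the
computations and recoverability of planted signal under clean conditions,
not performance on real literature-mined data.

## Numerical choices and degenerate inputs

* Hypergeometric tails use scipy's survival function at N_i − 1
  (inclusive upper tail); agreement with exhaustive subset enumeration is
  tested to 1e-12 for all frames with N_U ≤ 12.
* BY q-values are capped at 1 and returned in input order; empty input
  gives empty output; p = 0 is a contract violation (a true zero would be
  a certainty, not a test).
* MCL's pruning threshold (1e-5) trades exactness for sparsity; on the
  matrix sizes of interest (tens to hundreds of processes) its effect is
  below the convergence tolerance.
* Duplicate TSV records collapse; unknown vertex kinds map to `other`
  with a warning; malformed records fail with the line number.
* Ontology input with a relation cycle is a hard error naming one cycle.

## Problem sizes

The test suite and the acceptance script run entirely on generated
fixtures: random graphs up to ~50 genes × 30 processes for oracle
equivalence, 100-gene graphs over 100 replicates for planted-signal
recovery, ~450-vertex graphs for the three-condition comparison, and
exhaustive enumerations up to N_U = 12 for the hypergeometric check.
These sizes make every oracle comparison exact or exhaustive while the
whole suite completes in seconds.

## Known limitations

* The distinct-neighbour convention (parallel relations count once toward
  N_i) is a documented decision; a knowledge base that encodes evidence
  strength as edge multiplicity would need a weighted variant.
* The hypergeometric frame assumes members are an unbiased draw from the
  annotated universe; seed processes with strongly biased annotation
  (e.g. chromosome-clustered genes) violate this silently.
* No gene↔protein identifier unification, no multi-hop network expansion,
  no information-content similarity variants.
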