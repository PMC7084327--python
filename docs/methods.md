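# Methods

## Scope and model

`netpharm` implements the herb-to-mechanism inference chain used in
network pharmacology: candidate compounds are filtered on pharmacokinetic
plausibility, linked to protein targets, embedded in a protein–protein
interaction (PPI) context, clustered into dense functional modules, and
interpreted through gene-set over-representation. The object of inference
is not a fitted statistical model but a sequence of deterministic set and
graph operations plus one exact test; the scientific content is in the
thresholds, the graph algorithm, and the multiple-testing treatment, all
documented here.

## ADME screening

A component passes the strict filter iff all five criteria hold:

| criterion | rule | rationale |
|---|---|---|
| OB | ≥ 30 % | oral dose must reach circulation |
| Caco-2 | > −0.4 | below −0.4 is considered non-permeable |
| DL | ≥ 0.18 | conventional drug-likeness floor for herbal compounds |
| GI class | = High (case-insensitive) | BOILED-Egg-style absorption label, consumed as input |
| Lipinski | ≤ 1 violation | classical reading of the rule of five |

OB and DL are inclusive comparisons, Caco-2 strict, mirroring the
inequality conventions of the source criteria. Lipinski checks MW ≤ 500,
AlogP ≤ 5, H-bond donors ≤ 5, acceptors ≤ 10 and, only when the column is
present, rotatable bonds ≤ 10; tolerating one violation is deliberate —
pentacyclic triterpenes such as the boswellic acids exceed AlogP 5 yet are
conventionally counted as rule-of-five compliant. The whitelist is
configuration, not code: the bundled default contains the six components
restored in the reference analysis (five hepatoprotective compounds plus
anthraquinone). Screening is monotone by construction: relaxing any
threshold can only grow the strict-pass set.

Drug-likeness itself, when computed rather than consumed, is the
continuous Tanimoto similarity T(A,B) = A·B / (|A|² + |B|² − A·B) between
a compound's descriptor vector and the average descriptor vector of a
reference drug library. The denominator form is the canonical continuous
Tanimoto; it is symmetric, 1 on identical non-zero vectors, and bounded in
[0, 1] for non-negative descriptors.

## Component–target network

Associations carry a source tag: `identified` rows (curated evidence) are
kept unconditionally; `hitpick` rows require precision ≥ 0.5 and `sea`
rows MaxTc ≥ 0.5, both inclusive. Deduplication is plain set union on
(component, target) pairs — first within, then implicitly across sources —
because per-source unique target counts generally sum to more than the
union. Gene symbols are uppercased and stripped; no identifier-mapping
service is called, keeping the package fully offline (a static alias table
is the hook for symbol fixes). The two summary ratios are
targets/component = T/C and mean component degree per target = E/T,
reported at one decimal for display with full precision retained.

## PPI handling

STRING-dialect tables are accepted on either score scale; the dialect is
auto-detected (any score above 1 implies the 0–1000 scale, normalized by
/1000) and mixing fractional sub-1 scores with the 0–1000 scale in one
table is rejected as ambiguous rather than guessed. The confidence cutoff
is inclusive (≥). Cleaning removes self-loops and duplicate undirected
rows (keeping the maximum score), and nodes appear only as endpoints of
retained edges, so targets whose every interaction falls below the cutoff
drop out of the network — which is why a filtered network is smaller than
the target list that seeded it. Degree ranking breaks ties
lexicographically so hub lists are reproducible.

## Cluster detection

The clustering is a from-scratch implementation of the
molecular-complex-detection family of seed-and-grow algorithms:

1. *Vertex weighting.* For each node, the subgraph on its closed
   neighborhood is reduced to its highest k-core; the node's weight is
   k × density of that core, with loopless density 2E/(N(N−1)).
2. *Growth.* Seeds are taken in decreasing weight order (ties by node id);
   a neighbor joins when its weight ≥ (1 − vwp) × seed weight, with vertex
   weight percentage vwp = 0.2 by default. A vertex joins at most one
   cluster, so clusters are node-disjoint.
3. *Post-processing.* The haircut (default on) keeps the 2-core of the
   cluster subgraph, shedding loosely attached members; fluff (default
   off) may add dense boundary neighborhoods and is the one option that
   can create overlap. Finally, clusters not containing an internal
   k-core of at least `k_core` are discarded — the admission parameter the
   workflow varies between the disease network (k = 5) and the smaller
   herb∩disease overlap network (k = 2). Because the filter acts on a
   fixed set of grown clusters, raising `k_core` can only reduce the
   cluster count.

The cluster score is density × size = 2E/(N−1). This loopless form
reproduces every published (nodes, edges, score) triple checked in the
test suite to three decimals; the loop-including variant does not. Note
the formula gives 2.0, not 1.0, for a single edge — density 1 on two
nodes. All tie-breaks (seed order, growth order, output ranking by score,
then size, then smallest member id) are deterministic, so results are
invariant to node insertion order. The growth seed is always recorded on
the cluster; the implementation never reports a seedless cluster.

## Over-representation analysis

For a query of n genes against a set of K genes in a background of N, the
p-value is the exact hypergeometric upper tail P(X ≥ k) (one-sided:
over-representation only). The background defaults to the union of all
collection genes; an explicit universe overrides it, and the choice of
universe is the dominant source of variation in absolute p-values between
re-analyses — which is why absolute raw p-values from annotation-dependent
runs are not reproduction targets here, while the adjustment structure is.

The Benjamini–Hochberg step-up procedure is implemented directly (sort
ascending, adj_i = min over j ≥ i of p_(j)·m/j, capped at 1) because it
must support a family size m larger than the number of reported tests:
published tables often print a top-10 slice of a larger family, and the
printed adjusted values are only consistent with the full family size
(the bundled pathway table implies m = 146 exactly, recovered identically
from every row's p.adjust·rank/p ratio). Without the override the
implementation matches `statsmodels`' `fdr_bh`, which serves as the
cross-check in the tests. Screening applies to the *raw* p-value
(cutoff 0.05 by default) with adjusted values reported alongside;
ordering is by raw p, ties broken by larger overlap then set id; top-N
truncation is per category (BP/CC/MF tags are bookkeeping on sets, not
separate statistical families).

## Network assembly and export

The target–pathway network links each enriched set to its member (or hit)
genes; its edge count is the sum of per-pathway unique gene counts, since
targets shared between pathways fuse into single nodes. The tripartite
component–target–pathway network is the union of the C-T and T-P layers
over the shared target namespace; an id carrying different node kinds in
the two layers is an error rather than a silent merge. The bundled
pathway table maps the truncated symbol "GRIN2" to GRIN2B via the shipped
alias table — the only reading under which its unique-target union equals
the published count of 23 — and this is recorded as a fixture correction,
not a guess about biology. Exports: GraphML and edge TSV round-trip node
kinds and edge scores; SIF is the bare interaction list.

## Synthetic data

The generators exist to make every stage falsifiable offline, and their
defaults are the conditions the tests assume:

* `gen_components(n, pass_fraction, seed)` draws descriptors uniformly
  from ranges spanning typical herb constituents (MW 150–500 Da, AlogP
  −1–5, OB 10–90 %, Caco-2 −1.5–1, DL 0–0.8) and plants exact pass/fail
  labels; failing rows violate exactly one criterion (two rule-of-five
  conditions for the Lipinski mode, so the tolerated single violation
  cannot rescue them).
* `gen_planted_graph(n_background, p, module_sizes, seed)` overlays
  vertex-disjoint cliques on an Erdős–Rényi background (default test bed:
  two 6-cliques on 40 nodes at p = 0.03). Cliques rather than dense blobs
  are planted because density 1 makes the ground truth and the maximal
  score unambiguous.
* `gen_genesets(...)` plants one set with an exact query overlap among
  uniform decoys (default test bed: 50 sets of 20–40 genes in a
  1000-gene universe, query 50, planted overlap 15).

All generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`, and their outputs parse through the matching
readers. What they do **not** emulate: correlated real chemistry, the
heavy-tailed degree structure of real PPI networks, or annotation bias in
real gene-set collections — passing tests demonstrate algorithmic
correctness and calibration under the stated null, not performance on any
particular database snapshot.

## Pipeline and problem sizes

`run_pipeline` chains the six stages deterministically from a config
mapping and a seed, writing `report/`, `networks/`, `clusters/`,
`enrichment/` and a `manifest.json` (input SHA-256 checksums, effective
parameters, stage outputs; no timestamps, so identical runs produce
identical manifests). Inputs not supplied in the config fall back to the
bundled component/whitelist tables and to a seeded synthetic world on a
300-gene universe (200 disease genes, a sparse interactome with two
planted 8-cliques, ~10–30 targets per retained component). These sizes
were chosen so a full run is a sub-second smoke of every stage while
still giving the clustering and enrichment stages non-trivial structure.
The null-calibration simulation in the tests uses 200 replicates of 50
random sets over an 800-gene universe; the planted-clique recovery suite
uses 20 seeded instances.

## Known limitations

* Absolute enrichment p-values depend on the annotation snapshot and
  background; only the adjustment structure and calibrated error control
  are verified.
* The clustering reproduces the published *scores* exactly but published
  cluster *memberships* depend on an unshared interactome snapshot and
  are out of scope.
* Fluffed clusters may overlap; the disjointness guarantee holds only
  with fluff off (the default).
* GI absorption class and the tabulated OB/Caco-2/DL descriptors are
  consumed as inputs; computing them from chemical structure is out of
  scope.
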