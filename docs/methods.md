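# Methods

## The meta-pathway encoding

KGML describes two kinds of biochemical events with two different
structures: `reaction` records (metabolic; substrates → products, the
catalysing enzymes attached by a reaction id) and `relation` records
(signaling; PPrel protein–protein and PCrel protein–compound edges with
subtype annotations). `ginet` rewrites both into one grammar by
splitting every event into *formation of an intermediate* and
*production from the intermediate*.

For a metabolic reaction with substrate set S, product set P and enzyme
unit E, the intermediate node is

    ITM[s1;s2;...|E]        (substrates sorted; E empty if uncatalysed)

and the emitted edges are E → ITM (type 2), each s → ITM (type 3) and
ITM → each p (type 4). Multi-subunit enzymes additionally emit one
subunit → complex edge per member (type 1). Consequences of the
identifier scheme:

* isoenzymes catalysing the same reaction produce distinct
  intermediates (`same substrates, different enzyme slot`), so their
  regulation stays separable;
* a reversible reaction, split into two directed reactions, produces
  exactly twice the edges of its irreversible counterpart with two
  distinct intermediates per enzyme unit;
* the enzyme of a reaction is *inside* the graph: whatever signaling
  edge reaches the enzyme now reaches the metabolites downstream of it.
  This is the property that makes pathway crosstalk analysable.

Edges from an intermediate back to its enzyme ("enzyme release") are
deliberately absent: the enzyme is unchanged by the reaction, and such
edges would only create uninformative shortcuts.

A signaling relation U → V is read as U acting enzymatically on V, with
V both substrate and product (a phosphorylation modifies its target but
does not consume it): U → ITM[V|U] (type 2), V → ITM[V|U] (type 3),
ITM[V|U] → V (type 4). The self-loop V → ITM → V is intentional — it
encodes "substrate equals product". The four type labels are retained
in all output but ignored by every graph algorithm; they all denote
transformation of source into target.

### Sign placement and subtype mapping

KGML relation subtypes map to edge signs as: activation, expression →
`activation`; inhibition, repression → `inhibition`; everything else
(binding/association, phosphorylation alone, indirect effect,
dissociation, missing) → `neutral`. The sign is carried on the type-2
effector edge only; type-3/4 edges are neutral. Placing the sign on the
effector edge localises the biology (it is the effector whose action
activates or inhibits) and keeps the substrate/product plumbing
sign-free. Signs never block traversal in path analyses — an inhibitory
edge is still information flow — but are reported along retained paths.

Undirected binding/association relations emit a single triplet in the
direction stated by the file; `mirror_binding=True` adds the reciprocal
triplet. The default is conservative: mirroring invents an edge the
file does not assert.

### Complex expansion

A KGML `group` entry stores a complex with alternative subunits:
A + (B/C) + D is one group whose middle slot lists two candidates. Each
slot's alternatives (including the several gene ids a single entry may
list — KEGG's isoenzyme convention, treated as alternatives) enter a
Cartesian product; each combination becomes one concrete enzyme unit
with duplicate members collapsed, so a homo-oligomer is stored once
([{A},{A}] → {A}; copy number is not modelled). Nested groups expand
recursively, each nested unit contributing its member set to the outer
product. Unit identifiers are `CPLX[m1+m2+...]` over sorted members —
deterministic, human-readable, and collision-free because KEGG ids
contain none of `+[]`. The scheme itself is a package convention; any
injective naming would do.

### Scope rules

Entries of type `map` (links to other pathway maps) and `ortholog`
carry no species-specific molecule and are excluded from graph
construction by default (`include_map_entries=True` opts in). Relations
other than PPrel/PCrel (ECrel, maplink, ...) are parsed, classified
`other`, and ignored downstream. Only molecules *present in the file*
enter a reaction's node set: no lookup of the full reaction equation,
so ubiquitous cofactors (ATP, NADH, ...) absent from a map cannot
short-circuit functionally unrelated pathways.

## GIN assembly

Meta-pathways of one species merge by edge-set union; edges identical
in (source, target, type, sign) collapse to one edge whose provenance
is the union of contributing pathway ids. The merge is idempotent,
commutative and associative. Edges differing only in sign are kept
distinct — collapsing them would erase inhibition annotations. Output
is SIF (`source TAB relation-label TAB target`, label `t<1-4>` with an
optional `:activation`/`:inhibition` suffix) sorted lexicographically,
so a given GIN always serialises to identical bytes; provenance and the
species code live in a `<name>.prov.tsv` sidecar so the SIF stays
Cytoscape-clean.

Sub-networks are weakly connected components of the directed graph:
assembly is about which pieces hang together in the drawing, and strong
connectivity would shatter every linear cascade. Components with more
than 10 nodes are labeled 1..k by decreasing size, ties broken by the
lexicographically smallest member node. A node is *compound-related* if
it is a compound or an intermediate containing a compound in any slot
(substrates or a compound effector of a PCrel-derived intermediate);
the effector slot is included because the classification asks whether a
node involves chemistry, not which role the compound plays.

## Sub-network similarity

Gene nodes of each labeled sub-network are mapped to KEGG Orthology
ids through a user-supplied two-column TSV (genes without a mapping are
dropped and counted); compound ids pass through unchanged; intermediate
and complex nodes are construction artifacts and contribute nothing.
Similarity of two sub-networks is the Jaccard score |A∩B|/|A∪B| over
these feature sets, defined as 0 when both are empty (the 0/0 case).
The full matrix can exclude subnet 1 on both sides, focusing the
comparison on the fragments. "Matched" sub-networks are operationalised
as score ≥ 0.5 by default (a majority of the union shared); the
threshold is a package choice and configurable.

## Crosstalk analysis

Members of the two pathways are their gene and compound identifiers as
extracted from the KGML files (groups contribute their constituent
genes; intermediates never appear). Nodes belonging to both pathways
are removed from the endpoint sets and reported — they are shared
infrastructure, not crosstalk — though paths may still traverse them.
For every ordered pair (one node per pathway, both directions) the
unweighted directed shortest path is computed by breadth-first search.
Distances count **nodes**, so adjacent nodes are at distance 2. Ties
between equal-length paths resolve to the lexicographically smallest
node sequence (greedy reconstruction over BFS level sets), making every
reported path deterministic. Per direction, the single minimal pair
path is retained as the representative route; each reachable pair also
receives the display weight W = (2/n_shortest)², which is 1 for direct
contact and quadratically suppresses long detours in bipartite
connection plots.

Curation removals — (source, target) patterns with a reason — delete
the direct edge and every edge touching the intermediate `ITM[T|S]`
that the pair's signaling triplet created. A removal matching nothing
is a warning, not an error, because curation lists outlive database
releases. Removing edges can only increase distances (checked as a
property).

## Synthetic fixture generator

The generator emits structurally faithful KGML from a seeded RNG:
gene/compound/group/map entries, reversible and irreversible reactions,
isoenzyme entries (several gene ids per entry), groups with an
alternative-subunit slot, and PPrel/PCrel relations across the four
common subtypes. Identifiers use reserved namespaces (`syn:NNNN`,
`cpd:C9NNNN`) that exercise node classification without colliding with
real KEGG ids. Output is a pure function of the spec — the same seed
produces byte-identical files — and every generated file parses with
zero validation issues. One deliberate simplification: a group-catalysed
reaction carries its reaction reference on the group entry itself,
whereas real KGML usually repeats it on each member gene; the parser
accepts both.

Default sizes (12 genes, 8 compounds, 6 reactions, 6 relations per
pathway; reversibility 0.3, complex enzymes 0.25, isoenzymes 0.25) give
pathways small enough to inspect by eye yet touching every construct;
the multi-pathway set draws from one molecule namespace so overlapping
usage connects pathways in the merged GIN, which is what redundancy
removal and sub-network labeling need to be non-trivial.

Two planted structures provide exact ground truth:

* the **crosstalk motif** — cascade A → B → C where C catalyses F → G;
  its conversion must contain the bridging edge C → ITM[F|C] and a
  directed path from A to G;
* the **crosstalk pair** — a metabolic chain and a signaling cascade
  with disjoint member sets, joined by exactly one planted five-node
  bridge per direction (the inbound bridge traverses an inhibitory
  edge on purpose) plus an optional artifact route mimicking a
  misannotated ligand–receptor relation. The accompanying manifest
  (expected retained paths, node counts, weights, the curation entry
  that severs the artifact pair) is written from the construction, not
  by running the analysis, so it is an independent oracle.

What the generator does **not** emulate: realistic degree
distributions, pathway sizes, KEGG's graphics layer, or biological
coherence of the random reactions. Green tests therefore demonstrate
correctness of the conversion, merge, labeling and path machinery on
structurally representative input — not fidelity of any biological
conclusion drawn from a particular KEGG release.

## Numerical and engineering choices

* All orderings are canonical (entries by id; reactions, relations,
  edges, SIF rows lexicographic), so every artifact is byte-stable
  across runs — checked end to end.
* Jaccard and weight computations are exact rational arithmetic in
  floating point (set cardinalities; (2/n)²); no tolerances are needed
  anywhere in the library.
* Unreachable pairs carry distance ∞ (`math.inf`) and never enter the
  bipartite table.
* Degenerate inputs: empty pathway documents produce empty
  meta-pathways; an empty GIN yields all-zero statistics; an empty
  curation list is the identity; Jaccard of two empty sets is 0.
* Problem sizes in the test suite and acceptance script (pathway sets
  of 3–4 maps, random graphs up to 200 nodes, 50–1000 randomised
  trials per property) were chosen so that each independent oracle —
  brute-force Cartesian enumeration, union-find components,
  Floyd–Warshall all-pairs distances — runs exactly and the whole
  suite completes in seconds.

## Known limitations

* No stoichiometry, mass balance or thermodynamics; homo-oligomer copy
  number is ignored by design.
* The KO mapping is an input artifact; the package never calls KEGG.
* Transcription-factor-mediated indirect regulation is out of scope:
  crosstalk is computed on post-translational/metabolic edges only.
* Global statistics of a real species' GIN depend on the KEGG release
  the KGML files came from; the package reports whatever it computes
  from the given files and asserts nothing about specific releases.
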