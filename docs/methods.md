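# Methods

## The model

`aoplink` treats a curated toxicogenomic release as a relational substrate:
five tables of directly curated statements (chemical–gene, chemical–phenotype,
chemical–disease, gene–phenotype, gene–disease), each row carrying the set of
source articles behind it and, for disease relations, a direct-evidence class
(`marker_mechanism` — the chemical correlates with or plays a mechanistic role
in the disease — or `therapeutic`).  Phenotypes are GO terms, diseases live in
a MeSH/OMIM poly-hierarchy, chemicals in a MeSH-style tree.  All three
vocabularies are rooted DAGs, and every query is *subsuming*: a term stands
for itself plus its transitive descendants (`descendant_closure`).  This
mirrors how the curated database itself answers hierarchical queries, and it
is applied uniformly to phenotype retrieval, disease retrieval, chemical
categorisation, and the disease slot of tetramer queries.

An AOP is a typed event graph — one or more MIEs, intermediate KEs, terminal
AOs, joined by directed KERs.  Event typing is per-AOP (the same event id can
be an MIE in one pathway and a KE in another), events are shared across AOPs
by id, and an event may not be typed both MIE and AO within one AOP.

### Event coverage and the 1..E score

The event→term mapping is consumed, not inferred: it is inherently a
judgment call (event titles, components and descriptions rarely align with
any single vocabulary term), so the package takes it as declarative input
and ships the published six-event autism mapping as a packaged fixture
(two estrogen-receptor genes plus two signalling phenotypes; two MAP-kinase
genes plus two cascade phenotypes; the `GRIN*` wildcard plus four NMDAR
phenotypes; four synapse phenotypes; two nervous-system phenotypes; the
autism-spectrum disease restricted to marker/mechanism evidence).  A
chemical is incident to an event if at least one mapped term returns it;
several matching terms still count once.  The coverage score is the row sum
of the chemical × event incidence matrix — an integer in `1..E` — and
chemicals touching no event never appear.  Ranking sorts by score
descending, then canonical chemical id ascending; the id tie-break is
arbitrary but fixed, so reports are reproducible.

Gene-symbol wildcards are trailing-asterisk prefixes only, matched
case-insensitively.  The manual vetting step that a human performs on a
wildcard result (dropping spurious prefix matches) is reproduced as a
declarative exclusion list in the pipeline config — never interactively —
so a vetted analysis replays identically.

### Tetramers, dimers, evidence

A CGPD-tetramer (C, G, P, D) is admissible only when all five curated edges
exist: C–G, C–P, C–D, G–P, G–D.  By default the chemical–disease edge must
carry marker/mechanism evidence (consistent with how adverse-outcome
chemicals are retrieved) while the gene–disease edge accepts any direct
evidence; both filters are arguments.  Enumeration is an indexed join over
per-chemical adjacency — candidate chemicals are those with at least one
edge of each chemical-rooted kind, genes are intersected per chemical, then
phenotype and disease candidates per gene — never a materialised
cross-product; the quadruple loop over all tuples exists only as a test
oracle.  A fixed disease slot is closure-expanded and results deduplicated
on the full 4-tuple, so overlapping descendant expansions cannot repeat a
block.

The default evidence score of a tetramer is the number of distinct articles
in the union of its five edge-support sets.  The weighting that the source
database applies in its own "evidence strength" ranking is not public in
detail, so the score is a named, pluggable strategy
(`register_score_strategy`) and the distinct-article union is documented as
the transparent default; it is monotone non-decreasing in every edge's
support, which is the property downstream ranking relies on.

GP-dimers are the (gene, phenotype) projections of tetramers;
`shared_dimers` intersects the projections of two or more query results and
tallies how often each gene and phenotype occurs in the shared set.  Chord
export partitions the four roles into node groups and weights each node
pair by co-occurrence count (six pairs per tetramer); rendering is out of
scope — the export is data for whatever plotting tool the user prefers.

### Candidate-AOP assembly

Selected phenotypes are placed at four levels of biological organisation —
molecular, cellular, system, behavioral.  Level assignment is user input:
it encodes biological judgment, not graph structure, so the package refuses
to guess (the pipeline's fallback for unsupervised runs assigns levels
round-robin over the sorted shared phenotypes purely so the stage is
exercisable; any real analysis should configure levels).  Edges are
computed for *all* phenotype pairs with non-empty gene-set intersection,
not only adjacent levels — the level ordering is presentation metadata.
Every edge's shared-gene set is checked to be a subset of both endpoint
gene sets on every build, and node order (level, then id) makes rebuilds
deterministic.  Exports: GraphML (attributes: level, gene count, shared
genes) and a line-oriented text form that round-trips through `read_text`.

### Disease networks

For each mechanistic event, every mapped gene (or wildcard expansion
member) is fixed as the tetramer gene slot and every mapped phenotype as
the phenotype slot; the union of disease slots over all resulting tetramers
is the event's disease set.  An event mapped only to a disease term cannot
be queried this way — the query would be circular — and raises.  Disease
identity is the canonical id after normalisation; parent and descendant
diseases are distinct elements (no closure collapsing), matching the
treatment of a spectrum disorder and its sub-diagnoses as separate tetramer
outcomes.  `venn_cells` computes exact region counts over all `2^k − 1`
non-empty label subsets for 2–6 sets (the same counts back an UpSet-style
report; beyond six sets a Venn layout is unreadable anyway), and
`core_and_loo` returns the all-sets core, the intersection without one
dropped set, and their difference.

## The synthetic generator

The generator emulates the study conditions, not just "some data".  Its
defaults are the conditions the analysis describes:

* **Coverage tiers** `{6: 12, 5: 64, 4: 120, 3: 300, 2: 800, 1: 2352}` —
  twelve chemicals on all six events and seventy-six on five or more, with
  a long low-score tail summing to 3,648 distinct tier chemicals, the
  magnitudes of the published prioritisation.  Each tier-k chemical is
  wired to exactly k distinct events through a randomly chosen mapped term;
  hierarchical terms are hit through a random member of their descendant
  closure, so subsumption is always on the retrieval path.
* **Query-chemical tetramers** — three designated chemicals (the ids of the
  three autism-associated stressors) each receive the same block of ten
  shared GP-dimers plus ten exclusive tetramers, all ending in the autism
  branch of the disease hierarchy.  Shared-dimer genes cycle over a pool
  two-thirds the dimer count, so some genes annotate several phenotypes —
  the cross-phenotype links the candidate-AOP stage needs.  Every gene is
  paired with a fixed phenotype set and every query chemical keeps one
  fixed disease, which makes the planted edge set *closed* under the
  five-edge rule: at zero background density, enumeration returns exactly
  the planted tuples, never incidental recombinations.
* **Per-event disease structure** — one anchor chemical/gene/phenotype per
  mechanistic event fanned over a disease pool with 17 diseases common to
  all five events, 108 more common to all but the NMDAR offshoot event,
  and five private each.  The Venn core of 17 and leave-one-out gain of
  108 are therefore *emergent* from planted relations, at the magnitudes
  the published analysis reports, not constants anywhere in the pipeline.
* **Decoys** — 50 tuples carrying exactly four of the five tetramer edges,
  cycling the omitted edge through all five kinds.  Each decoy gets a
  fresh chemical and a fresh gene; since every tetramer edge involves the
  chemical or the gene, no other planted or background edge can complete
  a decoy, so decoy integrity is structural, not probabilistic.
* **Background noise** — density 0.01 (fraction of possible pairs) per
  relation kind, drawn only among background-pool entities that live
  outside every mapped-term closure.  Background can therefore add
  tetramers and dimers of its own but can neither remove planted
  recoveries nor contaminate event coverage; exact-recovery checks run at
  density 0, superset checks at positive density.
* **Articles** — per-edge support sets of size `geometric(p = 0.5)` (≥ 1)
  with globally unique synthetic article ids, enough to exercise
  evidence-score monotonicity without modelling real citation overlap.

One integer seed drives a single `numpy` generator; the same config and
seed reproduce byte-identical emitted files (relations as commented TSV,
the phenotype DAG as OBO, disease and chemical hierarchies as
tree-numbered TSVs, plus the ground-truth manifest as JSON).

**What the generator does not emulate:** real degree distributions (curated
databases are heavy-tailed; the background here is uniform), correlated
evidence across edges, organism annotations, and the absolute counts of
any specific curation revision.  Passing tests therefore demonstrate that
the pipeline's algebra is exact on known structure and stable under noise —
not that any particular live-database count will be reproduced, since those
shift with every monthly curation release.

## Numerical and design choices

* Identifier canonicalisation: upper-case namespace prefix plus colon
  (`MESH:D001321`, `GO:0006979`, `GENE:2099`); bare ids take their column's
  declared namespace.  A GO id must have exactly seven digits; the packaged
  mapping uses the seven-digit form of the one NMDAR-signalling term that
  appears in two spellings in its source.
* Duplicate relation rows identical up to their article sets merge with
  set union; rows differing in direct-evidence class stay separate, because
  the class changes query semantics.
* No organism filter by default (curated content is cross-species); an
  explicit allow-list drops rows from other organisms at load time.
* GO closure traverses `is_a` only by default; `part_of` is opt-in, and
  `regulates`-type relations are not traversed.
* Gzip is detected by magic bytes, not file extension.  XLSX readers take
  the first sheet unless a sheet is named in the column map.
* Ranking ties break on canonical chemical id; all serialisations sort
  rows, so every report is byte-stable for a fixed seed.
* Degenerate inputs: an empty tree-vocabulary file is an empty hierarchy;
  a phenotype requested for gene-set projection but absent from all
  tetramers is kept with an empty set and flagged; a coverage query with
  an empty mapping, a tetramer query with no fixed slot, and a Venn call
  outside 2–6 sets are validation errors.

## Problem sizes

The default test and acceptance runs use the study-scale snapshot
(~3,700 chemicals, ~600 planted tetramers, 200-node vocabularies), 100
random DAGs up to 200 nodes for the closure oracle, and 100 random
mini-snapshots (8 × 6 × 6 × 4 entities) for the enumeration oracle; the
whole suite completes in well under a minute.

## Known limitations

* The event→term mapping is an input; the package neither validates its
  biological plausibility nor attempts automated mapping.
* The evidence score is a stand-in ordering, not the source database's
  proprietary weighting; rankings by the two need not agree.
* Live-database quantities (per-term chemical counts, per-event disease-set
  sizes, the identity of shared diseases) depend on the curation revision
  and are not asserted anywhere; the loaders accept the deposited
  supplementary workbooks for users who have them locally.
* KER weight-of-evidence scoring per regulatory guidance, inference-network
  scoring, and chord-diagram rendering are out of scope.
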