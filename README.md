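# aoplink

Offline toolkit for joining curated toxicogenomic knowledge with adverse
outcome pathway (AOP) networks.

Public toxicogenomic resources curate pairwise relations — chemical–gene,
chemical–phenotype, chemical–disease, gene–phenotype, gene–disease — under
controlled vocabularies (Gene Ontology phenotypes, a MeSH/OMIM disease
poly-hierarchy, a MeSH chemical tree).  AOP repositories organise disease
biology as typed event graphs: a molecular initiating event (MIE) linked
through key events (KEs) to an adverse outcome (AO) by key event
relationships (KERs).  `aoplink` connects the two worlds on local files,
with no web service in the loop, for researchers who want to prioritise
candidate chemical stressors for a pathway and mine the curated relations
for new mechanistic links.

## What it computes

Given a knowledge snapshot, an AOP definition, and a mapping from each AOP
event to vocabulary terms (genes, a trailing-`*` gene-symbol wildcard,
GO phenotypes, or a disease with a direct-evidence filter):

1. **Chemical–event intersection and prioritisation.**  A chemical
   intersects an event if it has a curated relation to any of the event's
   mapped terms; hierarchical terms subsume their descendants.  Each
   chemical gets an integer coverage score in `1..E` (the number of the
   AOP's `E` events it touches), the prioritisation surface for candidate
   stressors.  Chemicals can then be grouped by shared parentage in the
   chemical hierarchy.
2. **CGPD-tetramer enumeration.**  A tetramer is a block
   (chemical *C*, gene *G*, phenotype *P*, disease *D*) admissible only
   when five directly curated relations all exist: C–G, C–P, C–D, G–P,
   G–D.  Tetramers carry the supporting article sets of their five edges
   and an evidence score (distinct supporting articles, by default).
   Projecting tetramers onto (gene, phenotype) pairs gives **GP-dimers**;
   intersecting dimer sets across query chemicals exposes the mechanistic
   intermediates they share, exported as chord-diagram data.
3. **Candidate-AOP assembly.**  Selected tetramer phenotypes, placed at
   four levels of biological organisation (molecular, cellular, system,
   behavioral), are linked wherever their tetramer gene sets intersect —
   a shared gene is independent mechanistic support for a KER.  The
   result is exported as GraphML and a text serialisation.
4. **Disease-network discovery.**  Fixing each event's mapped terms as
   tetramer queries and projecting onto the disease slot yields per-event
   disease sets; exact Venn/UpSet region counts find diseases co-using
   all events, and a leave-one-out comparison quantifies how much one
   restrictive event narrows the shared core.  Cross-AOP event sharing
   links the pathway to other outcomes.

A seeded synthetic-snapshot generator (`aoplink.synthetic_data`) emulates
a curated release at the study's scale with *planted*, machine-checkable
structure — coverage tiers, tetramers, near-miss decoys missing exactly
one edge, and a structured per-event disease core — so every stage is
testable end-to-end with no download.

## Worked example

```python
from aoplink import (
    SyntheticConfig, generate_snapshot, bundled_event_mapping,
    event_coverage, rank_chemicals, enumerate_tetramers, TetramerQuery,
    shared_dimers,
)
from aoplink.synthetic_data import synthetic_aop_definitions, AOP_ID

snapshot, truth = generate_snapshot(SyntheticConfig(seed=7, background_density=0.0))
coverage = event_coverage(
    snapshot, bundled_event_mapping(), synthetic_aop_definitions()[AOP_ID]
)
print("distinct chemicals:", len(coverage.chemicals))
print("tier sizes:", coverage.tier_sizes())
print(rank_chemicals(coverage, min_score=6).head(3).to_string(index=False))

per_query = [
    enumerate_tetramers(snapshot, TetramerQuery(chemical=c, disease="MESH:D000067877"))
    for c in truth.query_chemicals
]
shared, genes, phenos = shared_dimers(per_query)
print("shared GP-dimers:", len(shared),
      "over", len(genes), "genes and", len(phenos), "phenotypes")
```

prints

```
distinct chemicals: 3656
tier sizes: {1: 2360, 2: 800, 3: 300, 4: 120, 5: 64, 6: 12}
 chemical_id  score  MIE:112  KE:2207  KE:195  KE:2208  KE:386  AO:2209
MESH:C500001      6        1        1       1        1       1        1
MESH:C500002      6        1        1       1        1       1        1
MESH:C500003      6        1        1       1        1       1        1
shared GP-dimers: 10 over 6 genes and 10 phenotypes
```

3,656 chemicals intersect at least one event of the six-event autism AOP;
twelve reach the top tier (all six events), and the three designated query
chemicals share ten gene–phenotype dimers on their routes to the disease —
the intermediates a refined pathway would be built from.

The same run is available from the shell:

```sh
aoplink run-all --config config.yaml --seed 7
```

where `config.yaml` holds a `synthetic:` block (or `snapshot_dir:` pointing
at relation/vocabulary files), query chemicals, evidence-class options and
the output directory.  `aoplink simulate` writes a synthetic snapshot to
disk in the same dialects the loaders read (commented TSV relations, OBO,
tree-numbered vocabularies), together with its ground-truth manifest.

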