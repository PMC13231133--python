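"""Shared fixtures: hand-built snapshots and random mini-snapshots.

The random mini-snapshot builder deliberately stays tiny (a few chemicals
by a few genes/phenotypes/diseases) so brute-force oracles over every
candidate tuple remain instant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aoplink.kb_io import (
    KnowledgeSnapshot,
    RELATION_COLUMNS,
    RELATION_KINDS,
    assemble_snapshot,
)
from aoplink.vocabularies import OntologyHierarchy


def make_hierarchy(namespace: str, links: dict[str, list[str]], roots=()) -> OntologyHierarchy:
    """Build a hierarchy from {child: [parents]}; roots get empty lists."""
    h = OntologyHierarchy(namespace=namespace)
    nodes = set(links) | {p for ps in links.values() for p in ps} | set(roots)
    for n in sorted(nodes):
        h.add_term(n, n)
    for child, parents in links.items():
        for p in parents:
            h.add_parent_link(child, p)
    h.validate()
    return h


def relation_frame(rows) -> pd.DataFrame:
    """Rows: (subject, object[, evidence[, articles]]) tuples."""
    records = []
    for row in rows:
        subject, obj = row[0], row[1]
        evidence = row[2] if len(row) > 2 else None
        articles = frozenset(row[3]) if len(row) > 3 else frozenset()
        records.append(
            {
                "subject_id": subject,
                "object_id": obj,
                "direct_evidence": evidence,
                "organism_id": None,
                "support_articles": articles,
            }
        )
    return pd.DataFrame(records, columns=RELATION_COLUMNS)


def build_snapshot(
    relations: dict,
    phenotypes: dict[str, list[str]] | None = None,
    diseases: dict[str, list[str]] | None = None,
    chemicals: dict[str, list[str]] | None = None,
    genes: dict[str, str] | None = None,
) -> KnowledgeSnapshot:
    """Assemble a snapshot from terse inputs, inferring vocab membership.

    Hierarchy dicts map child -> parents; any referenced id missing from
    them is added as a root so strict assembly passes.
    """
    tables = {
        kind: relation_frame(relations.get(kind, [])) for kind in RELATION_KINDS
    }
    phenotypes = dict(phenotypes or {})
    diseases = dict(diseases or {})
    chemicals = dict(chemicals or {})
    genes = dict(genes or {})

    def referenced(namespaces):
        out = set()
        for kind, df in tables.items():
            from aoplink.kb_io import RELATION_NAMESPACES

            subj_ns, obj_ns = RELATION_NAMESPACES[kind]
            if subj_ns in namespaces:
                out |= set(df["subject_id"])
            if obj_ns in namespaces:
                out |= set(df["object_id"])
        return out

    for ident in referenced({"phenotype"}):
        phenotypes.setdefault(ident, [])
    for ident in referenced({"disease"}):
        diseases.setdefault(ident, [])
    for ident in referenced({"chemical"}):
        chemicals.setdefault(ident, [])
    for ident in referenced({"gene"}):
        genes.setdefault(ident, ident.split(":", 1)[1])
    return assemble_snapshot(
        tables,
        make_hierarchy("phenotype", phenotypes),
        make_hierarchy("disease", diseases),
        make_hierarchy("chemical", chemicals),
        genes,
        snapshot_label="test",
    )


def random_mini_snapshot(
    seed: int,
    n_chem: int = 8,
    n_gene: int = 6,
    n_pheno: int = 6,
    n_disease: int = 4,
    density: float = 0.35,
) -> KnowledgeSnapshot:
    """Random small snapshot with a nested disease pair and evidence mix."""
    rng = np.random.default_rng(seed)
    chems = [f"MESH:C{100000 + i}" for i in range(n_chem)]
    genes = [f"GENE:{10 + i}" for i in range(n_gene)]
    phenos = [f"GO:{1000000 + i}" for i in range(n_pheno)]
    diseases = [f"MESH:D{100000 + i}" for i in range(n_disease)]

    def sample(subjects, objects, with_evidence=False):
        rows = []
        for s in subjects:
            for o in objects:
                if rng.random() < density:
                    if with_evidence:
                        ev = (
                            "marker_mechanism"
                            if rng.random() < 0.7
                            else "therapeutic"
                        )
                    else:
                        ev = None
                    arts = [f"PMID:{int(rng.integers(1, 50))}"]
                    rows.append((s, o, ev, arts))
        return rows

    relations = {
        "chem_gene": sample(chems, genes),
        "chem_phenotype": sample(chems, phenos),
        "chem_disease": sample(chems, diseases, with_evidence=True),
        "gene_phenotype": sample(genes, phenos),
        "gene_disease": sample(genes, diseases, with_evidence=True),
    }
    # nest the last disease under the first to exercise closure expansion
    disease_links = {d: [] for d in diseases}
    if n_disease >= 2:
        disease_links[diseases[-1]] = [diseases[0]]
    # one nested phenotype pair likewise
    pheno_links = {p: [] for p in phenos}
    if n_pheno >= 2:
        pheno_links[phenos[-1]] = [phenos[0]]
    return build_snapshot(
        relations,
        phenotypes=pheno_links,
        diseases=disease_links,
        genes={g: f"SYM{i}" for i, g in enumerate(genes)},
    )


def brute_force_tetramers(
    snapshot: KnowledgeSnapshot,
    query,
    chem_disease_evidence="marker_mechanism",
    gene_disease_evidence=None,
) -> set[tuple[str, str, str, str]]:
    """Quadruple-loop oracle: test every candidate tuple independently."""

    def edge_set(kind, evidence):
        df = snapshot.relations[kind]
        if evidence is not None and not df.empty:
            df = df[df["direct_evidence"] == evidence]
        return set(zip(df["subject_id"], df["object_id"]))

    cg = edge_set("chem_gene", None)
    cp = edge_set("chem_phenotype", None)
    cd = edge_set("chem_disease", chem_disease_evidence)
    gp = edge_set("gene_phenotype", None)
    gd = edge_set("gene_disease", gene_disease_evidence)

    chems = {c for c, _ in cg} | {c for c, _ in cp} | {c for c, _ in cd}
    genes = set(snapshot.gene_universe)
    phenos = snapshot.phenotype_hierarchy.terms
    diseases = snapshot.disease_hierarchy.terms
    if query.chemical is not None:
        chems &= {query.chemical}
    if query.gene is not None:
        genes &= {query.gene}
    if query.phenotype is not None:
        phenos &= {query.phenotype}
    if query.disease is not None:
        diseases &= snapshot.disease_hierarchy.descendant_closure(query.disease)
    out = set()
    for c in chems:
        for g in genes:
            for p in phenos:
                for d in diseases:
                    if (
                        (c, g) in cg and (c, p) in cp and (c, d) in cd
                        and (g, p) in gp and (g, d) in gd
                    ):
                        out.add((c, g, p, d))
    return out


@pytest.fixture
def medic_fixture() -> OntologyHierarchy:
    """The autism branch: ASD parent with three descendant diseases."""
    return make_hierarchy(
        "disease",
        {
            "MESH:D001321": ["MESH:D000067877"],
            "MESH:D020817": ["MESH:D000067877"],
            "MESH:C538235": ["MESH:D000067877"],
        },
        roots=["MESH:D000067877"],
    )


@pytest.fixture
def planted_snapshot() -> KnowledgeSnapshot:
    """One complete tetramer (C1,G1,P1,D1) plus assorted extra edges."""
    return build_snapshot(
        {
            "chem_gene": [("MESH:C000001", "GENE:1")],
            "chem_phenotype": [("MESH:C000001", "GO:0000001")],
            "chem_disease": [("MESH:C000001", "MESH:D000001", "marker_mechanism")],
            "gene_phenotype": [("GENE:1", "GO:0000001")],
            "gene_disease": [("GENE:1", "MESH:D000001", "marker_mechanism")],
        }
    )
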