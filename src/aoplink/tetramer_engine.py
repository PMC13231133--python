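"""CGPD-tetramer enumeration, evidence scoring and dimer algebra.

A CGPD-tetramer is a four-identifier block — chemical, gene, phenotype,
disease — admissible only when five directly curated relations all exist
in the snapshot: chemical-gene, chemical-phenotype, chemical-disease,
gene-phenotype and gene-disease.  Missing any one edge disqualifies the
tuple.  Tetramers carry the supporting article sets of their five edges,
rankable by an evidence score; their (gene, phenotype) projections
("GP-dimers") are the units intersected across chemical queries to find
shared mechanistic intermediates.

Enumeration is implemented as indexed joins over per-chemical adjacency
(never a materialised cross-product); the brute-force quadruple loop
exists only as a test oracle.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .kb_io import KnowledgeSnapshot
from .vocabularies import LookupError_, ValidationError

__all__ = [
    "EDGE_NAMES",
    "TetramerQuery",
    "Tetramer",
    "GPDimer",
    "TetramerIndex",
    "enumerate_tetramers",
    "evidence_score",
    "register_score_strategy",
    "dimer_projection",
    "shared_dimers",
    "chord_data",
    "write_tetramers",
    "write_chord",
]

#: The five curated edges a tetramer must stand on.
EDGE_NAMES = ("chem_gene", "chem_phenotype", "chem_disease", "gene_phenotype", "gene_disease")


@dataclass(frozen=True)
class TetramerQuery:
    """A tetramer query: any non-empty subset of the four slots fixed.

    A fixed disease slot is expanded by descendant closure, mirroring
    hierarchy-subsuming retrieval (querying a parent disease also returns
    tetramers ending in its descendants).
    """

    chemical: str | None = None
    gene: str | None = None
    phenotype: str | None = None
    disease: str | None = None

    def __post_init__(self) -> None:
        if not any((self.chemical, self.gene, self.phenotype, self.disease)):
            raise ValidationError("tetramer query must fix at least one slot")


@dataclass(frozen=True)
class Tetramer:
    """One admissible (chemical, gene, phenotype, disease) block."""

    chemical_id: str
    gene_id: str
    phenotype_id: str
    disease_id: str
    edge_support: tuple[tuple[str, frozenset[str]], ...] = ()

    def support(self) -> dict[str, frozenset[str]]:
        return dict(self.edge_support)

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.chemical_id, self.gene_id, self.phenotype_id, self.disease_id)


@dataclass(frozen=True)
class GPDimer:
    """The (gene, phenotype) projection of a tetramer."""

    gene_id: str
    phenotype_id: str

    def __post_init__(self) -> None:
        if not self.gene_id or not self.phenotype_id:
            raise ValidationError("GP-dimer requires both a gene and a phenotype id")


# ---------------------------------------------------------------------------
# Indexed adjacency
# ---------------------------------------------------------------------------


class TetramerIndex:
    """Per-entity adjacency and article-support lookup over a snapshot.

    ``chem_disease_evidence`` / ``gene_disease_evidence`` restrict the
    disease edges to a direct-evidence class (``None`` accepts any).  The
    defaults require marker/mechanism evidence on the chemical-disease
    edge — consistent with adverse-outcome retrieval — and any direct
    evidence on the gene-disease edge.
    """

    def __init__(
        self,
        snapshot: KnowledgeSnapshot,
        chem_disease_evidence: str | None = "marker_mechanism",
        gene_disease_evidence: str | None = None,
    ) -> None:
        self.snapshot = snapshot
        self.adj: dict[str, dict[str, set[str]]] = {}
        self.support: dict[str, dict[tuple[str, str], frozenset[str]]] = {}
        filters = {
            "chem_disease": chem_disease_evidence,
            "gene_disease": gene_disease_evidence,
        }
        for kind in EDGE_NAMES:
            df = snapshot.relations[kind]
            evidence = filters.get(kind)
            if evidence is not None and not df.empty:
                df = df[df["direct_evidence"] == evidence]
            fwd: dict[str, set[str]] = defaultdict(set)
            supp: dict[tuple[str, str], frozenset[str]] = {}
            for subj, obj, arts in zip(
                df["subject_id"], df["object_id"], df["support_articles"]
            ):
                fwd[subj].add(obj)
                key = (subj, obj)
                supp[key] = supp.get(key, frozenset()) | arts
            self.adj[kind] = dict(fwd)
            self.support[kind] = supp

    def objects(self, kind: str, subject: str) -> set[str]:
        return self.adj[kind].get(subject, set())

    def edge_articles(self, kind: str, subject: str, obj: str) -> frozenset[str]:
        return self.support[kind].get((subject, obj), frozenset())


def enumerate_tetramers(
    snapshot: KnowledgeSnapshot,
    query: TetramerQuery,
    index: TetramerIndex | None = None,
    chem_disease_evidence: str | None = "marker_mechanism",
    gene_disease_evidence: str | None = None,
) -> set[Tetramer]:
    """All tetramers matching the query's fixed slots.

    The disease slot, when fixed, is expanded by descendant closure and
    the results deduplicated on the full 4-tuple (overlapping closure
    expansions would otherwise repeat tuples).  Each tetramer carries the
    article sets of its five supporting edges.

    A prebuilt :class:`TetramerIndex` can be passed to amortise adjacency
    construction across many queries.
    """
    if index is None:
        index = TetramerIndex(snapshot, chem_disease_evidence, gene_disease_evidence)
    _check_query_ids(snapshot, query)

    disease_filter: set[str] | None = None
    if query.disease is not None:
        disease_filter = snapshot.disease_hierarchy.descendant_closure(query.disease)

    chem_candidates: Iterable[str]
    if query.chemical is not None:
        chem_candidates = [query.chemical]
    else:
        chem_candidates = sorted(
            set(index.adj["chem_gene"])
            & set(index.adj["chem_phenotype"])
            & set(index.adj["chem_disease"])
        )

    out: set[Tetramer] = set()
    for chem in chem_candidates:
        genes = index.objects("chem_gene", chem)
        if query.gene is not None:
            genes = genes & {query.gene}
        if not genes:
            continue
        chem_phenos = index.objects("chem_phenotype", chem)
        if query.phenotype is not None:
            chem_phenos = chem_phenos & {query.phenotype}
        chem_diseases = index.objects("chem_disease", chem)
        if disease_filter is not None:
            chem_diseases = chem_diseases & disease_filter
        if not chem_phenos or not chem_diseases:
            continue
        for gene in genes:
            phenos = chem_phenos & index.objects("gene_phenotype", gene)
            if not phenos:
                continue
            diseases = chem_diseases & index.objects("gene_disease", gene)
            for pheno in phenos:
                for disease in diseases:
                    support = (
                        ("chem_gene", index.edge_articles("chem_gene", chem, gene)),
                        ("chem_phenotype", index.edge_articles("chem_phenotype", chem, pheno)),
                        ("chem_disease", index.edge_articles("chem_disease", chem, disease)),
                        ("gene_phenotype", index.edge_articles("gene_phenotype", gene, pheno)),
                        ("gene_disease", index.edge_articles("gene_disease", gene, disease)),
                    )
                    out.add(Tetramer(chem, gene, pheno, disease, support))
    return out


def _check_query_ids(snapshot: KnowledgeSnapshot, query: TetramerQuery) -> None:
    if query.gene is not None and query.gene not in snapshot.gene_universe:
        raise LookupError_(f"gene {query.gene!r} not in gene universe")
    if query.phenotype is not None and query.phenotype not in snapshot.phenotype_hierarchy:
        raise LookupError_(f"phenotype {query.phenotype!r} not in hierarchy")
    if query.disease is not None and query.disease not in snapshot.disease_hierarchy:
        raise LookupError_(f"disease {query.disease!r} not in hierarchy")
    # chemicals need not be hierarchy members (vocabulary coverage of
    # chemicals is reported by snapshot validation, not enforced here)


# ---------------------------------------------------------------------------
# Evidence scoring
# ---------------------------------------------------------------------------

_SCORE_STRATEGIES: dict[str, Callable[[Tetramer], float]] = {}


def register_score_strategy(name: str):
    def deco(fn: Callable[[Tetramer], float]):
        _SCORE_STRATEGIES[name] = fn
        return fn
    return deco


@register_score_strategy("distinct_articles")
def _distinct_articles(t: Tetramer) -> float:
    articles: set[str] = set()
    for _, arts in t.edge_support:
        articles |= arts
    return float(len(articles))


def evidence_score(t: Tetramer, strategy: str = "distinct_articles") -> float:
    """Evidence strength of a tetramer.

    The default strategy counts distinct supporting articles across the
    union of the five edge-support sets, which is monotone non-decreasing
    in every edge's support.  Alternative weightings can be registered
    under a name with :func:`register_score_strategy`.
    """
    try:
        fn = _SCORE_STRATEGIES[strategy]
    except KeyError:
        raise ValidationError(f"unknown evidence-score strategy {strategy!r}")
    return fn(t)


# ---------------------------------------------------------------------------
# Dimer algebra
# ---------------------------------------------------------------------------


def dimer_projection(tetramers: Iterable[Tetramer]) -> set[GPDimer]:
    """Distinct (gene, phenotype) pairs occurring in the tetramers."""
    return {GPDimer(t.gene_id, t.phenotype_id) for t in tetramers}


def shared_dimers(
    tetramer_sets: Sequence[Iterable[Tetramer] | Iterable[GPDimer]],
) -> tuple[set[GPDimer], Counter, Counter]:
    """Dimers common to every input set, with per-gene/phenotype tallies.

    Each input may be a set of tetramers (projected first) or already a
    set of dimers.  The tallies count, for every gene and phenotype, how
    many *shared* dimers contain it — the "frequently used components"
    view of the shared mechanism.
    """
    if len(tetramer_sets) < 2:
        raise ValidationError("shared_dimers requires at least two sets")
    projections: list[set[GPDimer]] = []
    for ts in tetramer_sets:
        items = set(ts)
        if items and isinstance(next(iter(items)), Tetramer):
            items = dimer_projection(items)
        projections.append(items)  # type: ignore[arg-type]
    shared = set.intersection(*projections)
    gene_tally = Counter(d.gene_id for d in shared)
    pheno_tally = Counter(d.phenotype_id for d in shared)
    return shared, gene_tally, pheno_tally


# ---------------------------------------------------------------------------
# Chord export
# ---------------------------------------------------------------------------


def chord_data(tetramers: Iterable[Tetramer]) -> dict:
    """Co-occurrence structure for chord-diagram rendering.

    Nodes are partitioned into the four roles; the ribbon weight between
    two nodes is the number of tetramers containing both.  Weights are
    symmetric by construction; each tetramer contributes C(4,2) = 6
    node pairs.
    """
    tetramers = list(tetramers)
    if not tetramers:
        raise ValidationError("chord_data requires a non-empty tetramer set")
    roles: dict[str, str] = {}
    weights: Counter = Counter()
    for t in tetramers:
        members = [
            (t.chemical_id, "chemical"),
            (t.gene_id, "gene"),
            (t.phenotype_id, "phenotype"),
            (t.disease_id, "disease"),
        ]
        for node, role in members:
            roles[node] = role
        for (a, _), (b, _) in combinations(members, 2):
            weights[tuple(sorted((a, b)))] += 1
    return {
        "groups": {
            role: sorted(n for n, r in roles.items() if r == role)
            for role in ("chemical", "gene", "phenotype", "disease")
        },
        "links": [
            {"source": a, "target": b, "weight": w}
            for (a, b), w in sorted(weights.items())
        ],
        "n_tetramers": len(tetramers),
    }


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def tetramers_to_frame(
    tetramers: Iterable[Tetramer], snapshot: KnowledgeSnapshot | None = None
) -> pd.DataFrame:
    """Tabulate tetramers in the export dialect plus edge-support columns."""
    rows = []
    for t in sorted(tetramers, key=lambda t: t.key):
        row = {
            "chemical_id": t.chemical_id,
            "gene": t.gene_id,
            "phenotype_id": t.phenotype_id,
            "disease_id": t.disease_id,
            "evidence_score": evidence_score(t),
        }
        if snapshot is not None:
            row["gene_symbol"] = snapshot.gene_universe.get(t.gene_id, "")
        for edge, arts in t.edge_support:
            row[f"articles_{edge}"] = "|".join(sorted(arts))
        rows.append(row)
    return pd.DataFrame(rows)


def write_tetramers(
    tetramers: Iterable[Tetramer],
    path: str | Path,
    snapshot: KnowledgeSnapshot | None = None,
) -> Path:
    path = Path(path)
    tetramers_to_frame(tetramers, snapshot).to_csv(path, index=False)
    return path


def write_chord(chord: Mapping, path: str | Path) -> Path:
    """Write the chord structure as a plain-text sectioned file."""
    path = Path(path)
    lines = [f"# tetramers\t{chord['n_tetramers']}"]
    for role, nodes in chord["groups"].items():
        for node in nodes:
            lines.append(f"NODE\t{node}\t{role}")
    for link in chord["links"]:
        lines.append(f"LINK\t{link['source']}\t{link['target']}\t{link['weight']}")
    path.write_text("\n".join(lines) + "\n")
    return path
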