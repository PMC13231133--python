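"""Data-driven assembly of a candidate AOP series from tetramer content.

Selected tetramer phenotypes are placed at four levels of biological
organisation (molecular, cellular, system, behavioral) and connected by
edges wherever their tetramer-derived gene sets intersect: a gene shared
between two phenotype gene-sets is independent mechanistic support for a
key-event relationship between them.  The result is a leveled phenotype
network with the triggering chemicals as stressors and a disease as the
terminal outcome, exportable as GraphML or a line-oriented text form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .tetramer_engine import Tetramer
from .vocabularies import ValidationError

__all__ = [
    "LEVELS",
    "LeveledPhenotype",
    "AOPGraphCandidate",
    "phenotype_gene_sets",
    "shared_gene_edges",
    "assemble_aop_graph",
    "write_graphml",
    "write_text",
    "read_text",
]

#: Levels of biological organisation, in pathway order.
LEVELS = ("molecular", "cellular", "system", "behavioral")


@dataclass(frozen=True)
class LeveledPhenotype:
    phenotype_id: str
    level: str
    gene_set: frozenset[str]

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(
                f"unknown level {self.level!r}; expected one of {LEVELS}"
            )


@dataclass
class AOPGraphCandidate:
    """A candidate AOP series: stressors -> leveled phenotypes -> outcome."""

    stressors: frozenset[str]
    nodes: tuple[LeveledPhenotype, ...]
    edges: tuple[tuple[str, str, frozenset[str]], ...]
    outcome: str

    def gene_set(self, phenotype_id: str) -> frozenset[str]:
        for node in self.nodes:
            if node.phenotype_id == phenotype_id:
                return node.gene_set
        raise ValidationError(f"{phenotype_id!r} is not a node of this candidate")

    def check(self) -> None:
        """Assert the structural invariants: edge genes ⊆ both endpoints."""
        for a, b, genes in self.edges:
            if a == b:
                raise ValidationError(f"self-edge on {a}")
            if not (genes <= self.gene_set(a) and genes <= self.gene_set(b)):
                raise ValidationError(
                    f"edge ({a}, {b}) carries genes outside its endpoints"
                )


def phenotype_gene_sets(
    tetramers: Iterable[Tetramer], phenotype_ids: Sequence[str]
) -> tuple[dict[str, frozenset[str]], set[str]]:
    """Per-phenotype tetramer gene sets.

    Returns the mapping and the set of requested phenotypes that occur in
    no tetramer (kept in the mapping with an empty set, but flagged so a
    report can call them out).
    """
    if not phenotype_ids:
        raise ValidationError("no phenotypes selected")
    tetramers = list(tetramers)
    out: dict[str, set[str]] = {p: set() for p in phenotype_ids}
    for t in tetramers:
        if t.phenotype_id in out:
            out[t.phenotype_id].add(t.gene_id)
    frozen = {p: frozenset(g) for p, g in out.items()}
    flagged = {p for p, g in frozen.items() if not g}
    return frozen, flagged


def shared_gene_edges(
    gene_sets: Mapping[str, Iterable[str]]
) -> list[tuple[str, str, frozenset[str]]]:
    """One edge per unordered phenotype pair with shared genes.

    Pairs whose gene sets are disjoint are omitted; every phenotype pair
    is compared, regardless of level (level ordering is presentation
    metadata, not a connectivity constraint).
    """
    if len(gene_sets) < 2:
        raise ValidationError("need at least two phenotype gene sets")
    sets = {p: frozenset(g) for p, g in gene_sets.items()}
    edges = []
    for a, b in combinations(sorted(sets), 2):
        shared = sets[a] & sets[b]
        if shared:
            edges.append((a, b, shared))
    return edges


def assemble_aop_graph(
    stressors: Iterable[str],
    leveled: Mapping[str, str],
    gene_sets: Mapping[str, Iterable[str]],
    outcome: str,
    edges: Sequence[tuple[str, str, frozenset[str]]] | None = None,
) -> AOPGraphCandidate:
    """Assemble and validate the candidate graph.

    ``leveled`` maps each phenotype to its level; ``edges`` defaults to
    :func:`shared_gene_edges` over the gene sets.  Nodes are ordered by
    level (molecular < cellular < system < behavioral), then id, so
    rebuilding from the same input is deterministic.
    """
    for pheno, level in leveled.items():
        if level not in LEVELS:
            raise ValidationError(f"unknown level {level!r} for {pheno}")
    missing = set(leveled) - set(gene_sets)
    if missing:
        raise ValidationError(f"no gene sets for leveled phenotypes {sorted(missing)}")
    if edges is None:
        edges = shared_gene_edges({p: gene_sets[p] for p in leveled}) if len(leveled) > 1 else []
    nodes = tuple(
        LeveledPhenotype(p, leveled[p], frozenset(gene_sets[p]))
        for p in sorted(leveled, key=lambda p: (LEVELS.index(leveled[p]), p))
    )
    candidate = AOPGraphCandidate(
        stressors=frozenset(stressors),
        nodes=nodes,
        edges=tuple(sorted(edges, key=lambda e: (e[0], e[1]))),
        outcome=outcome,
    )
    candidate.check()
    return candidate


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------


def to_networkx(candidate: AOPGraphCandidate) -> nx.Graph:
    g = nx.Graph()
    for node in candidate.nodes:
        g.add_node(
            node.phenotype_id,
            level=node.level,
            gene_count=len(node.gene_set),
            genes="|".join(sorted(node.gene_set)),
        )
    for a, b, genes in candidate.edges:
        g.add_edge(a, b, shared_genes="|".join(sorted(genes)), weight=len(genes))
    g.graph["stressors"] = "|".join(sorted(candidate.stressors))
    g.graph["outcome"] = candidate.outcome
    return g


def write_graphml(candidate: AOPGraphCandidate, path: str | Path) -> Path:
    path = Path(path)
    nx.write_graphml(to_networkx(candidate), path)
    return path


def write_text(candidate: AOPGraphCandidate, path: str | Path) -> Path:
    """Line-oriented serialisation (STRESSOR/NODE/EDGE/OUTCOME records)."""
    path = Path(path)
    lines = []
    for s in sorted(candidate.stressors):
        lines.append(f"STRESSOR\t{s}")
    for node in candidate.nodes:
        lines.append(
            f"NODE\t{node.phenotype_id}\t{node.level}\t"
            + "|".join(sorted(node.gene_set))
        )
    for a, b, genes in candidate.edges:
        lines.append(f"EDGE\t{a}\t{b}\t" + "|".join(sorted(genes)))
    lines.append(f"OUTCOME\t{candidate.outcome}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_text(path: str | Path) -> AOPGraphCandidate:
    """Parse the text serialisation back into a candidate graph."""
    stressors: list[str] = []
    leveled: dict[str, str] = {}
    gene_sets: dict[str, frozenset[str]] = {}
    edges: list[tuple[str, str, frozenset[str]]] = []
    outcome = ""
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        tag = parts[0]
        if tag == "STRESSOR":
            stressors.append(parts[1])
        elif tag == "NODE":
            pheno, level = parts[1], parts[2]
            genes = frozenset(g for g in parts[3].split("|") if g) if len(parts) > 3 else frozenset()
            leveled[pheno] = level
            gene_sets[pheno] = genes
        elif tag == "EDGE":
            genes = frozenset(g for g in parts[3].split("|") if g) if len(parts) > 3 else frozenset()
            edges.append((parts[1], parts[2], genes))
        elif tag == "OUTCOME":
            outcome = parts[1]
        else:
            raise ValidationError(f"{path}: unknown record tag {tag!r}")
    return assemble_aop_graph(stressors, leveled, gene_sets, outcome, edges=edges)
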