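"""Hierarchy algebra over controlled vocabularies.

CTD-style resources organise phenotypes (Gene Ontology), diseases (MEDIC,
a MeSH/OMIM poly-hierarchy) and chemicals (MeSH chemical tree) as rooted
directed acyclic graphs.  Queries against a term are *subsuming*: data
annotated to any descendant of the query term count for the term itself.
This module provides that closure semantics, canonical identifier
normalisation, and prefix-wildcard gene-symbol expansion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "ValidationError",
    "LookupError_",
    "OntologyHierarchy",
    "GenePattern",
    "normalize_identifier",
    "expand_gene_pattern",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural contract."""


class LookupError_(KeyError):
    """Raised when a term id is not a member of the queried structure."""


# ---------------------------------------------------------------------------
# Identifier normalisation
# ---------------------------------------------------------------------------

#: Canonical patterns per namespace, applied AFTER prefixing/upper-casing.
_CANONICAL = {
    "gene": re.compile(r"^GENE:\d+$"),
    "phenotype": re.compile(r"^GO:\d{7}$"),
    "disease": re.compile(r"^(MESH:[CD]\d{6,9}|OMIM:\d{6})$"),
    "chemical": re.compile(r"^MESH:[CD]\d{6,9}$"),
    "event": re.compile(r"^(MIE|KE|AO):\d+$"),
    "aop": re.compile(r"^AOP:\d+$"),
}

#: Default prefix attached to bare identifiers, per namespace.
_BARE_PREFIX = {
    "gene": "GENE:",
    "phenotype": "GO:",
    "disease": "MESH:",
    "chemical": "MESH:",
    "aop": "AOP:",
}


def normalize_identifier(raw: str, namespace: str) -> str:
    """Return the canonical upper-case prefixed form of an identifier.

    Bare identifiers are prefixed with the declared namespace's prefix
    ("d001321" in the disease namespace becomes "MESH:D001321"); already
    canonical identifiers pass through unchanged, so the function is
    idempotent.

    Raises
    ------
    ValidationError
        If ``raw`` is empty, the namespace is unknown, or the result does
        not match the namespace's canonical shape (e.g. a GO id without
        exactly seven digits).
    """
    if namespace not in _CANONICAL:
        raise ValidationError(f"unknown namespace {namespace!r}")
    if raw is None or not str(raw).strip():
        raise ValidationError(f"empty identifier in namespace {namespace!r}")
    ident = str(raw).strip().upper()
    if ":" not in ident and namespace in _BARE_PREFIX:
        ident = _BARE_PREFIX[namespace] + ident
    if not _CANONICAL[namespace].match(ident):
        raise ValidationError(
            f"identifier {raw!r} is not a valid {namespace} id "
            f"(canonical form would be {ident!r})"
        )
    return ident


# ---------------------------------------------------------------------------
# Ontology hierarchies
# ---------------------------------------------------------------------------


@dataclass
class OntologyHierarchy:
    """A rooted acyclic term graph supporting subsumption queries.

    Parent links point child -> parent.  Multiple parents are allowed
    (GO is a DAG; MEDIC merges MeSH tree positions), multiple roots are
    allowed.  Closure queries treat every stored relation label (``is_a``,
    ``part_of``, tree-number parentage ...) identically; filtering by
    label happens at construction time.
    """

    namespace: str
    _graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    # -- construction -------------------------------------------------------

    def add_term(self, term_id: str, name: str = "") -> None:
        self._graph.add_node(term_id, name=name)

    def add_parent_link(self, child_id: str, parent_id: str, label: str = "is_a") -> None:
        """Record ``child_id`` as a child of ``parent_id``.

        Both ends must have been declared with :meth:`add_term`.
        """
        for tid in (child_id, parent_id):
            if tid not in self._graph:
                raise ValidationError(
                    f"parent link ({child_id} -> {parent_id}) references "
                    f"undeclared term {tid!r}"
                )
        self._graph.add_edge(child_id, parent_id, label=label)

    def validate(self) -> None:
        """Check acyclicity; raise :class:`ValidationError` listing one cycle."""
        if not nx.is_directed_acyclic_graph(self._graph):
            cycle = nx.find_cycle(self._graph)
            path = " -> ".join(str(a) for a, _ in cycle) + f" -> {cycle[0][0]}"
            raise ValidationError(f"hierarchy contains a cycle: {path}")

    # -- inspection ---------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._graph

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def terms(self) -> set[str]:
        return set(self._graph.nodes)

    def name(self, term_id: str) -> str:
        self._require(term_id)
        return self._graph.nodes[term_id].get("name", "")

    @property
    def roots(self) -> set[str]:
        return {n for n in self._graph.nodes if self._graph.out_degree(n) == 0}

    def parents(self, term_id: str) -> set[str]:
        self._require(term_id)
        return set(self._graph.successors(term_id))

    def children(self, term_id: str) -> set[str]:
        self._require(term_id)
        return set(self._graph.predecessors(term_id))

    def parent_links(self) -> set[tuple[str, str, str]]:
        """All (child, parent, label) triples."""
        return {
            (c, p, d.get("label", "is_a")) for c, p, d in self._graph.edges(data=True)
        }

    def _require(self, term_id: str) -> None:
        if term_id not in self._graph:
            raise LookupError_(
                f"term {term_id!r} is not in the {self.namespace} hierarchy"
            )

    # -- subsumption queries ------------------------------------------------

    def descendant_closure(self, term_id: str) -> set[str]:
        """The term itself plus all transitive descendants.

        This is CTD's query semantics: data annotated to any member of the
        closure are subsumed and reported for the query term.
        """
        self._require(term_id)
        # edges run child -> parent, so descendants are graph *ancestors*
        return {term_id} | nx.ancestors(self._graph, term_id)

    def ancestors(self, term_id: str) -> set[str]:
        """All transitive ancestors, excluding the term itself."""
        self._require(term_id)
        return nx.descendants(self._graph, term_id)


# ---------------------------------------------------------------------------
# Gene patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenePattern:
    """A gene-symbol pattern: a literal symbol or a trailing-asterisk prefix.

    The only wildcard form supported is a trailing ``*`` ("GRIN*"), matching
    case-insensitively on the symbol prefix.  A lone ``*`` is rejected: an
    unbounded match over the whole gene universe is never meaningful.
    """

    pattern: str
    match_field: str = "symbol"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValidationError("empty gene pattern")
        if self.pattern == "*":
            raise ValidationError("a lone '*' gene pattern is not allowed")
        if "*" in self.pattern[:-1]:
            raise ValidationError(
                f"only trailing-asterisk wildcards are supported: {self.pattern!r}"
            )

    @property
    def is_wildcard(self) -> bool:
        return self.pattern.endswith("*")


def expand_gene_pattern(
    pattern: GenePattern,
    gene_universe: Mapping[str, str],
    exclude_symbols: Iterable[str] = (),
) -> set[str]:
    """Expand a gene pattern to the matching gene ids.

    ``gene_universe`` maps gene id -> gene symbol.  Matching is
    case-insensitive.  ``exclude_symbols`` reproduces, declaratively, the
    manual vetting step that removes spuriously matched symbols from a
    wildcard expansion (e.g. keeping only NMDA-receptor "GRIN" genes).
    Literal patterns match at most one symbol.
    """
    excluded = {s.upper() for s in exclude_symbols}
    if pattern.is_wildcard:
        prefix = pattern.pattern[:-1].upper()
        return {
            gid
            for gid, sym in gene_universe.items()
            if sym.upper().startswith(prefix) and sym.upper() not in excluded
        }
    literal = pattern.pattern.upper()
    return {
        gid
        for gid, sym in gene_universe.items()
        if sym.upper() == literal and sym.upper() not in excluded
    }
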