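"""Chemical-event intersection, coverage scoring and prioritisation.

Each event of an adverse outcome pathway is mapped to one or more curated
vocabulary terms (genes, gene-symbol wildcards, GO phenotypes, or a
disease with an evidence-class filter).  A chemical *intersects* an event
when it has at least one curated relation to any of that event's mapped
terms, with hierarchical terms expanded by descendant closure.  Counting
the distinct events each chemical touches yields an integer coverage
score in 1..E — the prioritisation surface for candidate stressors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .kb_io import AOPDefinition, FormatError, KnowledgeSnapshot
from .vocabularies import (
    GenePattern,
    LookupError_,
    ValidationError,
    expand_gene_pattern,
    normalize_identifier,
)

__all__ = [
    "MappedTerm",
    "EventMapping",
    "CoverageMatrix",
    "chemicals_for_term",
    "event_coverage",
    "rank_chemicals",
    "categorize_chemicals",
    "load_event_mapping",
    "bundled_event_mapping",
    "load_coverage_workbook",
]

TERM_KINDS = ("gene", "gene_pattern", "phenotype", "disease")


@dataclass(frozen=True)
class MappedTerm:
    """One vocabulary term standing in for (part of) an AOP event."""

    term_kind: str
    term: str | GenePattern
    evidence_filter: str | None = None

    def __post_init__(self) -> None:
        if self.term_kind not in TERM_KINDS:
            raise ValidationError(f"unknown term kind {self.term_kind!r}")
        if self.evidence_filter is not None and self.term_kind != "disease":
            raise ValidationError(
                "evidence_filter applies only to disease terms "
                f"(got {self.term_kind!r})"
            )


@dataclass
class EventMapping:
    """Ordered lists of mapped terms per event, plus explicit gaps.

    Events the mapping deliberately leaves unmapped are listed in
    ``unmapped`` so coverage can distinguish "no terms found" from
    "forgot this event".
    """

    terms: dict[str, list[MappedTerm]]
    unmapped: set[str] = field(default_factory=set)

    def events(self) -> set[str]:
        return set(self.terms) | set(self.unmapped)


def load_event_mapping(path: str | Path) -> EventMapping:
    """Read an event mapping TSV (event_id, term_kind, term, evidence_filter).

    A row with term_kind ``unmapped`` flags an event that intentionally
    has no vocabulary equivalent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    required = {"event_id", "term_kind", "term"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    terms: dict[str, list[MappedTerm]] = {}
    unmapped: set[str] = set()
    for _, row in df.iterrows():
        event = normalize_identifier(row["event_id"], "event")
        kind = row["term_kind"].strip()
        if kind == "unmapped":
            unmapped.add(event)
            continue
        raw = row["term"].strip()
        term: str | GenePattern
        if kind == "gene_pattern":
            term = GenePattern(raw)
        elif kind in ("gene", "phenotype", "disease"):
            term = normalize_identifier(raw, kind)
        else:
            raise ValidationError(f"{path}: unknown term kind {kind!r}")
        evidence = row.get("evidence_filter", "")
        if pd.isna(evidence):
            evidence = ""
        evidence = str(evidence).strip() or None
        terms.setdefault(event, []).append(MappedTerm(kind, term, evidence))
    return EventMapping(terms=terms, unmapped=unmapped)


def bundled_event_mapping() -> EventMapping:
    """The packaged event-term mapping for the autism AOP (AOP:522).

    Encodes the published mapping of the six events to CTD terms: the two
    estrogen-receptor genes and signalling phenotypes for the MIE, the
    MAPK genes and ERK-cascade phenotypes, the GRIN* wildcard and NMDAR
    phenotypes, the synapse phenotypes, the nervous-system phenotypes,
    and Autism Spectrum Disorder restricted to marker/mechanism evidence.
    """
    ref = resources.files("aoplink.data") / "aop522_event_mapping.tsv"
    with resources.as_file(ref) as path:
        return load_event_mapping(path)


# ---------------------------------------------------------------------------
# Retrieval
# ---------------------------------------------------------------------------


def _pairs(snapshot: KnowledgeSnapshot, kind: str) -> pd.DataFrame:
    return snapshot.relations[kind]


def chemicals_for_term(
    snapshot: KnowledgeSnapshot,
    term: MappedTerm,
    exclude_symbols: Iterable[str] = (),
) -> set[str]:
    """All chemicals with a curated relation to the mapped term.

    Gene terms match any chemical-gene interaction regardless of action;
    wildcard patterns union over their expansion (after applying the
    declarative vetting exclusions); phenotype and disease terms are
    expanded by descendant closure before matching, and disease terms may
    additionally restrict to a direct-evidence class.
    """
    if term.term_kind == "gene":
        df = _pairs(snapshot, "chem_gene")
        if term.term not in snapshot.gene_universe:
            raise LookupError_(f"gene {term.term!r} not in gene universe")
        return set(df.loc[df["object_id"] == term.term, "subject_id"])
    if term.term_kind == "gene_pattern":
        genes = expand_gene_pattern(term.term, snapshot.gene_universe, exclude_symbols)
        df = _pairs(snapshot, "chem_gene")
        return set(df.loc[df["object_id"].isin(genes), "subject_id"])
    if term.term_kind == "phenotype":
        closure = snapshot.phenotype_hierarchy.descendant_closure(term.term)
        df = _pairs(snapshot, "chem_phenotype")
        return set(df.loc[df["object_id"].isin(closure), "subject_id"])
    # disease
    closure = snapshot.disease_hierarchy.descendant_closure(term.term)
    df = _pairs(snapshot, "chem_disease")
    mask = df["object_id"].isin(closure)
    if term.evidence_filter is not None:
        mask &= df["direct_evidence"] == term.evidence_filter
    return set(df.loc[mask, "subject_id"])


# ---------------------------------------------------------------------------
# Coverage and ranking
# ---------------------------------------------------------------------------


@dataclass
class CoverageMatrix:
    """Chemical × event incidence with per-chemical coverage scores.

    ``incidence`` is a boolean frame indexed by chemical id with one
    column per event; ``scores`` is its row sum.  Chemicals intersecting
    no event are never present, so scores run 1..E.  Rows are ordered by
    descending score, then ascending chemical id.
    """

    incidence: pd.DataFrame
    scores: pd.Series

    @classmethod
    def from_incidence(
        cls, incidence: pd.DataFrame, events: Sequence[str]
    ) -> "CoverageMatrix":
        incidence = incidence.reindex(columns=list(events), fill_value=False)
        incidence = incidence.astype(bool)
        scores = incidence.sum(axis=1).astype(int)
        keep = scores > 0
        incidence, scores = incidence.loc[keep], scores.loc[keep]
        order = sorted(incidence.index, key=lambda c: (-int(scores[c]), c))
        incidence = incidence.loc[order]
        scores = scores.loc[order].rename("score")
        return cls(incidence=incidence, scores=scores)

    @property
    def chemicals(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def events(self) -> list[str]:
        return list(self.incidence.columns)

    def tier(self, score: int) -> set[str]:
        """Chemicals with exactly the given coverage score."""
        return set(self.scores.index[self.scores == score])

    def tier_sizes(self) -> dict[int, int]:
        return {int(k): int(v) for k, v in self.scores.value_counts().items()}

    def to_frame(self) -> pd.DataFrame:
        out = self.incidence.astype(int).copy()
        out.insert(0, "score", self.scores)
        out.index.name = "chemical_id"
        return out.reset_index()


def event_coverage(
    snapshot: KnowledgeSnapshot,
    mapping: EventMapping,
    aop: AOPDefinition,
    exclude_symbols: Iterable[str] = (),
) -> CoverageMatrix:
    """Intersect the snapshot's chemicals with every event of an AOP.

    A chemical is incident to an event if at least one of the event's
    mapped terms returns it; several matching terms still count once
    (duplicate listings from multiple queries are removed).  Events
    flagged unmapped contribute empty columns.
    """
    events = [e for e in aop.event_types if e in mapping.events()]
    if not events or not any(mapping.terms.get(e) for e in events):
        raise ValidationError(
            f"event mapping covers no event of {aop.aop_id} with any term"
        )
    per_event: dict[str, set[str]] = {}
    for event in events:
        hits: set[str] = set()
        for term in mapping.terms.get(event, []):
            hits |= chemicals_for_term(snapshot, term, exclude_symbols)
        per_event[event] = hits
    all_chems = sorted(set().union(*per_event.values()))
    incidence = pd.DataFrame(
        {event: [c in per_event[event] for c in all_chems] for event in events},
        index=pd.Index(all_chems, name="chemical_id"),
    )
    return CoverageMatrix.from_incidence(incidence, events)


def rank_chemicals(coverage: CoverageMatrix, min_score: int = 1) -> pd.DataFrame:
    """Chemicals at or above a coverage threshold, highest scores first.

    Ties within a score tier are broken by ascending canonical chemical
    id, making reports reproducible.  The result carries the per-event
    incidence vector of every ranked chemical.
    """
    n_events = len(coverage.events)
    if not 1 <= min_score <= n_events:
        raise ValidationError(
            f"min_score must be in 1..{n_events}, got {min_score}"
        )
    frame = coverage.to_frame()
    return frame[frame["score"] >= min_score].reset_index(drop=True)


def categorize_chemicals(
    chemical_hierarchy,
    chemicals: Iterable[str],
    category_parents: Sequence[str],
) -> dict[str, set[str]]:
    """Group chemicals by shared parentage in the chemical hierarchy.

    A chemical joins every listed category whose descendant closure
    contains it (multi-membership is expected — a phthalate can also be
    a pollutant); chemicals matched by no category land in
    ``"uncategorized"``.
    """
    chemicals = set(chemicals)
    groups: dict[str, set[str]] = {}
    assigned: set[str] = set()
    for parent in category_parents:
        members = chemical_hierarchy.descendant_closure(parent) & chemicals
        groups[parent] = members
        assigned |= members
    groups["uncategorized"] = chemicals - assigned
    return groups


# ---------------------------------------------------------------------------
# Published coverage-workbook layout (chemical rows × event columns)
# ---------------------------------------------------------------------------


def load_coverage_workbook(
    path: str | Path,
    chemical_column: str = "ChemicalID",
    event_columns: Mapping[str, str] | None = None,
) -> CoverageMatrix:
    """Read a chemical × event incidence workbook into a coverage matrix.

    The expected layout is the one used for published per-chemical event
    distributions: one row per chemical, an id column, and one column per
    event whose cells are non-empty when the chemical intersects the
    event.  ``event_columns`` maps workbook column names to event ids;
    when omitted, every column whose name parses as an event id is used.
    XLSX, CSV and TSV are accepted.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df = pd.read_excel(path, dtype=str).fillna("")
    else:
        df = pd.read_csv(
            path,
            sep="\t" if path.suffix.lower() in (".tsv", ".txt") else ",",
            dtype=str,
            keep_default_na=False,
        )
    if chemical_column not in df.columns:
        raise FormatError(f"{path}: no chemical id column {chemical_column!r}")
    if event_columns is None:
        event_columns = {}
        for col in df.columns:
            try:
                event_columns[col] = normalize_identifier(col, "event")
            except ValidationError:
                continue
    if not event_columns:
        raise FormatError(f"{path}: no event columns recognised")
    falsy = {"", "0", "no", "false"}
    rows: dict[str, dict[str, bool]] = {}
    for _, row in df.iterrows():
        chem = normalize_identifier(row[chemical_column], "chemical")
        rec = rows.setdefault(chem, {ev: False for ev in event_columns.values()})
        for col, event in event_columns.items():
            if str(row[col]).strip().lower() not in falsy:
                rec[event] = True
    incidence = pd.DataFrame.from_dict(rows, orient="index")
    incidence.index.name = "chemical_id"
    return CoverageMatrix.from_incidence(incidence, list(event_columns.values()))
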