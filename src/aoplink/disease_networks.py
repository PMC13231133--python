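"""Shared-mechanism disease discovery and cross-AOP event sharing.

Fixing each mapped gene or phenotype term of an AOP event as a tetramer
query and projecting the resulting tetramers onto their disease slot
yields, per event, the set of diseases reachable through that mechanistic
step.  Intersecting the per-event sets (exact Venn/UpSet region counts)
exposes diseases that co-use *all* events — candidate comorbidities of
the pathway's own outcome — and a leave-one-out comparison quantifies how
much a single restrictive event narrows the shared core.  Separately,
events re-used by other AOPs link the pathway into an outcome network.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .event_intersection import EventMapping, MappedTerm
from .kb_io import AOPDefinition, KnowledgeSnapshot
from .tetramer_engine import TetramerIndex, TetramerQuery, enumerate_tetramers
from .vocabularies import LookupError_, ValidationError, expand_gene_pattern

__all__ = [
    "VennResult",
    "diseases_for_event",
    "event_disease_sets",
    "venn_cells",
    "core_and_loo",
    "related_aops",
]


def diseases_for_event(
    snapshot: KnowledgeSnapshot,
    mapping: EventMapping,
    event_id: str,
    index: TetramerIndex | None = None,
    exclude_symbols: Iterable[str] = (),
) -> set[str]:
    """Distinct tetramer-derived diseases for one event.

    Each of the event's gene/pattern/phenotype terms is fixed as the
    corresponding tetramer-query slot; the union of the disease slots of
    all resulting tetramers is returned.  Wildcard gene terms union over
    their expansion.  An event mapped only to a disease term cannot be
    queried this way (the query would be circular) and raises.
    """
    terms = mapping.terms.get(event_id, [])
    queryable = [t for t in terms if t.term_kind != "disease"]
    if not queryable:
        raise ValidationError(
            f"event {event_id} has no gene or phenotype terms to query "
            "(a disease-only event would be a circular query)"
        )
    if index is None:
        index = TetramerIndex(snapshot)
    diseases: set[str] = set()
    for term in queryable:
        if term.term_kind == "gene":
            queries = [TetramerQuery(gene=term.term)]
        elif term.term_kind == "gene_pattern":
            genes = expand_gene_pattern(term.term, snapshot.gene_universe, exclude_symbols)
            queries = [TetramerQuery(gene=g) for g in sorted(genes)]
        else:  # phenotype
            queries = [TetramerQuery(phenotype=term.term)]
        for q in queries:
            for t in enumerate_tetramers(snapshot, q, index=index):
                diseases.add(t.disease_id)
    return diseases


def event_disease_sets(
    snapshot: KnowledgeSnapshot,
    mapping: EventMapping,
    event_ids: Sequence[str],
    exclude_symbols: Iterable[str] = (),
) -> dict[str, set[str]]:
    """Per-event disease sets for several events, sharing one index."""
    index = TetramerIndex(snapshot)
    return {
        e: diseases_for_event(snapshot, mapping, e, index=index,
                              exclude_symbols=exclude_symbols)
        for e in event_ids
    }


# ---------------------------------------------------------------------------
# Venn / UpSet algebra
# ---------------------------------------------------------------------------


@dataclass
class VennResult:
    """Exact multi-set region counts.

    ``region_counts`` maps every non-empty label subset to the number of
    elements belonging to exactly those sets; the regions are disjoint by
    construction and sum to the union size.  ``core`` is the element set
    common to all inputs.
    """

    labels: tuple[str, ...]
    region_counts: dict[frozenset[str], int]
    core: set[str]

    def count(self, *labels: str) -> int:
        return self.region_counts.get(frozenset(labels), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(1, len(self.labels) + 1):
            for combo in combinations(self.labels, r):
                key = frozenset(combo)
                rows.append(
                    {"region": "&".join(combo),
                     "count": self.region_counts.get(key, 0)}
                )
        return pd.DataFrame(rows)


def venn_cells(sets: Mapping[str, Iterable], k_max: int = 6) -> VennResult:
    """Exact region counts over all 2^k - 1 non-empty label subsets.

    Supports 2..6 sets — beyond that a Venn layout stops being readable
    and an UpSet-style report over the same region counts is the right
    view (the frame from :meth:`VennResult.to_frame` serves both).
    """
    labels = tuple(sets)
    k = len(labels)
    if not 2 <= k <= k_max:
        raise ValidationError(f"venn_cells supports 2..{k_max} sets, got {k}")
    materialised = {lbl: set(s) for lbl, s in sets.items()}
    union = set(chain.from_iterable(materialised.values()))
    region_counts: dict[frozenset[str], int] = {}
    for element in union:
        membership = frozenset(l for l in labels if element in materialised[l])
        region_counts[membership] = region_counts.get(membership, 0) + 1
    core = set.intersection(*materialised.values()) if materialised else set()
    return VennResult(labels=labels, region_counts=region_counts, core=core)


def core_and_loo(
    sets: Mapping[str, Iterable], drop_label: str
) -> tuple[set, set, set]:
    """Core intersection, leave-one-out expansion, and the gain.

    ``core`` is the intersection of all sets; ``expanded`` drops
    ``drop_label`` before intersecting; ``additional`` is the expansion
    gained by the drop (``expanded - core``), always disjoint from the
    core and satisfying |additional| = |expanded| - |core|.
    """
    if len(sets) < 3:
        raise ValidationError("leave-one-out needs at least three sets")
    if drop_label not in sets:
        raise LookupError_(f"unknown label {drop_label!r}")
    materialised = {lbl: set(s) for lbl, s in sets.items()}
    core = set.intersection(*materialised.values())
    expanded = set.intersection(
        *(s for lbl, s in materialised.items() if lbl != drop_label)
    )
    return core, expanded, expanded - core


# ---------------------------------------------------------------------------
# Cross-AOP event sharing
# ---------------------------------------------------------------------------


def related_aops(
    aop_definitions: Mapping[str, AOPDefinition],
    event_ids: Iterable[str],
) -> pd.DataFrame:
    """Which other AOPs re-use the queried events, and to what outcomes.

    One row per (event, containing AOP) with that AOP's AO-typed events
    pipe-joined; events contained in no AOP simply yield no rows.
    Querying an event of a given AOP always reports that AOP too —
    reflexivity is informative when scanning for *exclusive* use.
    """
    rows = []
    for event in event_ids:
        for aop_id in sorted(aop_definitions):
            aop = aop_definitions[aop_id]
            if event in aop.event_types:
                rows.append(
                    {
                        "event_id": event,
                        "aop_id": aop_id,
                        "adverse_outcomes": "|".join(sorted(aop.events_of_type("AO"))),
                    }
                )
    return pd.DataFrame(rows, columns=["event_id", "aop_id", "adverse_outcomes"])
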