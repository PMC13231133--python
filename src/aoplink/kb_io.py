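"""Reading, validating and serialising the knowledge snapshot.

A snapshot is the local, file-backed stand-in for a CTD-style curated
database release: five relation tables (chemical-gene, chemical-phenotype,
chemical-disease, gene-phenotype, gene-disease), three vocabulary
hierarchies (GO phenotypes in OBO; MEDIC diseases and the chemical tree as
tree-numbered TSVs), and a gene universe mapping gene ids to symbols.
All downstream queries (event intersection, tetramer enumeration, disease
networks) run against this object; nothing in the package talks to a web
service.
"""

from __future__ import annotations

import gzip
import hashlib
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

from .vocabularies import (
    LookupError_,
    OntologyHierarchy,
    ValidationError,
    normalize_identifier,
)

__all__ = [
    "FormatError",
    "RELATION_KINDS",
    "RELATION_NAMESPACES",
    "EVIDENCE_CLASSES",
    "AOPDefinition",
    "KnowledgeSnapshot",
    "load_relation_table",
    "parse_obo",
    "parse_tree_vocab",
    "load_aop_definitions",
    "load_tetramer_export",
    "assemble_snapshot",
    "write_snapshot",
    "read_snapshot",
]


class FormatError(ValueError):
    """Raised when a file does not match its declared dialect."""


#: The five curated relation kinds and their (subject, object) namespaces.
RELATION_NAMESPACES: dict[str, tuple[str, str]] = {
    "chem_gene": ("chemical", "gene"),
    "chem_phenotype": ("chemical", "phenotype"),
    "chem_disease": ("chemical", "disease"),
    "gene_phenotype": ("gene", "phenotype"),
    "gene_disease": ("gene", "disease"),
}
RELATION_KINDS = tuple(RELATION_NAMESPACES)

#: CTD direct-evidence classes on chemical-disease and gene-disease rows.
EVIDENCE_CLASSES = ("marker_mechanism", "therapeutic")

_EVIDENCE_ALIASES = {
    "marker/mechanism": "marker_mechanism",
    "marker_mechanism": "marker_mechanism",
    "therapeutic": "therapeutic",
}

#: Canonical relation-table columns, in serialisation order.
RELATION_COLUMNS = [
    "subject_id",
    "object_id",
    "direct_evidence",
    "organism_id",
    "support_articles",
]


# ---------------------------------------------------------------------------
# Low-level text helpers
# ---------------------------------------------------------------------------


def _open_text(path: str | Path) -> io.TextIOWrapper:
    """Open a possibly gzip-compressed text file, sniffing magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _read_commented_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a TSV/CSV whose leading '#' lines are commentary.

    CTD bulk files carry their header inside the final comment line
    ("# Fields: ..."); plain exports carry a normal header row.  Both are
    accepted: if the first non-comment line looks like data relative to a
    '# Fields:'-style comment, the commented names win.
    """
    with _open_text(path) as fh:
        raw = fh.read()
    lines = raw.splitlines()
    comments = []
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            comments.append(line)
            body_start = i + 1
        else:
            break
    body = "\n".join(lines[body_start:])
    if not body.strip():
        if comments:
            header = _header_from_comments(comments, sep)
            if header:
                return pd.DataFrame(columns=header)
        return pd.DataFrame()
    if sep is None:
        first = lines[body_start]
        sep = "\t" if "\t" in first else ","
    header_names = _header_from_comments(comments, sep)
    if header_names:
        df = pd.read_csv(
            io.StringIO(body), sep=sep, header=None, names=header_names,
            dtype=str, keep_default_na=False,
        )
    else:
        df = pd.read_csv(io.StringIO(body), sep=sep, dtype=str, keep_default_na=False)
    return df


def _header_from_comments(comments: list[str], sep: str | None) -> list[str] | None:
    for line in reversed(comments):
        text = line.lstrip("#").strip()
        if text.lower().startswith("fields:"):
            text = text[len("fields:"):].strip()
        else:
            continue
        use_sep = sep if sep is not None else ("\t" if "\t" in text else ",")
        return [c.strip() for c in text.split(use_sep)]
    return None


def _split_articles(cell: str) -> frozenset[str]:
    if not cell or not str(cell).strip():
        return frozenset()
    return frozenset(p.strip() for p in re.split(r"[|;]", str(cell)) if p.strip())


# ---------------------------------------------------------------------------
# Relation tables
# ---------------------------------------------------------------------------


def load_relation_table(
    path: str | Path,
    relation_kind: str,
    column_map: Mapping[str, str] | None = None,
    organism_allow: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Load one curated relation table into canonical form.

    Parameters
    ----------
    path
        TSV or CSV file, optionally gzip-compressed, with '#' comment
        headers.
    relation_kind
        One of :data:`RELATION_KINDS`; fixes the subject/object namespaces.
    column_map
        Mapping from dialect column names to canonical fields
        (``subject_id``, ``object_id``, and optionally ``direct_evidence``,
        ``organism_id``, ``support_articles``).  When omitted, the file is
        assumed to already use canonical names.

    Returns a DataFrame with :data:`RELATION_COLUMNS`; ``support_articles``
    holds frozensets.  Rows missing subject or object are dropped; rows
    identical up to their article sets are merged with the sets unioned
    (rows differing in ``direct_evidence`` stay separate, because the
    evidence class changes query semantics downstream).
    """
    if relation_kind not in RELATION_NAMESPACES:
        raise ValidationError(f"unknown relation kind {relation_kind!r}")
    df = _read_commented_table(path)
    column_map = dict(column_map or {})
    if not column_map:
        column_map = {c: c for c in RELATION_COLUMNS if c in df.columns}
    for dialect_col in column_map:
        if dialect_col not in df.columns:
            raise FormatError(
                f"{path}: mapped column {dialect_col!r} absent "
                f"(found columns {list(df.columns)})"
            )
    df = df.rename(columns=column_map)
    for required in ("subject_id", "object_id"):
        if required not in df.columns:
            raise FormatError(f"{path}: no column mapped to {required!r}")
    out = normalize_relation_frame(df, relation_kind, source=str(path))
    if organism_allow is not None:
        # cross-species content is kept by default; an explicit allow-list
        # restricts to the named organisms (rows without one are dropped)
        allowed = set(organism_allow)
        out = out[out["organism_id"].isin(allowed)].reset_index(drop=True)
    return out


def normalize_relation_frame(
    df: pd.DataFrame, relation_kind: str, source: str = "<memory>"
) -> pd.DataFrame:
    """Normalise identifiers, evidence classes and article sets; deduplicate."""
    subj_ns, obj_ns = RELATION_NAMESPACES[relation_kind]
    records: list[dict] = []
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        subj = str(row.get("subject_id", "") or "").strip()
        obj = str(row.get("object_id", "") or "").strip()
        if not subj or not obj:
            continue  # rejected: incomplete statement
        try:
            subj = normalize_identifier(subj, subj_ns)
            obj = normalize_identifier(obj, obj_ns)
        except ValidationError as exc:
            raise ValidationError(f"{source}, row {pos}: {exc}") from exc
        evidence = str(row.get("direct_evidence", "") or "").strip().lower()
        if evidence:
            if evidence not in _EVIDENCE_ALIASES:
                raise ValidationError(
                    f"{source}, row {pos}: unknown direct-evidence class "
                    f"{evidence!r}"
                )
            evidence = _EVIDENCE_ALIASES[evidence]
        else:
            evidence = None
        organism = str(row.get("organism_id", "") or "").strip() or None
        articles = _split_articles(row.get("support_articles", ""))
        records.append(
            {
                "subject_id": subj,
                "object_id": obj,
                "direct_evidence": evidence,
                "organism_id": organism,
                "support_articles": articles,
            }
        )
    return _dedup_relations(pd.DataFrame(records, columns=RELATION_COLUMNS))


def _dedup_relations(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        return df.reindex(columns=RELATION_COLUMNS)
    grouped = (
        df.groupby(["subject_id", "object_id", "direct_evidence"], dropna=False)
        .agg(
            organism_id=("organism_id", lambda s: next((x for x in s if x), None)),
            support_articles=(
                "support_articles",
                lambda s: frozenset().union(*s),
            ),
        )
        .reset_index()
    )
    grouped["direct_evidence"] = grouped["direct_evidence"].where(
        pd.notna(grouped["direct_evidence"]), None
    )
    grouped = grouped.sort_values(
        ["subject_id", "object_id", "direct_evidence"],
        na_position="first",
        kind="mergesort",
    ).reset_index(drop=True)
    return grouped.reindex(columns=RELATION_COLUMNS)


# ---------------------------------------------------------------------------
# Vocabulary files
# ---------------------------------------------------------------------------


def parse_obo(path: str | Path, include_part_of: bool = False) -> OntologyHierarchy:
    """Parse an OBO 1.2/1.4 ontology into a phenotype hierarchy.

    Obsolete terms are excluded.  ``is_a`` edges always contribute
    parentage; ``part_of`` relationships only when ``include_part_of`` is
    set.  Acyclicity is verified; a dangling parent reference raises a
    :class:`~aoplink.vocabularies.ValidationError`.
    """
    graph = obonet.read_obo(str(path), ignore_obsolete=True)
    hierarchy = OntologyHierarchy(namespace="phenotype")
    declared = {n for n, data in graph.nodes(data=True) if data.get("name") is not None}
    for node in sorted(declared):
        hierarchy.add_term(node, graph.nodes[node].get("name", ""))
    wanted = {"is_a"} | ({"part_of"} if include_part_of else set())
    for child, parent, key in graph.edges(keys=True):
        if key not in wanted:
            continue
        if parent not in declared:
            raise ValidationError(
                f"{path}: term {child!r} references undeclared parent {parent!r}"
            )
        hierarchy.add_parent_link(child, parent, label=key)
    hierarchy.validate()
    return hierarchy


_ID_COL = re.compile(r"^(disease|chemical)?id$", re.I)
_NAME_COL = re.compile(r"name$", re.I)


def parse_tree_vocab(path: str | Path, namespace: str) -> OntologyHierarchy:
    """Parse a MEDIC-style tree-numbered vocabulary TSV.

    Parentage is the union of the explicit ``ParentIDs`` column and
    tree-number prefix relations (the owner of ``C01.123`` is a parent of
    the owner of ``C01.123.456``).  Multi-parent terms are the norm in
    poly-hierarchies and are preserved.  Tree-number prefixes whose owner
    is absent from the file are ignored (subset files legitimately omit
    upper levels); an explicit parent id referencing an absent term is a
    validation error.
    """
    if namespace not in ("disease", "chemical"):
        raise ValidationError(f"tree vocabularies carry disease or chemical ids, not {namespace!r}")
    df = _read_commented_table(path, sep="\t")
    hierarchy = OntologyHierarchy(namespace=namespace)
    if df.empty and not len(df.columns):
        return hierarchy
    id_col = next((c for c in df.columns if _ID_COL.match(c.strip())), None)
    name_col = next((c for c in df.columns if _NAME_COL.search(c.strip())), None)
    parent_col = next((c for c in df.columns if c.strip().lower() == "parentids"), None)
    tree_col = next((c for c in df.columns if c.strip().lower() == "treenumbers"), None)
    if id_col is None:
        raise FormatError(f"{path}: no identifier column found in {list(df.columns)}")

    rows = []
    tree_owner: dict[str, str] = {}
    for _, row in df.iterrows():
        term_id = normalize_identifier(row[id_col], namespace)
        name = str(row[name_col]).strip() if name_col else ""
        parents = (
            [p for p in re.split(r"[|;]", str(row[parent_col])) if p.strip()]
            if parent_col
            else []
        )
        trees = (
            [t.strip() for t in re.split(r"[|;]", str(row[tree_col])) if t.strip()]
            if tree_col
            else []
        )
        rows.append((term_id, name, parents, trees))
        for t in trees:
            tree_owner[t] = term_id
        hierarchy.add_term(term_id, name)
    for term_id, _, parents, trees in rows:
        parent_ids = set()
        for p in parents:
            pid = normalize_identifier(p, namespace)
            if pid not in hierarchy:
                raise ValidationError(
                    f"{path}: term {term_id} names absent parent {pid}"
                )
            parent_ids.add(pid)
        for t in trees:
            prefix = t.rsplit(".", 1)[0] if "." in t else None
            if prefix and prefix in tree_owner:
                parent_ids.add(tree_owner[prefix])
        for pid in sorted(parent_ids - {term_id}):
            hierarchy.add_parent_link(term_id, pid, label="tree")
    hierarchy.validate()
    return hierarchy


# ---------------------------------------------------------------------------
# AOP definitions
# ---------------------------------------------------------------------------


@dataclass
class AOPDefinition:
    """One adverse outcome pathway: typed events joined by KER edges.

    ``event_types`` types each event *within this AOP* (the same event id
    may be an MIE in one pathway and a KE in another); ``kers`` are
    directed (upstream, downstream) pairs.  ``components`` carries the
    AOP-Wiki event-component ontology terms, possibly empty for events
    the wiki has not mapped.
    """

    aop_id: str
    event_types: dict[str, str]  # event_id -> MIE | KE | AO
    event_titles: dict[str, str]
    kers: set[tuple[str, str]]
    components: dict[str, list[str]] = field(default_factory=dict)

    @property
    def events(self) -> set[str]:
        return set(self.event_types)

    def events_of_type(self, event_type: str) -> set[str]:
        return {e for e, t in self.event_types.items() if t == event_type}


def load_aop_definitions(
    aop_path: str | Path, event_component_path: str | Path | None = None
) -> dict[str, AOPDefinition]:
    """Load AOP event/KER tables plus the optional event-component mapping.

    The AOP table is a TSV with columns ``aop_id``, ``event_id``,
    ``event_type`` (MIE/KE/AO), ``event_title`` and ``downstream_events``
    (pipe-separated event ids within the same AOP, encoding the KERs).
    The component file (aop_ke_ec.tsv dialect) pairs event ids with
    ontology term ids; events it does not mention keep an empty component
    list.
    """
    df = _read_commented_table(aop_path, sep="\t")
    required = {"aop_id", "event_id", "event_type"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{aop_path}: missing columns {sorted(missing)}")
    aops: dict[str, AOPDefinition] = {}
    pending_edges: dict[str, list[tuple[str, str]]] = {}
    for pos, row in df.iterrows():
        aop_id = normalize_identifier(row["aop_id"], "aop")
        event_id = normalize_identifier(row["event_id"], "event")
        event_type = str(row["event_type"]).strip().upper()
        if event_type not in ("MIE", "KE", "AO"):
            raise ValidationError(
                f"{aop_path}, row {pos + 1}: bad event type {event_type!r}"
            )
        aop = aops.setdefault(
            aop_id,
            AOPDefinition(aop_id, {}, {}, set(), {}),
        )
        prior = aop.event_types.get(event_id)
        if prior is not None and {prior, event_type} == {"MIE", "AO"}:
            raise ValidationError(
                f"{aop_path}: event {event_id} typed both MIE and AO in {aop_id}"
            )
        aop.event_types[event_id] = event_type
        title = str(row.get("event_title", "") or "").strip()
        if title:
            aop.event_titles[event_id] = title
        downstream = str(row.get("downstream_events", "") or "").strip()
        for target in (t for t in re.split(r"[|;]", downstream) if t.strip()):
            pending_edges.setdefault(aop_id, []).append(
                (event_id, normalize_identifier(target, "event"))
            )
    for aop_id, edges in pending_edges.items():
        aop = aops[aop_id]
        for src, dst in edges:
            if dst not in aop.event_types:
                raise ValidationError(
                    f"{aop_path}: KER {src} -> {dst} names undeclared event "
                    f"{dst} in {aop_id}"
                )
            aop.kers.add((src, dst))
    if event_component_path is not None:
        comp = _read_commented_table(event_component_path, sep="\t")
        if len(comp.columns) >= 2:
            ev_col = "event_id" if "event_id" in comp.columns else comp.columns[0]
            term_col = "term_id" if "term_id" in comp.columns else comp.columns[1]
            by_event: dict[str, list[str]] = {}
            for _, row in comp.iterrows():
                ev = normalize_identifier(row[ev_col], "event")
                term = str(row[term_col]).strip()
                if term:
                    by_event.setdefault(ev, []).append(term)
            for aop in aops.values():
                for ev in aop.event_types:
                    aop.components[ev] = by_event.get(ev, [])
    else:
        for aop in aops.values():
            for ev in aop.event_types:
                aop.components.setdefault(ev, [])
    return aops


# ---------------------------------------------------------------------------
# Tetramer exports
# ---------------------------------------------------------------------------

_TETRAMER_SLOTS = ("chemical_id", "gene", "phenotype_id", "disease_id")


def load_tetramer_export(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Load a tetramer-tool export (CSV/TSV/XLSX), one row per tetramer.

    ``column_map`` maps dialect column names to the canonical slots
    ``chemical_id``, ``gene`` (id or symbol), ``phenotype_id``,
    ``disease_id``; the reserved key ``__sheet__`` selects an XLSX sheet
    (first sheet by default).  Row count is preserved — exports are
    already one-row-per-tetramer and deduplication is a query-stage
    concern, not a load-stage one.
    """
    path = Path(path)
    column_map = dict(column_map or {})
    sheet = column_map.pop("__sheet__", 0)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df = pd.read_excel(path, sheet_name=sheet, dtype=str).fillna("")
    else:
        df = _read_commented_table(path)
    if not column_map:
        column_map = {c: c for c in _TETRAMER_SLOTS if c in df.columns}
    for dialect_col in column_map:
        if dialect_col not in df.columns:
            raise FormatError(f"{path}: mapped column {dialect_col!r} absent")
    df = df.rename(columns=column_map)
    missing = [c for c in _TETRAMER_SLOTS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing tetramer identifier columns {missing}")
    out = df.copy()
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        for slot in _TETRAMER_SLOTS:
            if not str(row[slot]).strip():
                raise FormatError(f"{path}, row {pos}: empty {slot} column")
    out["chemical_id"] = [
        normalize_identifier(v, "chemical") for v in out["chemical_id"]
    ]
    out["phenotype_id"] = [
        normalize_identifier(v, "phenotype") for v in out["phenotype_id"]
    ]
    out["disease_id"] = [normalize_identifier(v, "disease") for v in out["disease_id"]]
    out["gene"] = [
        normalize_identifier(v, "gene")
        if re.fullmatch(r"(GENE:)?\d+", str(v).strip(), re.I)
        else str(v).strip().upper()
        for v in out["gene"]
    ]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Snapshot assembly and canonical serialisation
# ---------------------------------------------------------------------------


@dataclass
class KnowledgeSnapshot:
    """Five relation tables + three hierarchies + the gene universe."""

    relations: dict[str, pd.DataFrame]
    phenotype_hierarchy: OntologyHierarchy
    disease_hierarchy: OntologyHierarchy
    chemical_hierarchy: OntologyHierarchy
    gene_universe: dict[str, str]  # gene id -> symbol
    snapshot_label: str = ""

    def hierarchy_for(self, namespace: str) -> OntologyHierarchy:
        return {
            "phenotype": self.phenotype_hierarchy,
            "disease": self.disease_hierarchy,
            "chemical": self.chemical_hierarchy,
        }[namespace]

    def validate(self) -> pd.DataFrame:
        """Referential-integrity report: one row per failing identifier.

        Genes must be members of the gene universe; phenotype, disease and
        chemical ids must be members of their hierarchy.  An empty frame
        means the snapshot is internally consistent.
        """
        problems: list[dict] = []
        seen: set[tuple[str, str]] = set()
        for kind, df in self.relations.items():
            subj_ns, obj_ns = RELATION_NAMESPACES[kind]
            for col, ns in (("subject_id", subj_ns), ("object_id", obj_ns)):
                for ident in df[col].unique() if not df.empty else []:
                    if (ident, ns) in seen:
                        continue
                    seen.add((ident, ns))
                    if ns == "gene":
                        if ident not in self.gene_universe:
                            problems.append(
                                {"id": ident, "namespace": ns,
                                 "problem": "gene id absent from gene universe"}
                            )
                    elif ident not in self.hierarchy_for(ns):
                        problems.append(
                            {"id": ident, "namespace": ns,
                             "problem": f"id absent from {ns} hierarchy"}
                        )
        return pd.DataFrame(problems, columns=["id", "namespace", "problem"])


def assemble_snapshot(
    relations: Mapping[str, pd.DataFrame],
    phenotype_hierarchy: OntologyHierarchy,
    disease_hierarchy: OntologyHierarchy,
    chemical_hierarchy: OntologyHierarchy,
    gene_universe: Mapping[str, str],
    snapshot_label: str = "",
    strict: bool = True,
) -> KnowledgeSnapshot:
    """Build a referentially consistent snapshot from loaded parts.

    With ``strict`` set (the default) any referential-integrity failure
    raises; otherwise the failures are left to :meth:`KnowledgeSnapshot.validate`
    so callers can report on deliberately partial snapshots.
    """
    tables = {}
    for kind in RELATION_KINDS:
        df = relations.get(kind)
        if df is None:
            df = pd.DataFrame(columns=RELATION_COLUMNS)
        tables[kind] = _dedup_relations(df)
    snapshot = KnowledgeSnapshot(
        relations=tables,
        phenotype_hierarchy=phenotype_hierarchy,
        disease_hierarchy=disease_hierarchy,
        chemical_hierarchy=chemical_hierarchy,
        gene_universe=dict(gene_universe),
        snapshot_label=snapshot_label,
    )
    if strict:
        report = snapshot.validate()
        if not report.empty:
            sample = ", ".join(report["id"].head(5))
            raise ValidationError(
                f"snapshot fails referential integrity for {len(report)} ids "
                f"(e.g. {sample})"
            )
    return snapshot


def _articles_to_cell(articles: frozenset[str]) -> str:
    return "|".join(sorted(articles))


def write_snapshot(snapshot: KnowledgeSnapshot, out_dir: str | Path) -> Path:
    """Serialise a snapshot to its canonical on-disk form.

    One TSV per relation kind (sorted rows, article sets pipe-joined in
    sorted order), the gene universe and each hierarchy as sorted TSVs,
    and a manifest recording the label and per-file SHA-256 digests.
    Output is deterministic: the same snapshot always produces
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for kind in RELATION_KINDS:
        df = snapshot.relations[kind].copy()
        df["support_articles"] = df["support_articles"].map(_articles_to_cell)
        df = df.fillna("")
        name = f"{kind}.tsv"
        df.to_csv(out_dir / name, sep="\t", index=False)
        files[name] = _sha256(out_dir / name)
    genes = pd.DataFrame(
        sorted(snapshot.gene_universe.items()), columns=["gene_id", "gene_symbol"]
    )
    genes.to_csv(out_dir / "gene_universe.tsv", sep="\t", index=False)
    files["gene_universe.tsv"] = _sha256(out_dir / "gene_universe.tsv")
    for ns in ("phenotype", "disease", "chemical"):
        h = snapshot.hierarchy_for(ns)
        nodes = pd.DataFrame(
            sorted((t, h.name(t)) for t in h.terms), columns=["term_id", "name"]
        )
        links = pd.DataFrame(
            sorted(h.parent_links()), columns=["child_id", "parent_id", "label"]
        )
        nodes.to_csv(out_dir / f"{ns}_terms.tsv", sep="\t", index=False)
        links.to_csv(out_dir / f"{ns}_parents.tsv", sep="\t", index=False)
        files[f"{ns}_terms.tsv"] = _sha256(out_dir / f"{ns}_terms.tsv")
        files[f"{ns}_parents.tsv"] = _sha256(out_dir / f"{ns}_parents.tsv")
    manifest = {
        "snapshot_label": snapshot.snapshot_label,
        "files": files,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return out_dir


def read_snapshot(in_dir: str | Path, strict: bool = True) -> KnowledgeSnapshot:
    """Load a snapshot previously written by :func:`write_snapshot`."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    relations = {}
    for kind in RELATION_KINDS:
        df = pd.read_csv(
            in_dir / f"{kind}.tsv", sep="\t", dtype=str, keep_default_na=False
        )
        df["support_articles"] = df["support_articles"].map(_split_articles)
        df["direct_evidence"] = df["direct_evidence"].map(lambda v: v or None)
        df["organism_id"] = df["organism_id"].map(lambda v: v or None)
        relations[kind] = df
    hierarchies = {}
    for ns in ("phenotype", "disease", "chemical"):
        h = OntologyHierarchy(namespace=ns)
        nodes = pd.read_csv(
            in_dir / f"{ns}_terms.tsv", sep="\t", dtype=str, keep_default_na=False
        )
        for _, row in nodes.iterrows():
            h.add_term(row["term_id"], row["name"])
        links = pd.read_csv(
            in_dir / f"{ns}_parents.tsv", sep="\t", dtype=str, keep_default_na=False
        )
        for _, row in links.iterrows():
            h.add_parent_link(row["child_id"], row["parent_id"], row["label"])
        h.validate()
        hierarchies[ns] = h
    genes = pd.read_csv(
        in_dir / "gene_universe.tsv", sep="\t", dtype=str, keep_default_na=False
    )
    gene_universe = dict(zip(genes["gene_id"], genes["gene_symbol"]))
    return assemble_snapshot(
        relations,
        hierarchies["phenotype"],
        hierarchies["disease"],
        hierarchies["chemical"],
        gene_universe,
        snapshot_label=manifest.get("snapshot_label", ""),
        strict=strict,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
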