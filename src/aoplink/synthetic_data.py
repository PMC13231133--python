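"""Seeded synthetic knowledge snapshots with planted, checkable structure.

The generator emulates a curated toxicogenomic release at the scale and
shape of the study conditions: a six-event autism AOP (one MIE, four KEs,
one AO, bifurcated at the NMDAR event), the published event-term mapping,
a GO-like phenotype DAG, a MEDIC-like disease poly-hierarchy containing
the Autism Spectrum Disorder branch, and a chemical tree with category
parents.  Into this background it plants machine-checkable structure:

* **coverage tiers** — for each score k, a block of chemicals wired to
  exactly k distinct AOP events through mapped terms (hierarchical terms
  are hit through random members of their descendant closure, so
  subsumption is always exercised);
* **tetramers** — complete five-edge chemical/gene/phenotype/disease
  blocks for three designated query chemicals, including a block of
  gene-phenotype dimers shared by *all* query chemicals;
* **near-miss decoys** — tuples carrying exactly four of the five edges.
  Every decoy gets a fresh chemical and a fresh gene, and all five
  tetramer edges involve the chemical or the gene, so no other planted or
  background edge can ever complete a decoy.

Background relations are drawn only among background-pool entities, and
background phenotypes/diseases live outside the mapped-term closures, so
planted recoveries are never diluted — background can add solutions of
its own but cannot subtract from or contaminate the manifest.

Everything is driven by one integer seed through a single explicit
pseudo-random stream; the same config and seed reproduce byte-identical
emitted files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .event_intersection import EventMapping, bundled_event_mapping
from .kb_io import (
    AOPDefinition,
    KnowledgeSnapshot,
    RELATION_COLUMNS,
    RELATION_KINDS,
    assemble_snapshot,
)
from .vocabularies import OntologyHierarchy, ValidationError

__all__ = [
    "SyntheticConfig",
    "GroundTruthManifest",
    "generate_snapshot",
    "synthetic_aop_definitions",
    "write_synthetic_inputs",
    "AOP_ID",
    "EVENT_ORDER",
]

AOP_ID = "AOP:522"
#: The six events in pathway order; KERs are defined in
#: :func:`synthetic_aop_definitions`.
EVENT_ORDER = ("MIE:112", "KE:2207", "KE:195", "KE:2208", "KE:386", "AO:2209")
_ASD = "MESH:D000067877"
_ASD_CHILDREN = ("MESH:D001321", "MESH:D020817", "MESH:C538235")

#: Query chemicals emulating the three autism-associated stressors
#: (bisphenol A, particulate matter, valproic acid).
QUERY_CHEMICALS = ("MESH:C006780", "MESH:D052638", "MESH:D014635")

_CORE_GENES = {
    "GENE:2099": "ESR1",
    "GENE:2100": "ESR2",
    "GENE:5594": "MAPK1",
    "GENE:5595": "MAPK3",
    "GENE:2902": "GRIN1",
    "GENE:2903": "GRIN2A",
    "GENE:2904": "GRIN2B",
    "GENE:2905": "GRIN2C",
    "GENE:2906": "GRIN2D",
    "GENE:116443": "GRIN3A",
    "GENE:116444": "GRIN3B",
    "GENE:2907": "GRINA",
}

_CATEGORY_PARENTS = {
    "MESH:D008670": "Metals",
    "MESH:D010860": "Phthalic Acids",
    "MESH:D004787": "Environmental Pollutants",
    "MESH:D010575": "Pesticides",
}


@dataclass
class SyntheticConfig:
    """Generator knobs; the defaults are the study conditions.

    The default coverage tiers reproduce the magnitudes of the published
    prioritisation (12 chemicals on all six events, 64 more on five, a
    long low-score tail summing to 3,648 distinct chemicals); three query
    chemicals carry planted tetramers with a block of dimers shared by
    all three; decoy tuples miss exactly one named edge each, cycling
    through the five edge kinds.
    """

    coverage_tiers: dict[int, int] = field(
        default_factory=lambda: {6: 12, 5: 64, 4: 120, 3: 300, 2: 800, 1: 2352}
    )
    n_planted_tetramers: int = 30  # exclusive tetramers, split across query chems
    n_shared_dimers: int = 10      # dimers planted for every query chemical
    n_decoys: int = 50
    # per-event mechanism tetramers feeding the disease-network stage:
    # a disease core shared by all five mechanistic events, an additional
    # block shared by all but the NMDAR event, and a few private each
    n_core_diseases: int = 17
    n_loo_additional_diseases: int = 108
    n_private_diseases: int = 5
    n_background_chemicals: int = 120
    n_background_genes: int = 150
    n_background_phenotypes: int = 120
    n_background_diseases: int = 200
    background_density: float = 0.01   # per relation kind, over background pools
    extra_parent_prob: float = 0.15    # DAG-ification of synthetic hierarchies
    article_geom_p: float = 0.5        # per-edge article count ~ geometric(p), >= 1
    n_chemicals: int | None = None     # optional cap for feasibility checking
    seed: int = 0

    def validate(self) -> None:
        n_events = len(EVENT_ORDER)
        for score, count in self.coverage_tiers.items():
            if not 1 <= score <= n_events:
                raise ValidationError(
                    f"tier score {score} outside 1..{n_events}"
                )
            if count < 0:
                raise ValidationError(f"negative tier count for score {score}")
        if not 0.0 <= self.background_density <= 1.0:
            raise ValidationError("background_density must be in [0, 1]")
        if not 0.0 <= self.extra_parent_prob <= 1.0:
            raise ValidationError("extra_parent_prob must be in [0, 1]")
        if not 0.0 < self.article_geom_p <= 1.0:
            raise ValidationError("article_geom_p must be in (0, 1]")
        if min(
            self.n_planted_tetramers, self.n_shared_dimers, self.n_decoys,
            self.n_core_diseases, self.n_loo_additional_diseases,
            self.n_private_diseases,
            self.n_background_chemicals, self.n_background_genes,
            self.n_background_phenotypes, self.n_background_diseases,
        ) < 0:
            raise ValidationError("entity counts must be non-negative")
        n_pairs = self.n_shared_dimers + self.n_planted_tetramers
        if n_pairs > 0 and (
            self.n_background_genes < n_pairs
            or self.n_background_phenotypes < n_pairs
        ):
            raise ValidationError(
                "background gene/phenotype pools must be at least "
                f"{n_pairs} to host the planted tetramer pairs"
            )
        if self.n_chemicals is not None:
            needed = (
                sum(self.coverage_tiers.values())
                + len(QUERY_CHEMICALS)
                + self.n_decoys
                + self.n_background_chemicals
            )
            if needed > self.n_chemicals:
                raise ValidationError(
                    f"config is infeasible: {needed} chemicals required "
                    f"but n_chemicals caps at {self.n_chemicals}"
                )


@dataclass
class GroundTruthManifest:
    """What was planted, for exact recovery checks.

    ``incidence`` records, for every planted chemical (tier, query or
    decoy), the exact set of AOP events it touches through the edges the
    generator wrote — the oracle for coverage recovery at zero background
    density (background never touches mapped terms, so it holds at any
    density too).
    """

    tiers: dict[int, list[str]]
    incidence: dict[str, list[str]]
    planted_tetramers: list[tuple[str, str, str, str]]
    shared_dimers: list[tuple[str, str]]
    query_chemicals: list[str]
    decoys: list[dict]  # {"tuple": [...4 ids...], "omitted_edge": name}
    event_diseases: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "tiers": {str(k): sorted(v) for k, v in sorted(self.tiers.items())},
            "incidence": {c: sorted(e) for c, e in sorted(self.incidence.items())},
            "planted_tetramers": sorted(list(t) for t in self.planted_tetramers),
            "shared_dimers": sorted(list(d) for d in self.shared_dimers),
            "query_chemicals": list(self.query_chemicals),
            "decoys": sorted(
                self.decoys, key=lambda d: (d["tuple"], d["omitted_edge"])
            ),
            "event_diseases": {
                e: sorted(d) for e, d in sorted(self.event_diseases.items())
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        data = json.loads(text)
        return cls(
            tiers={int(k): v for k, v in data["tiers"].items()},
            incidence=data["incidence"],
            planted_tetramers=[tuple(t) for t in data["planted_tetramers"]],
            shared_dimers=[tuple(d) for d in data["shared_dimers"]],
            query_chemicals=data["query_chemicals"],
            decoys=data["decoys"],
            event_diseases=data.get("event_diseases", {}),
        )


# ---------------------------------------------------------------------------
# AOP fixtures
# ---------------------------------------------------------------------------


def synthetic_aop_definitions() -> dict[str, AOPDefinition]:
    """The autism AOP plus the event-sharing neighbour AOPs.

    AOP:522's five KERs form a chain bifurcated at KE:195, which joins at
    the synapse event.  The neighbours re-use single events with other
    adverse outcomes (estrogen-receptor antagonism towards metastatic
    breast cancer and decreased sperm quantity; the synaptic and
    neuronal-network events towards learning/memory impairment and
    memory loss), so cross-AOP sharing queries have non-trivial answers.
    """
    aops = {
        AOP_ID: AOPDefinition(
            aop_id=AOP_ID,
            event_types={
                "MIE:112": "MIE", "KE:2207": "KE", "KE:195": "KE",
                "KE:2208": "KE", "KE:386": "KE", "AO:2209": "AO",
            },
            event_titles={
                "MIE:112": "antagonism, estrogen receptor",
                "KE:2207": "inhibition, ERK1/2 signaling pathway",
                "KE:195": "inhibition, NMDARs",
                "KE:2208": "aberrant, synaptic formation and plasticity",
                "KE:386": "decrease of neuronal network function",
                "AO:2209": "autism-like behavior",
            },
            kers={
                ("MIE:112", "KE:2207"),
                ("KE:2207", "KE:2208"),
                ("KE:195", "KE:2208"),
                ("KE:2208", "KE:386"),
                ("KE:386", "AO:2209"),
            },
        ),
        "AOP:443": AOPDefinition(
            aop_id="AOP:443",
            event_types={"MIE:112": "MIE", "AO:1982": "AO"},
            event_titles={"AO:1982": "metastatic breast cancer"},
            kers={("MIE:112", "AO:1982")},
        ),
        "AOP:595": AOPDefinition(
            aop_id="AOP:595",
            event_types={"MIE:112": "MIE", "AO:520": "AO"},
            event_titles={"AO:520": "decreased sperm quantity"},
            kers={("MIE:112", "AO:520")},
        ),
        "AOP:429": AOPDefinition(
            aop_id="AOP:429",
            event_types={"KE:386": "KE", "AO:1941": "AO"},
            event_titles={"AO:1941": "memory loss"},
            kers={("KE:386", "AO:1941")},
        ),
        "AOP:12": AOPDefinition(
            aop_id="AOP:12",
            event_types={"KE:2208": "KE", "KE:386": "KE", "AO:341": "AO"},
            event_titles={"AO:341": "impairment, learning or memory"},
            kers={("KE:2208", "KE:386"), ("KE:386", "AO:341")},
        ),
    }
    for aop in aops.values():
        for ev in aop.event_types:
            aop.components.setdefault(ev, [])
    return aops


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


class _EdgeStore:
    """Accumulates relation rows keyed by (kind, subject, object, evidence)."""

    def __init__(self, rng: np.random.Generator, geom_p: float):
        self.rng = rng
        self.geom_p = geom_p
        self.rows: dict[tuple[str, str, str, str | None], set[str]] = {}
        self._article_serial = 0

    def _articles(self) -> set[str]:
        n = int(self.rng.geometric(self.geom_p))
        out = set()
        for _ in range(n):
            self._article_serial += 1
            out.add(f"PMID:{1000000 + self._article_serial}")
        return out

    def add(self, kind: str, subject: str, obj: str, evidence: str | None = None) -> None:
        key = (kind, subject, obj, evidence)
        self.rows.setdefault(key, set()).update(self._articles())

    def has(self, kind: str, subject: str, obj: str) -> bool:
        return any(
            k == kind and s == subject and o == obj for k, s, o, _ in self.rows
        )

    def to_frames(self) -> dict[str, pd.DataFrame]:
        frames: dict[str, list] = {k: [] for k in RELATION_KINDS}
        for (kind, subj, obj, evidence), arts in self.rows.items():
            frames[kind].append(
                {
                    "subject_id": subj,
                    "object_id": obj,
                    "direct_evidence": evidence,
                    "organism_id": None,
                    "support_articles": frozenset(arts),
                }
            )
        return {
            k: pd.DataFrame(v, columns=RELATION_COLUMNS) for k, v in frames.items()
        }


def _build_phenotype_hierarchy(
    config: SyntheticConfig, rng: np.random.Generator, mapping: EventMapping
) -> tuple[OntologyHierarchy, dict[str, list[str]], list[str]]:
    """GO-like DAG: mapped terms with synthetic descendants + a background branch.

    Returns the hierarchy, the closure members planted under each mapped
    term, and the background phenotype pool (disjoint from every mapped
    closure).
    """
    h = OntologyHierarchy(namespace="phenotype")
    root = "GO:0008150"
    h.add_term(root, "biological_process (synthetic root)")
    mapped_terms = sorted(
        {
            str(t.term)
            for terms in mapping.terms.values()
            for t in terms
            if t.term_kind == "phenotype"
        }
    )
    closure_members: dict[str, list[str]] = {}
    serial = 9000000
    for term in mapped_terms:
        h.add_term(term, f"mapped phenotype {term}")
        h.add_parent_link(term, root)
        members = [term]
        for _ in range(2):  # two synthetic descendants per mapped term
            serial += 1
            child = f"GO:{serial}"
            h.add_term(child, f"synthetic descendant of {term}")
            h.add_parent_link(child, term)
            members.append(child)
        closure_members[term] = members
    bg_root = "GO:0009987"
    h.add_term(bg_root, "background processes (synthetic branch)")
    h.add_parent_link(bg_root, root)
    background: list[str] = []
    for i in range(config.n_background_phenotypes):
        node = f"GO:{9500000 + i}"
        h.add_term(node, f"background phenotype {i}")
        parent = bg_root if not background else str(
            rng.choice(background + [bg_root])
        )
        h.add_parent_link(node, parent)
        if background and rng.random() < config.extra_parent_prob:
            extra = str(rng.choice(background))
            if extra != node and extra != parent:
                h.add_parent_link(node, extra)
        background.append(node)
    h.validate()
    return h, closure_members, background


def _build_disease_hierarchy(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[OntologyHierarchy, list[str], list[str]]:
    """MEDIC-like poly-hierarchy with the autism branch planted.

    Returns the hierarchy, the autism closure (parent + descendants) and
    the background disease pool (outside the autism branch).
    """
    h = OntologyHierarchy(namespace="disease")
    root = "MESH:D999999"
    h.add_term(root, "diseases (synthetic root)")
    h.add_term(_ASD, "Autism Spectrum Disorder")
    h.add_parent_link(_ASD, root)
    for child, name in zip(
        _ASD_CHILDREN,
        ("Autistic Disorder", "Asperger Syndrome", "Adenylosuccinate lyase deficiency"),
    ):
        h.add_term(child, name)
        h.add_parent_link(child, _ASD)
    background: list[str] = []
    for i in range(config.n_background_diseases):
        node = f"MESH:D{900000 + i}"
        h.add_term(node, f"background disease {i}")
        parent = root if not background else str(rng.choice(background + [root]))
        h.add_parent_link(node, parent)
        if background and rng.random() < config.extra_parent_prob:
            extra = str(rng.choice(background))
            if extra not in (node, parent):
                h.add_parent_link(node, extra)
        background.append(node)
    h.validate()
    return h, [_ASD, *_ASD_CHILDREN], background


def _build_chemical_hierarchy(
    rng: np.random.Generator, chemicals: list[str]
) -> OntologyHierarchy:
    """Chemical tree: every chemical filed under >= 1 category parent."""
    h = OntologyHierarchy(namespace="chemical")
    root = "MESH:D002241"
    h.add_term(root, "chemicals (synthetic root)")
    categories = sorted(_CATEGORY_PARENTS)
    for cat in categories:
        h.add_term(cat, _CATEGORY_PARENTS[cat])
        h.add_parent_link(cat, root)
    for chem in chemicals:
        h.add_term(chem, f"chemical {chem}")
        primary = categories[int(rng.integers(len(categories)))]
        h.add_parent_link(chem, primary)
        if rng.random() < 0.1:  # occasional multi-category membership
            secondary = categories[int(rng.integers(len(categories)))]
            if secondary != primary:
                h.add_parent_link(chem, secondary)
    h.validate()
    return h


def generate_snapshot(
    config: SyntheticConfig | None = None,
) -> tuple[KnowledgeSnapshot, GroundTruthManifest]:
    """Generate a snapshot and its ground-truth manifest from one seed."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    mapping = bundled_event_mapping()
    store = _EdgeStore(rng, config.article_geom_p)

    pheno_h, pheno_closures, bg_phenos = _build_phenotype_hierarchy(config, rng, mapping)
    disease_h, asd_closure, bg_diseases = _build_disease_hierarchy(config, rng)

    gene_universe = dict(_CORE_GENES)
    bg_genes = []
    for i in range(config.n_background_genes):
        gid = f"GENE:{900000 + i}"
        gene_universe[gid] = f"BKG{i:04d}"
        bg_genes.append(gid)
    grin_genes = sorted(
        g for g, s in _CORE_GENES.items() if s.upper().startswith("GRIN")
    )

    # --- coverage tiers ----------------------------------------------------
    events = list(EVENT_ORDER)
    tiers: dict[int, list[str]] = {}
    incidence: dict[str, set[str]] = {}
    chem_serial = 0
    for score in sorted(config.coverage_tiers, reverse=True):
        count = config.coverage_tiers[score]
        members = []
        for _ in range(count):
            chem_serial += 1
            chem = f"MESH:C{500000 + chem_serial}"
            chosen = [events[j] for j in sorted(
                rng.choice(len(events), size=score, replace=False)
            )]
            for event in chosen:
                _wire_chemical_to_event(
                    store, rng, chem, event, mapping, pheno_closures,
                    asd_closure, grin_genes,
                )
            incidence[chem] = set(chosen)
            members.append(chem)
        tiers[score] = members

    # --- planted tetramers for the query chemicals -------------------------
    # Each gene index is paired with exactly one phenotype index and each
    # query chemical keeps one fixed disease, so the planted edge set is
    # *closed* under the five-edge rule: enumeration over the snapshot
    # yields exactly the planted tuples, never incidental recombinations.
    chem_disease = {
        chem: _ASD_CHILDREN[i % len(_ASD_CHILDREN)]
        for i, chem in enumerate(QUERY_CHEMICALS)
    }
    planted_tetramers: list[tuple[str, str, str, str]] = []
    # shared-dimer genes cycle over a smaller pool than the phenotypes, so
    # some genes annotate several phenotypes — the cross-phenotype links
    # the candidate-AOP stage builds edges from
    n_sh = config.n_shared_dimers
    n_sh_genes = max(1, (2 * n_sh) // 3) if n_sh else 0
    shared = [
        (bg_genes[k % n_sh_genes], bg_phenos[k]) for k in range(n_sh)
    ]

    def _pair(k: int) -> tuple[str, str]:
        return bg_genes[k], bg_phenos[k]
    for chem in QUERY_CHEMICALS:
        incidence.setdefault(chem, set())
        for gene, pheno in shared:
            planted_tetramers.append(
                _plant_tetramer(store, chem, gene, pheno, chem_disease[chem])
            )
            incidence[chem].add("AO:2209")  # ASD-closure marker/mechanism edge
    for i in range(config.n_planted_tetramers):
        chem = QUERY_CHEMICALS[i % len(QUERY_CHEMICALS)]
        gene, pheno = _pair(config.n_shared_dimers + i)
        planted_tetramers.append(
            _plant_tetramer(store, chem, gene, pheno, chem_disease[chem])
        )
        incidence[chem].add("AO:2209")

    # --- per-event mechanism tetramers (disease-network substrate) ----------
    # One anchor chemical/gene/phenotype triple per mechanistic event, fanned
    # out over a structured disease pool: a core shared by all five events,
    # an additional block shared by all but the NMDAR offshoot, and a few
    # private diseases each.  Anchors are chosen so each tetramer flows
    # through exactly one event's mapped terms.
    event_diseases: dict[str, list[str]] = {}
    n_disease_slots = (
        config.n_core_diseases
        + config.n_loo_additional_diseases
        + config.n_private_diseases * 5
    )
    if bg_diseases and n_disease_slots > 0:
        def _dslice(start: int, count: int) -> list[str]:
            return [bg_diseases[(start + j) % len(bg_diseases)] for j in range(count)]

        core = _dslice(0, config.n_core_diseases)
        additional = _dslice(config.n_core_diseases, config.n_loo_additional_diseases)
        offset = config.n_core_diseases + config.n_loo_additional_diseases
        mech_events = list(EVENT_ORDER[:-1])  # all but the AO
        loo_excluded = "KE:195"
        # anchors: (gene, phenotype) per event; gene events pair a mapped gene
        # with a dedicated mechanism phenotype, phenotype events pair a
        # dedicated mechanism gene with the event's first mapped term
        mech_phenos = {}
        for i, event in enumerate(("MIE:112", "KE:2207", "KE:195")):
            node = f"GO:{9600000 + i}"
            pheno_h.add_term(node, f"mechanism phenotype for {event}")
            pheno_h.add_parent_link(node, "GO:0009987")
            mech_phenos[event] = node
        mech_genes = {}
        for i, event in enumerate(("KE:2208", "KE:386")):
            gid = f"GENE:{850000 + i}"
            gene_universe[gid] = f"MECH{i:02d}"
            mech_genes[event] = gid
        anchors = {
            "MIE:112": ("GENE:2099", mech_phenos["MIE:112"]),
            "KE:2207": ("GENE:5594", mech_phenos["KE:2207"]),
            "KE:195": (grin_genes[0], mech_phenos["KE:195"]),
            "KE:2208": (mech_genes["KE:2208"], "GO:0045202"),
            "KE:386": (mech_genes["KE:386"], "GO:0007399"),
        }
        for i, event in enumerate(mech_events):
            diseases = sorted(
                set(core)
                | (set(additional) if event != loo_excluded else set())
                | set(_dslice(offset + i * config.n_private_diseases,
                              config.n_private_diseases))
            )
            gene, pheno = anchors[event]
            chem = f"MESH:C{750000 + i}"
            for disease in diseases:
                planted_tetramers.append(
                    _plant_tetramer(store, chem, gene, pheno, disease)
                )
            event_diseases[event] = diseases
            incidence[chem] = {event}

    # --- decoys -------------------------------------------------------------
    decoys: list[dict] = []
    for i in range(config.n_decoys):
        chem = f"MESH:C{700000 + i}"
        gid = f"GENE:{800000 + i}"  # fresh gene: decoy edges are unforgeable
        gene_universe[gid] = f"DCY{i:04d}"
        pheno = bg_phenos[int(rng.integers(len(bg_phenos)))] if bg_phenos else "GO:9500000"
        disease = bg_diseases[int(rng.integers(len(bg_diseases)))] if bg_diseases else _ASD
        omitted = EDGE_NAMES_CYCLE[i % 5]
        edges = {
            "chem_gene": (chem, gid, None),
            "chem_phenotype": (chem, pheno, None),
            "chem_disease": (chem, disease, "marker_mechanism"),
            "gene_phenotype": (gid, pheno, None),
            "gene_disease": (gid, disease, "marker_mechanism"),
        }
        for name, (s, o, ev) in edges.items():
            if name != omitted:
                store.add(name, s, o, ev)
        decoys.append(
            {"tuple": [chem, gid, pheno, disease], "omitted_edge": omitted}
        )
        incidence[chem] = set()  # decoy phenotypes/diseases are outside mapped closures

    # --- background noise ----------------------------------------------------
    bg_chems = [f"MESH:C{600000 + i}" for i in range(config.n_background_chemicals)]
    _add_background(store, rng, config.background_density, bg_chems, bg_genes,
                    bg_phenos, bg_diseases)

    all_chemicals = sorted(
        {s for (k, s, _, _) in store.rows if k.startswith("chem_")}
        | set(bg_chems)
        | set(QUERY_CHEMICALS)
    )
    chem_h = _build_chemical_hierarchy(rng, all_chemicals)

    snapshot = assemble_snapshot(
        store.to_frames(),
        pheno_h,
        disease_h,
        chem_h,
        gene_universe,
        snapshot_label=f"synthetic-seed-{config.seed}",
    )
    manifest = GroundTruthManifest(
        tiers=tiers,
        incidence={c: sorted(e) for c, e in incidence.items()},
        planted_tetramers=planted_tetramers,
        shared_dimers=shared,
        query_chemicals=list(QUERY_CHEMICALS),
        decoys=decoys,
        event_diseases=event_diseases,
    )
    return snapshot, manifest


EDGE_NAMES_CYCLE = (
    "chem_gene", "chem_phenotype", "chem_disease", "gene_phenotype", "gene_disease"
)


def _wire_chemical_to_event(
    store: _EdgeStore,
    rng: np.random.Generator,
    chem: str,
    event: str,
    mapping: EventMapping,
    pheno_closures: dict[str, list[str]],
    asd_closure: list[str],
    grin_genes: list[str],
) -> None:
    """Add one relation making ``chem`` intersect ``event``."""
    terms = mapping.terms[event]
    term = terms[int(rng.integers(len(terms)))]
    if term.term_kind == "gene":
        store.add("chem_gene", chem, str(term.term))
    elif term.term_kind == "gene_pattern":
        store.add("chem_gene", chem, grin_genes[int(rng.integers(len(grin_genes)))])
    elif term.term_kind == "phenotype":
        members = pheno_closures[str(term.term)]
        store.add("chem_phenotype", chem, members[int(rng.integers(len(members)))])
    else:  # disease (the AO): marker/mechanism evidence into the ASD closure
        target = asd_closure[int(rng.integers(len(asd_closure)))]
        store.add("chem_disease", chem, target, "marker_mechanism")


def _plant_tetramer(
    store: _EdgeStore, chem: str, gene: str, pheno: str, disease: str
) -> tuple[str, str, str, str]:
    store.add("chem_gene", chem, gene)
    store.add("chem_phenotype", chem, pheno)
    store.add("chem_disease", chem, disease, "marker_mechanism")
    store.add("gene_phenotype", gene, pheno)
    store.add("gene_disease", gene, disease, "marker_mechanism")
    return (chem, gene, pheno, disease)


def _add_background(
    store: _EdgeStore,
    rng: np.random.Generator,
    density: float,
    chems: list[str],
    genes: list[str],
    phenos: list[str],
    diseases: list[str],
) -> None:
    if density <= 0:
        return
    pools = {
        "chem_gene": (chems, genes, None),
        "chem_phenotype": (chems, phenos, None),
        "chem_disease": (chems, diseases, "marker_mechanism"),
        "gene_phenotype": (genes, phenos, None),
        "gene_disease": (genes, diseases, "marker_mechanism"),
    }
    for kind, (subjects, objects, evidence) in pools.items():
        if not subjects or not objects:
            continue
        n_edges = int(round(density * len(subjects) * len(objects)))
        for _ in range(n_edges):
            s = subjects[int(rng.integers(len(subjects)))]
            o = objects[int(rng.integers(len(objects)))]
            store.add(kind, s, o, evidence)


# ---------------------------------------------------------------------------
# File emission (the same dialects kb_io reads)
# ---------------------------------------------------------------------------


def write_synthetic_inputs(
    config: SyntheticConfig, out_dir: str | Path
) -> tuple[Path, GroundTruthManifest]:
    """Emit a full synthetic input set as files, plus the manifest.

    Relation TSVs in the commented bulk dialect, the phenotype hierarchy
    as OBO, the disease and chemical hierarchies as tree-numbered TSVs,
    the AOP tables, the event mapping, and ``manifest.json`` — everything
    the file-based pipeline entry point consumes.  Deterministic for a
    fixed config and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    snapshot, manifest = generate_snapshot(config)

    for kind in RELATION_KINDS:
        df = snapshot.relations[kind].copy()
        df["support_articles"] = df["support_articles"].map(
            lambda s: "|".join(sorted(s))
        )
        df = df.fillna("")
        header = "# synthetic curated relations\n# Fields:\t" + "\t".join(df.columns) + "\n"
        body = df.to_csv(sep="\t", index=False, header=False)
        (out_dir / f"{kind}.tsv").write_text(header + body)

    _write_obo(snapshot.phenotype_hierarchy, out_dir / "phenotypes.obo")
    _write_tree_vocab(snapshot.disease_hierarchy, out_dir / "diseases.tsv", "Disease")
    _write_tree_vocab(snapshot.chemical_hierarchy, out_dir / "chemicals.tsv", "Chemical")

    genes = pd.DataFrame(
        sorted(snapshot.gene_universe.items()), columns=["GeneID", "GeneSymbol"]
    )
    genes.to_csv(out_dir / "genes.tsv", sep="\t", index=False)

    _write_aop_tables(out_dir)
    from importlib import resources

    mapping_text = (
        resources.files("aoplink.data") / "aop522_event_mapping.tsv"
    ).read_text()
    (out_dir / "event_mapping.tsv").write_text(mapping_text)
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return out_dir, manifest


def _write_obo(hierarchy: OntologyHierarchy, path: Path) -> None:
    parents: dict[str, list[str]] = {}
    for child, parent, _ in sorted(hierarchy.parent_links()):
        parents.setdefault(child, []).append(parent)
    lines = ["format-version: 1.2", "ontology: aoplink-synthetic", ""]
    for term in sorted(hierarchy.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {hierarchy.name(term)}")
        for parent in sorted(parents.get(term, [])):
            lines.append(f"is_a: {parent}")
        lines.append("")
    path.write_text("\n".join(lines))


def _write_tree_vocab(hierarchy: OntologyHierarchy, path: Path, kind: str) -> None:
    # assign tree numbers by DFS from the roots; extra parents become
    # additional ParentIDs entries
    tree_numbers: dict[str, str] = {}
    counter = [0]

    def assign(node: str, prefix: str) -> None:
        counter[0] += 1
        number = f"{prefix}.{counter[0]:05d}" if prefix else f"T{counter[0]:05d}"
        if node in tree_numbers:
            return
        tree_numbers[node] = number
        for child in sorted(hierarchy.children(node)):
            assign(child, number)

    for root in sorted(hierarchy.roots):
        assign(root, "")
    rows = []
    for term in sorted(hierarchy.terms):
        parent_ids = "|".join(sorted(hierarchy.parents(term)))
        rows.append(
            {
                f"{kind}Name": hierarchy.name(term),
                f"{kind}ID": term,
                "ParentIDs": parent_ids,
                "TreeNumbers": tree_numbers.get(term, ""),
            }
        )
    df = pd.DataFrame(rows)
    header = "# Fields:\t" + "\t".join(df.columns) + "\n"
    path.write_text(header + df.to_csv(sep="\t", index=False, header=False))


def _write_aop_tables(out_dir: Path) -> None:
    aops = synthetic_aop_definitions()
    rows = []
    for aop_id in sorted(aops):
        aop = aops[aop_id]
        downstream: dict[str, list[str]] = {}
        for src, dst in sorted(aop.kers):
            downstream.setdefault(src, []).append(dst)
        for event in sorted(aop.event_types):
            rows.append(
                {
                    "aop_id": aop_id,
                    "event_id": event,
                    "event_type": aop.event_types[event],
                    "event_title": aop.event_titles.get(event, ""),
                    "downstream_events": "|".join(downstream.get(event, [])),
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "aops.tsv", sep="\t", index=False)
    comp_rows = [
        {"event_id": ev, "term_id": term}
        for aop_id in sorted(aops)
        for ev in sorted(aops[aop_id].event_types)
        for term in aops[aop_id].components.get(ev, [])
    ]
    pd.DataFrame(comp_rows, columns=["event_id", "term_id"]).to_csv(
        out_dir / "aop_event_components.tsv", sep="\t", index=False
    )
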