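"""End-to-end pipeline: snapshot -> coverage -> tetramers -> AOP -> diseases.

The four analysis stages mirror the method's figures in order: chemical
prioritisation over the AOP events, tetramer enumeration with shared
GP-dimer discovery and chord export, candidate-AOP assembly from shared
phenotype gene sets, and disease-network discovery (per-event disease
sets, Venn regions, leave-one-out, cross-AOP sharing).  Every run writes
a machine-readable run manifest (seed, input digests, per-stage counts)
and is deterministic for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .aop_construction import (
    assemble_aop_graph,
    phenotype_gene_sets,
    write_graphml,
    write_text,
)
from .disease_networks import core_and_loo, event_disease_sets, related_aops, venn_cells
from .event_intersection import (
    bundled_event_mapping,
    categorize_chemicals,
    event_coverage,
    load_event_mapping,
    rank_chemicals,
)
from .kb_io import (
    KnowledgeSnapshot,
    RELATION_KINDS,
    load_aop_definitions,
    load_relation_table,
    parse_obo,
    parse_tree_vocab,
    assemble_snapshot,
)
from .synthetic_data import (
    AOP_ID,
    QUERY_CHEMICALS,
    SyntheticConfig,
    generate_snapshot,
    synthetic_aop_definitions,
)
from .tetramer_engine import (
    TetramerIndex,
    TetramerQuery,
    chord_data,
    dimer_projection,
    enumerate_tetramers,
    shared_dimers,
    tetramers_to_frame,
    write_chord,
    write_tetramers,
)
from .vocabularies import ValidationError

logger = logging.getLogger("aoplink")

__all__ = ["PipelineConfig", "StageError", "run_full_analysis", "load_snapshot_inputs"]

_ASD = "MESH:D000067877"
_LEVELS_CYCLE = ("molecular", "cellular", "system", "behavioral")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Everything one run needs.  Exactly one input source must be set."""

    snapshot_dir: str | None = None
    synthetic: SyntheticConfig | None = None
    aop_id: str = AOP_ID
    event_mapping_path: str | None = None  # None -> packaged mapping
    query_chemicals: list[str] = field(default_factory=lambda: list(QUERY_CHEMICALS))
    query_disease: str = _ASD
    phenotype_levels: dict[str, str] | None = None  # None -> derived round-robin
    min_score: int = 5
    category_parents: list[str] = field(default_factory=list)
    chem_disease_evidence: str | None = "marker_mechanism"
    gene_disease_evidence: str | None = None
    wildcard_exclusions: list[str] = field(default_factory=list)
    output_dir: str = "aoplink_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.snapshot_dir is None) == (self.synthetic is None):
            raise ValidationError(
                "exactly one of snapshot_dir / synthetic must be configured"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in data and data["synthetic"] is not None:
            syn = dict(data["synthetic"])
            if "coverage_tiers" in syn:
                syn["coverage_tiers"] = {
                    int(k): int(v) for k, v in syn["coverage_tiers"].items()
                }
            data["synthetic"] = SyntheticConfig(**syn)
        cfg = cls(**data)
        if seed is not None:
            cfg.seed = seed
            if cfg.synthetic is not None:
                cfg.synthetic.seed = seed
        return cfg


# ---------------------------------------------------------------------------
# Input loading
# ---------------------------------------------------------------------------


def load_snapshot_inputs(in_dir: str | Path) -> KnowledgeSnapshot:
    """Assemble a snapshot from a directory of dialect files.

    Expects the file names the synthetic emitter writes: one
    ``<kind>.tsv`` per relation, ``phenotypes.obo``, ``diseases.tsv``,
    ``chemicals.tsv`` (tree vocabularies) and ``genes.tsv``.
    """
    in_dir = Path(in_dir)
    relations = {
        kind: load_relation_table(in_dir / f"{kind}.tsv", kind)
        for kind in RELATION_KINDS
    }
    pheno = parse_obo(in_dir / "phenotypes.obo")
    disease = parse_tree_vocab(in_dir / "diseases.tsv", "disease")
    chemical = parse_tree_vocab(in_dir / "chemicals.tsv", "chemical")
    genes = pd.read_csv(
        in_dir / "genes.tsv", sep="\t", dtype=str, keep_default_na=False
    )
    gene_universe = dict(zip(genes.iloc[:, 0], genes.iloc[:, 1]))
    return assemble_snapshot(
        relations, pheno, disease, chemical, gene_universe,
        snapshot_label=str(in_dir),
    )


def _prepare(config: PipelineConfig):
    if config.synthetic is not None:
        snapshot, manifest = generate_snapshot(config.synthetic)
        aops = synthetic_aop_definitions()
    else:
        snapshot = load_snapshot_inputs(config.snapshot_dir)
        manifest = None
        aop_path = Path(config.snapshot_dir) / "aops.tsv"
        comp_path = Path(config.snapshot_dir) / "aop_event_components.tsv"
        aops = load_aop_definitions(
            aop_path, comp_path if comp_path.exists() else None
        )
    mapping = (
        load_event_mapping(config.event_mapping_path)
        if config.event_mapping_path
        else bundled_event_mapping()
    )
    if config.aop_id not in aops:
        raise StageError("prepare", "validation", f"unknown AOP {config.aop_id}")
    return snapshot, manifest, aops, mapping


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_coverage(snapshot, mapping, aop, config, out_dir: Path) -> dict:
    coverage = event_coverage(
        snapshot, mapping, aop, exclude_symbols=config.wildcard_exclusions
    )
    coverage.to_frame().to_csv(out_dir / "coverage.tsv", sep="\t", index=False)
    ranked = rank_chemicals(coverage, config.min_score)
    ranked.to_csv(out_dir / "ranking.tsv", sep="\t", index=False)
    counts = {
        "chemicals_total": len(coverage.chemicals),
        "tier_sizes": coverage.tier_sizes(),
        "ranked_at_min_score": len(ranked),
    }
    if config.category_parents:
        groups = categorize_chemicals(
            snapshot.chemical_hierarchy,
            ranked["chemical_id"],
            config.category_parents,
        )
        rows = [
            {"category": cat, "chemical_id": chem}
            for cat, members in groups.items()
            for chem in sorted(members)
        ]
        pd.DataFrame(rows, columns=["category", "chemical_id"]).to_csv(
            out_dir / "categories.tsv", sep="\t", index=False
        )
        counts["categories"] = {cat: len(m) for cat, m in groups.items()}
    logger.info("coverage: %d chemicals, tiers %s",
                counts["chemicals_total"], counts["tier_sizes"])
    return counts


def stage_tetramers(snapshot, config, out_dir: Path) -> tuple[dict, list, set]:
    index = TetramerIndex(
        snapshot, config.chem_disease_evidence, config.gene_disease_evidence
    )
    per_query = []
    for chem in config.query_chemicals:
        tets = enumerate_tetramers(
            snapshot,
            TetramerQuery(chemical=chem, disease=config.query_disease),
            index=index,
        )
        write_tetramers(
            tets, out_dir / f"tetramers_{chem.replace(':', '_')}.csv", snapshot
        )
        per_query.append(tets)
    if len(per_query) >= 2:
        shared, gene_tally, pheno_tally = shared_dimers(per_query)
    else:
        shared = dimer_projection(per_query[0]) if per_query else set()
        gene_tally = pheno_tally = {}
    pd.DataFrame(
        sorted((d.gene_id, d.phenotype_id) for d in shared),
        columns=["gene_id", "phenotype_id"],
    ).to_csv(out_dir / "shared_dimers.tsv", sep="\t", index=False)
    restricted = [
        t
        for tets in per_query
        for t in tets
        if (t.gene_id, t.phenotype_id) in {(d.gene_id, d.phenotype_id) for d in shared}
    ]
    if restricted:
        write_chord(chord_data(restricted), out_dir / "chord.txt")
    counts = {
        "tetramers_per_query": {
            chem: len(tets)
            for chem, tets in zip(config.query_chemicals, per_query)
        },
        "shared_dimers": len(shared),
        "shared_genes": len(set(gene_tally)),
        "shared_phenotypes": len(set(pheno_tally)),
        "restricted_tetramers": len(restricted),
    }
    logger.info("tetramers: %s; %d shared dimers",
                counts["tetramers_per_query"], counts["shared_dimers"])
    return counts, restricted, shared


def stage_aop_candidate(restricted, shared, config, out_dir: Path) -> dict:
    if not restricted:
        raise StageError("build-aop", "runtime", "no shared-dimer tetramers to build from")
    levels = config.phenotype_levels
    if levels is None:
        phenos = sorted({d.phenotype_id for d in shared})
        levels = {
            p: _LEVELS_CYCLE[i % len(_LEVELS_CYCLE)] for i, p in enumerate(phenos)
        }
    gene_sets, flagged = phenotype_gene_sets(restricted, sorted(levels))
    candidate = assemble_aop_graph(
        stressors=config.query_chemicals,
        leveled=levels,
        gene_sets=gene_sets,
        outcome=config.query_disease,
    )
    write_graphml(candidate, out_dir / "aop_candidate.graphml")
    write_text(candidate, out_dir / "aop_candidate.txt")
    counts = {
        "aop_nodes": len(candidate.nodes),
        "aop_edges": len(candidate.edges),
        "aop_gene_union": len(set().union(*(n.gene_set for n in candidate.nodes))),
        "phenotypes_without_tetramers": sorted(flagged),
    }
    logger.info("aop candidate: %d nodes, %d edges", counts["aop_nodes"], counts["aop_edges"])
    return counts


def stage_disease_networks(snapshot, mapping, aop, aops, config, out_dir: Path) -> dict:
    mech_events = [
        e for e in aop.event_types
        if any(t.term_kind != "disease" for t in mapping.terms.get(e, []))
    ]
    sets = event_disease_sets(
        snapshot, mapping, mech_events, exclude_symbols=config.wildcard_exclusions
    )
    pd.DataFrame(
        [(e, d) for e in mech_events for d in sorted(sets[e])],
        columns=["event_id", "disease_id"],
    ).to_csv(out_dir / "event_diseases.tsv", sep="\t", index=False)
    nonempty = {e: s for e, s in sets.items() if s}
    counts: dict = {"event_disease_sizes": {e: len(s) for e, s in sets.items()}}
    if 2 <= len(nonempty) <= 6:
        venn = venn_cells(nonempty)
        venn.to_frame().to_csv(out_dir / "venn.tsv", sep="\t", index=False)
        counts["venn_core"] = len(venn.core)
        if len(nonempty) >= 3:
            drop = min(nonempty, key=lambda e: (len(nonempty[e]), e))
            core, expanded, additional = core_and_loo(nonempty, drop)
            pd.DataFrame(
                sorted(additional), columns=["disease_id"]
            ).to_csv(out_dir / "loo_additional.tsv", sep="\t", index=False)
            counts["loo_dropped_event"] = drop
            counts["loo_additional"] = len(additional)
    related = related_aops(aops, sorted(mech_events))
    related.to_csv(out_dir / "related_aops.tsv", sep="\t", index=False)
    counts["related_aop_rows"] = len(related)
    logger.info("disease networks: sizes %s", counts["event_disease_sizes"])
    return counts


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run all stages in order; returns the run manifest dictionary."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run: dict = {
        "version": __version__,
        "seed": config.seed,
        "aop_id": config.aop_id,
        "stages": {},
    }
    if config.snapshot_dir is not None:
        run["input_digests"] = {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(Path(config.snapshot_dir).glob("*"))
            if p.is_file()
        }
    stage = "prepare"
    try:
        snapshot, manifest, aops, mapping = _prepare(config)
        aop = aops[config.aop_id]
        run["snapshot_label"] = snapshot.snapshot_label
        stage = "intersect"
        run["stages"]["coverage"] = stage_coverage(
            snapshot, mapping, aop, config, out_dir
        )
        stage = "tetramers"
        tet_counts, restricted, shared = stage_tetramers(snapshot, config, out_dir)
        run["stages"]["tetramers"] = tet_counts
        stage = "build-aop"
        run["stages"]["aop_candidate"] = stage_aop_candidate(
            restricted, shared, config, out_dir
        )
        stage = "disease-net"
        run["stages"]["disease_networks"] = stage_disease_networks(
            snapshot, mapping, aop, aops, config, out_dir
        )
    except StageError:
        (out_dir / "FAILED").write_text(stage + "\n")
        raise
    except ValidationError as exc:
        (out_dir / "FAILED").write_text(stage + "\n")
        raise StageError(stage, "validation", str(exc)) from exc
    except Exception as exc:  # pragma: no cover - defensive
        (out_dir / "FAILED").write_text(stage + "\n")
        raise StageError(stage, "runtime", str(exc)) from exc
    (out_dir / "run_manifest.json").write_text(
        json.dumps(run, indent=2, sort_keys=True) + "\n"
    )
    return run
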