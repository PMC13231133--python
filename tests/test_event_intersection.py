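"""Chemical retrieval per term, coverage scoring, ranking, categorisation."""

import numpy as np
import pandas as pd
import pytest

from aoplink.event_intersection import (
    CoverageMatrix,
    EventMapping,
    MappedTerm,
    bundled_event_mapping,
    categorize_chemicals,
    chemicals_for_term,
    event_coverage,
    load_coverage_workbook,
    rank_chemicals,
)
from aoplink.kb_io import AOPDefinition
from aoplink.vocabularies import GenePattern, LookupError_, ValidationError
from conftest import build_snapshot, make_hierarchy, random_mini_snapshot


def _aop(events):
    return AOPDefinition(
        aop_id="AOP:1",
        event_types={e: ("AO" if e.startswith("AO") else "KE") for e in events},
        event_titles={},
        kers=set(),
    )


class TestChemicalsForTerm:
    def test_gene_direct_lookup(self):
        snap = build_snapshot(
            {"chem_gene": [("MESH:C000001", "GENE:1"), ("MESH:C000002", "GENE:1")]}
        )
        got = chemicals_for_term(snap, MappedTerm("gene", "GENE:1"))
        assert got == {"MESH:C000001", "MESH:C000002"}

    def test_phenotype_closure_subsumption(self):
        snap = build_snapshot(
            {"chem_phenotype": [("MESH:C000003", "GO:0000002")]},
            phenotypes={"GO:0000002": ["GO:0000001"]},
        )
        got = chemicals_for_term(snap, MappedTerm("phenotype", "GO:0000001"))
        assert got == {"MESH:C000003"}

    def test_disease_evidence_filter(self):
        snap = build_snapshot(
            {
                "chem_disease": [
                    ("MESH:C000004", "MESH:D000001", "therapeutic"),
                    ("MESH:C000005", "MESH:D000001", "marker_mechanism"),
                ]
            }
        )
        filtered = chemicals_for_term(
            snap, MappedTerm("disease", "MESH:D000001", "marker_mechanism")
        )
        assert filtered == {"MESH:C000005"}
        unfiltered = chemicals_for_term(snap, MappedTerm("disease", "MESH:D000001"))
        assert unfiltered == {"MESH:C000004", "MESH:C000005"}

    def test_gene_pattern_union(self):
        snap = build_snapshot(
            {
                "chem_gene": [
                    ("MESH:C000001", "GENE:1"),
                    ("MESH:C000002", "GENE:2"),
                    ("MESH:C000003", "GENE:3"),
                ]
            },
            genes={"GENE:1": "GRIN1", "GENE:2": "GRIN2A", "GENE:3": "ESR1"},
        )
        got = chemicals_for_term(snap, MappedTerm("gene_pattern", GenePattern("GRIN*")))
        assert got == {"MESH:C000001", "MESH:C000002"}

    def test_unknown_gene_raises(self, planted_snapshot):
        with pytest.raises(LookupError_):
            chemicals_for_term(planted_snapshot, MappedTerm("gene", "GENE:999"))


class TestEventCoverage:
    def _snapshot_two_events(self):
        return build_snapshot(
            {
                "chem_gene": [("MESH:C000001", "GENE:1"), ("MESH:C000001", "GENE:2")],
                "chem_phenotype": [("MESH:C000002", "GO:0000001")],
            }
        )

    def test_two_terms_same_event_count_once(self):
        snap = self._snapshot_two_events()
        mapping = EventMapping(
            {
                "KE:1": [MappedTerm("gene", "GENE:1"), MappedTerm("gene", "GENE:2")],
                "KE:2": [MappedTerm("phenotype", "GO:0000001")],
            }
        )
        cov = event_coverage(snap, mapping, _aop(["KE:1", "KE:2"]))
        assert int(cov.scores["MESH:C000001"]) == 1

    def test_score_is_event_row_sum_and_sorting(self):
        snap = build_snapshot(
            {
                "chem_gene": [
                    ("MESH:C000001", "GENE:1"),
                    ("MESH:C000001", "GENE:2"),
                    ("MESH:C000002", "GENE:1"),
                ],
            }
        )
        mapping = EventMapping(
            {
                "KE:1": [MappedTerm("gene", "GENE:1")],
                "KE:2": [MappedTerm("gene", "GENE:2")],
            }
        )
        cov = event_coverage(snap, mapping, _aop(["KE:1", "KE:2"]))
        assert cov.chemicals == ["MESH:C000001", "MESH:C000002"]  # score desc
        assert cov.tier_sizes() == {2: 1, 1: 1}

    def test_zero_score_chemicals_absent(self):
        snap = self._snapshot_two_events()
        mapping = EventMapping({"KE:1": [MappedTerm("gene", "GENE:1")]})
        cov = event_coverage(snap, mapping, _aop(["KE:1"]))
        assert "MESH:C000002" not in cov.chemicals

    def test_empty_mapping_rejected(self):
        snap = self._snapshot_two_events()
        with pytest.raises(ValidationError):
            event_coverage(snap, EventMapping({}), _aop(["KE:1"]))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_per_triple_brute_force(self, seed):
        """Coverage equals testing every (chemical, event, term) triple."""
        rng = np.random.default_rng(seed)
        snap = random_mini_snapshot(seed, n_chem=int(rng.integers(10, 50)))
        phenos = sorted(snap.phenotype_hierarchy.terms)[:4]
        genes = sorted(snap.gene_universe)[:3]
        mapping = EventMapping(
            {
                "KE:1": [MappedTerm("gene", g) for g in genes[:2]],
                "KE:2": [MappedTerm("phenotype", p) for p in phenos[:2]],
                "KE:3": [MappedTerm("gene", genes[2]),
                         MappedTerm("phenotype", phenos[2])],
            }
        )
        cov = event_coverage(snap, mapping, _aop(["KE:1", "KE:2", "KE:3"]))
        # brute force: each (chemical, event, term) tested independently
        chems = set(snap.relations["chem_gene"]["subject_id"]) | set(
            snap.relations["chem_phenotype"]["subject_id"]
        )
        expect: dict[str, set[str]] = {}
        for chem in chems:
            for event, terms in mapping.terms.items():
                for term in terms:
                    if chem in chemicals_for_term(snap, term):
                        expect.setdefault(chem, set()).add(event)
        assert {c: set(cov.incidence.columns[cov.incidence.loc[c]])
                for c in cov.chemicals} == expect

    def test_monotone_in_relations(self):
        """Adding a relation never decreases any chemical's score."""
        genes = {"GENE:1": "G1", "GENE:2": "G2", "GENE:3": "G3"}
        mapping = EventMapping(
            {"KE:1": [MappedTerm("gene", "GENE:1")],
             "KE:2": [MappedTerm("gene", "GENE:3")]}
        )
        before = event_coverage(
            build_snapshot(
                {"chem_gene": [("MESH:C000001", "GENE:1")]}, genes=genes
            ),
            mapping,
            _aop(["KE:1", "KE:2"]),
        ).scores
        bigger = build_snapshot(
            {
                "chem_gene": [
                    ("MESH:C000001", "GENE:1"),
                    ("MESH:C000001", "GENE:2"),
                    ("MESH:C000001", "GENE:3"),
                ],
            },
            genes=genes,
        )
        after = event_coverage(bigger, mapping, _aop(["KE:1", "KE:2"])).scores
        for chem, score in before.items():
            assert after.get(chem, 0) >= score


class TestRanking:
    def _coverage(self, scores):
        events = [f"KE:{i}" for i in range(1, 7)]
        rows = {}
        for chem, score in scores.items():
            rows[chem] = {e: i < score for i, e in enumerate(events)}
        return CoverageMatrix.from_incidence(
            pd.DataFrame.from_dict(rows, orient="index"), events
        )

    def test_tie_break_by_chemical_id(self):
        cov = self._coverage(
            {"MESH:C000001": 6, "MESH:C000003": 5, "MESH:C000002": 5}
        )
        ranked = rank_chemicals(cov, 5)
        assert list(ranked["chemical_id"]) == [
            "MESH:C000001", "MESH:C000002", "MESH:C000003",
        ]

    def test_min_score_above_max_gives_empty(self):
        cov = self._coverage({"MESH:C000001": 3})
        assert rank_chemicals(cov, 6).empty

    def test_min_score_out_of_range(self):
        cov = self._coverage({"MESH:C000001": 3})
        with pytest.raises(ValidationError):
            rank_chemicals(cov, 0)

    def test_conservation_distinct_chemicals(self):
        cov = self._coverage({"MESH:C000001": 2, "MESH:C000002": 4})
        assert len(cov.chemicals) == len(set(cov.chemicals)) == 2


class TestCategorisation:
    def test_closure_membership_and_multimembership(self):
        h = make_hierarchy(
            "chemical",
            {
                "MESH:D000002": ["MESH:D000001"],  # cadmium under metals
                "MESH:D000003": ["MESH:D000010", "MESH:D000011"],
            },
            roots=["MESH:D000001", "MESH:D000010", "MESH:D000011"],
        )
        groups = categorize_chemicals(
            h,
            {"MESH:D000002", "MESH:D000003", "MESH:D000099"},
            ["MESH:D000001", "MESH:D000010", "MESH:D000011"],
        )
        assert groups["MESH:D000001"] == {"MESH:D000002"}
        assert groups["MESH:D000010"] == {"MESH:D000003"}
        assert groups["MESH:D000011"] == {"MESH:D000003"}  # multi-membership
        assert groups["uncategorized"] == {"MESH:D000099"}

    def test_empty_parent_list_all_uncategorized(self):
        h = make_hierarchy("chemical", {}, roots=["MESH:D000001"])
        groups = categorize_chemicals(h, {"MESH:C000001"}, [])
        assert groups == {"uncategorized": {"MESH:C000001"}}

    def test_unknown_parent_raises(self):
        h = make_hierarchy("chemical", {}, roots=["MESH:D000001"])
        with pytest.raises(LookupError_):
            categorize_chemicals(h, set(), ["MESH:D999999"])


class TestBundledMapping:
    def test_published_term_structure(self):
        """Six events; 19 gene/phenotype terms + 1 evidence-filtered disease."""
        mapping = bundled_event_mapping()
        assert set(mapping.terms) == {
            "MIE:112", "KE:2207", "KE:195", "KE:2208", "KE:386", "AO:2209",
        }
        kinds = [t.term_kind for terms in mapping.terms.values() for t in terms]
        assert kinds.count("gene") == 4
        assert kinds.count("gene_pattern") == 1
        assert kinds.count("phenotype") == 14
        ao = mapping.terms["AO:2209"]
        assert ao == [
            MappedTerm("disease", "MESH:D000067877", "marker_mechanism")
        ]
        ke195 = mapping.terms["KE:195"]
        assert ke195[0].term.pattern == "GRIN*"
        assert "GO:0098989" in {str(t.term) for t in ke195}


class TestCoverageWorkbook:
    def test_round_trip_through_xlsx(self, tmp_path):
        events = ["MIE:112", "KE:2207", "AO:2209"]
        frame = pd.DataFrame(
            {
                "ChemicalID": ["MESH:C000001", "MESH:C000002"],
                "MIE:112": ["x", ""],
                "KE:2207": ["x", "x"],
                "AO:2209": ["", "x"],
            }
        )
        path = tmp_path / "s1.xlsx"
        frame.to_excel(path, index=False)
        cov = load_coverage_workbook(path)
        assert cov.events == events
        assert cov.tier_sizes() == {2: 2}
        assert bool(cov.incidence.loc["MESH:C000001", "MIE:112"]) is True
        assert bool(cov.incidence.loc["MESH:C000002", "MIE:112"]) is False
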