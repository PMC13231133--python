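"""File dialects: relation TSVs, OBO, tree vocabularies, AOP tables, exports."""

import gzip

import pandas as pd
import pytest

from aoplink.kb_io import (
    FormatError,
    load_aop_definitions,
    load_relation_table,
    load_tetramer_export,
    parse_obo,
    parse_tree_vocab,
    read_snapshot,
    write_snapshot,
)
from aoplink.vocabularies import ValidationError
from conftest import build_snapshot

MINI_OBO = """format-version: 1.2
ontology: test

[Term]
id: GO:0000001
name: A

[Term]
id: GO:0000002
name: B
is_a: GO:0000001

[Term]
id: GO:0000003
name: C
is_a: GO:0000002
"""


class TestRelationTables:
    def test_parse_with_comment_lines(self, tmp_path):
        path = tmp_path / "cg.tsv"
        path.write_text(
            "# comment\n# another\n"
            "subject_id\tobject_id\tsupport_articles\n"
            "MESH:C000001\tGENE:1\tPMID:1\n"
            "MESH:C000002\tGENE:1\tPMID:2\n"
            "MESH:C000003\tGENE:2\t\n"
        )
        df = load_relation_table(path, "chem_gene")
        assert len(df) == 3
        assert df["support_articles"].iloc[0] == frozenset({"PMID:1"})

    def test_duplicate_rows_union_articles(self, tmp_path):
        path = tmp_path / "cg.tsv"
        path.write_text(
            "subject_id\tobject_id\tsupport_articles\n"
            "MESH:C000001\tGENE:1\tPMID:1\n"
            "MESH:C000001\tGENE:1\tPMID:2\n"
        )
        df = load_relation_table(path, "chem_gene")
        assert len(df) == 1
        assert df["support_articles"].iloc[0] == frozenset({"PMID:1", "PMID:2"})

    def test_rows_differing_in_evidence_kept_separate(self, tmp_path):
        path = tmp_path / "cd.tsv"
        path.write_text(
            "subject_id\tobject_id\tdirect_evidence\n"
            "MESH:C000001\tMESH:D000001\tmarker/mechanism\n"
            "MESH:C000001\tMESH:D000001\ttherapeutic\n"
        )
        df = load_relation_table(path, "chem_disease")
        assert len(df) == 2
        assert set(df["direct_evidence"]) == {"marker_mechanism", "therapeutic"}

    def test_missing_mapped_column_is_format_error(self, tmp_path):
        path = tmp_path / "cg.tsv"
        path.write_text("a\tb\nMESH:C000001\tGENE:1\n")
        with pytest.raises(FormatError, match="ChemicalID"):
            load_relation_table(
                path, "chem_gene", {"ChemicalID": "subject_id", "b": "object_id"}
            )

    def test_namespace_mismatch_names_row(self, tmp_path):
        path = tmp_path / "cg.tsv"
        path.write_text(
            "subject_id\tobject_id\nMESH:C000001\tGENE:1\nGO:0000001\tGENE:2\n"
        )
        with pytest.raises(ValidationError, match="row 2"):
            load_relation_table(path, "chem_gene")

    def test_gzip_detected_by_magic_bytes_not_extension(self, tmp_path):
        path = tmp_path / "cg.tsv"  # plain name, compressed content
        content = "subject_id\tobject_id\nMESH:C000001\tGENE:1\n"
        path.write_bytes(gzip.compress(content.encode()))
        df = load_relation_table(path, "chem_gene")
        assert len(df) == 1

    def test_ctd_style_header_in_fields_comment(self, tmp_path):
        path = tmp_path / "cg.tsv"
        path.write_text(
            "# CTD-style dump\n# Fields:\tsubject_id\tobject_id\n"
            "MESH:C000001\tGENE:1\n"
        )
        df = load_relation_table(path, "chem_gene")
        assert list(df["object_id"]) == ["GENE:1"]

    def test_organism_allow_list_filters(self, tmp_path):
        path = tmp_path / "cg.tsv"
        path.write_text(
            "subject_id\tobject_id\torganism_id\n"
            "MESH:C000001\tGENE:1\t9606\n"
            "MESH:C000002\tGENE:1\t10090\n"
        )
        df = load_relation_table(path, "chem_gene", organism_allow=["9606"])
        assert list(df["subject_id"]) == ["MESH:C000001"]


class TestObo:
    def test_three_node_chain(self, tmp_path):
        path = tmp_path / "t.obo"
        path.write_text(MINI_OBO)
        h = parse_obo(path)
        assert len(h) == 3
        assert h.descendant_closure("GO:0000001") == {
            "GO:0000001", "GO:0000002", "GO:0000003",
        }

    def test_obsolete_excluded(self, tmp_path):
        path = tmp_path / "t.obo"
        path.write_text(
            MINI_OBO + "\n[Term]\nid: GO:0000004\nname: D\nis_obsolete: true\n"
        )
        h = parse_obo(path)
        assert "GO:0000004" not in h

    def test_dangling_parent_rejected(self, tmp_path):
        path = tmp_path / "t.obo"
        path.write_text(
            "format-version: 1.2\nontology: test\n\n"
            "[Term]\nid: GO:0000001\nname: A\nis_a: GO:0009999\n"
        )
        with pytest.raises(ValidationError, match="undeclared parent"):
            parse_obo(path)

    def test_part_of_only_when_enabled(self, tmp_path):
        path = tmp_path / "t.obo"
        path.write_text(
            "format-version: 1.2\nontology: test\n\n"
            "[Term]\nid: GO:0000001\nname: A\n\n"
            "[Term]\nid: GO:0000002\nname: B\nrelationship: part_of GO:0000001\n"
        )
        assert parse_obo(path).descendant_closure("GO:0000001") == {"GO:0000001"}
        h = parse_obo(path, include_part_of=True)
        assert h.descendant_closure("GO:0000001") == {"GO:0000001", "GO:0000002"}


class TestTreeVocab:
    def test_autism_branch_fixture(self, tmp_path):
        path = tmp_path / "medic.tsv"
        path.write_text(
            "# Fields:\tDiseaseName\tDiseaseID\tParentIDs\tTreeNumbers\n"
            "Autism Spectrum Disorder\tMESH:D000067877\t\tC10.1\n"
            "Autistic Disorder\tMESH:D001321\tMESH:D000067877\tC10.1.1\n"
            "Asperger Syndrome\tMESH:D020817\tMESH:D000067877\tC10.1.2\n"
            "ASL deficiency\tMESH:C538235\tMESH:D000067877\tC10.1.3\n"
        )
        h = parse_tree_vocab(path, "disease")
        assert len(h) == 4
        assert h.children("MESH:D000067877") == {
            "MESH:D001321", "MESH:D020817", "MESH:C538235",
        }

    def test_tree_number_prefixes_alone_give_parentage(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(
            "# Fields:\tChemicalName\tChemicalID\tTreeNumbers\n"
            "root\tMESH:D000001\tD01\n"
            "child\tMESH:D000002\tD01.100\n"
        )
        h = parse_tree_vocab(path, "chemical")
        assert h.parents("MESH:D000002") == {"MESH:D000001"}

    def test_two_tree_numbers_two_parents(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(
            "# Fields:\tDiseaseName\tDiseaseID\tTreeNumbers\n"
            "a\tMESH:D000001\tC01\n"
            "b\tMESH:D000002\tC02\n"
            "c\tMESH:D000003\tC01.1|C02.9\n"
        )
        h = parse_tree_vocab(path, "disease")
        assert h.parents("MESH:D000003") == {"MESH:D000001", "MESH:D000002"}

    def test_empty_file_empty_hierarchy(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text("")
        assert len(parse_tree_vocab(path, "disease")) == 0

    def test_absent_explicit_parent_rejected(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(
            "# Fields:\tDiseaseName\tDiseaseID\tParentIDs\tTreeNumbers\n"
            "a\tMESH:D000001\tMESH:D999999\tC01\n"
        )
        with pytest.raises(ValidationError, match="absent parent"):
            parse_tree_vocab(path, "disease")


AOP_TSV = (
    "aop_id\tevent_id\tevent_type\tevent_title\tdownstream_events\n"
    "AOP:522\tMIE:112\tMIE\tantagonism, estrogen receptor\tKE:2207\n"
    "AOP:522\tKE:2207\tKE\tinhibition, ERK1/2\tKE:2208\n"
    "AOP:522\tKE:195\tKE\tinhibition, NMDARs\tKE:2208\n"
    "AOP:522\tKE:2208\tKE\taberrant synapses\tKE:386\n"
    "AOP:522\tKE:386\tKE\tneuronal network decrease\tAO:2209\n"
    "AOP:522\tAO:2209\tAO\tautism-like behavior\t\n"
)


class TestAopDefinitions:
    def test_bifurcated_six_event_aop(self, tmp_path):
        path = tmp_path / "aops.tsv"
        path.write_text(AOP_TSV)
        aops = load_aop_definitions(path)
        aop = aops["AOP:522"]
        assert len(aop.events) == 6
        assert len(aop.kers) == 5
        assert ("KE:195", "KE:2208") in aop.kers
        assert aop.events_of_type("AO") == {"AO:2209"}

    def test_event_shared_across_aops(self, tmp_path):
        path = tmp_path / "aops.tsv"
        path.write_text(
            AOP_TSV
            + "AOP:443\tMIE:112\tMIE\t\tAO:1982\n"
            + "AOP:443\tAO:1982\tAO\tmetastatic breast cancer\t\n"
        )
        aops = load_aop_definitions(path)
        assert "MIE:112" in aops["AOP:522"].events
        assert "MIE:112" in aops["AOP:443"].events

    def test_ker_to_undeclared_event_rejected(self, tmp_path):
        path = tmp_path / "aops.tsv"
        path.write_text(
            "aop_id\tevent_id\tevent_type\tevent_title\tdownstream_events\n"
            "AOP:1\tMIE:1\tMIE\t\tKE:99\n"
        )
        with pytest.raises(ValidationError, match="undeclared event"):
            load_aop_definitions(path)

    def test_event_typed_both_mie_and_ao_rejected(self, tmp_path):
        path = tmp_path / "aops.tsv"
        path.write_text(
            "aop_id\tevent_id\tevent_type\tevent_title\tdownstream_events\n"
            "AOP:1\tMIE:1\tMIE\t\t\n"
            "AOP:1\tMIE:1\tAO\t\t\n"
        )
        with pytest.raises(ValidationError, match="both MIE and AO"):
            load_aop_definitions(path)

    def test_component_mapping_attached_and_gaps_kept(self, tmp_path):
        aop_path = tmp_path / "aops.tsv"
        aop_path.write_text(AOP_TSV)
        comp = tmp_path / "ec.tsv"
        comp.write_text("event_id\tterm_id\nKE:2208\tGO:0045202\n")
        aops = load_aop_definitions(aop_path, comp)
        aop = aops["AOP:522"]
        assert aop.components["KE:2208"] == ["GO:0045202"]
        assert aop.components["KE:386"] == []  # unmapped but retained


class TestTetramerExport:
    def test_csv_rows_preserved(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "chemical_id,gene,phenotype_id,disease_id\n"
            "MESH:C000001,GENE:1,GO:0000001,MESH:D000001\n"
            "MESH:C000001,ESR1,GO:0000002,MESH:D000001\n"
            "MESH:C000002,2099,GO:0000001,MESH:D000001\n"
        )
        df = load_tetramer_export(path)
        assert len(df) == 3
        assert list(df["gene"]) == ["GENE:1", "ESR1", "GENE:2099"]

    def test_xlsx_with_dialect_columns(self, tmp_path):
        src = pd.DataFrame(
            {
                "Chemical ID": ["MESH:C000001"],
                "Gene Symbol": ["ESR1"],
                "Phenotype ID": ["GO:0000001"],
                "Disease ID": ["MESH:D000001"],
            }
        )
        path = tmp_path / "t.xlsx"
        src.to_excel(path, index=False)
        df = load_tetramer_export(
            path,
            {
                "Chemical ID": "chemical_id",
                "Gene Symbol": "gene",
                "Phenotype ID": "phenotype_id",
                "Disease ID": "disease_id",
            },
        )
        assert df.iloc[0]["chemical_id"] == "MESH:C000001"

    def test_empty_identifier_cell_names_row(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "chemical_id,gene,phenotype_id,disease_id\n"
            "MESH:C000001,GENE:1,GO:0000001,\n"
        )
        with pytest.raises(FormatError, match="row 1"):
            load_tetramer_export(path)

    def test_missing_identifier_column(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("chemical_id,gene,phenotype_id\nMESH:C000001,GENE:1,GO:0000001\n")
        with pytest.raises(FormatError, match="disease_id"):
            load_tetramer_export(path)


class TestSnapshotSerialisation:
    def test_round_trip_identical_records(self, tmp_path, planted_snapshot):
        out = write_snapshot(planted_snapshot, tmp_path / "snap")
        again = read_snapshot(out)
        for kind, df in planted_snapshot.relations.items():
            pd.testing.assert_frame_equal(df, again.relations[kind])
        assert again.gene_universe == planted_snapshot.gene_universe

    def test_serialisation_idempotent_byte_identical(self, tmp_path, planted_snapshot):
        a = write_snapshot(planted_snapshot, tmp_path / "a")
        b = write_snapshot(read_snapshot(a), tmp_path / "b")
        for f in sorted(p.name for p in a.iterdir()):
            assert (a / f).read_bytes() == (b / f).read_bytes(), f

    def test_validation_report_enumerates_failures(self):
        snapshot = build_snapshot(
            {"chem_gene": [("MESH:C000001", "GENE:1")]},
        )
        # corrupt: drop the gene from the universe
        snapshot.gene_universe.pop("GENE:1")
        report = snapshot.validate()
        assert list(report["id"]) == ["GENE:1"]
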