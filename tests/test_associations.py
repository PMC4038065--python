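"""Association readers, evidence filtering, id mapping and resolution."""

import io
import logging
import random

import pytest

from gosets.associations import (
    Association,
    IdMap,
    apply_id_map,
    filter_by_evidence,
    load_id_map,
    read_array_annotation,
    read_gaf,
    read_gene2go,
    resolve_associations,
)
from gosets.errors import DialectError, GosetsError
from gosets.fixtures import FixtureSpec, make_associations, make_ontology
from gosets.ontology import parse_obo

G2G_HEADER = "#tax_id\tGeneID\tGO_ID\tEvidence\tQualifier\tGO_term\tPubMed\tCategory\n"


def _g2g_row(tax, gene, term, ev="IEA", qual="-"):
    return f"{tax}\t{gene}\t{term}\t{ev}\t{qual}\tname\t-\tProcess\n"


def _gaf_row(symbol, term, ev="IDA", qual="involved_in", taxon="taxon:10090"):
    cols = ["DB", f"DB:{symbol}", symbol, qual, term, "PMID:1", ev, "", "P",
            "name", "", "protein", taxon, "20130901", "DB", "", ""]
    return "\t".join(cols) + "\n"


class TestReadGene2go:
    def test_taxon_filter(self):
        text = G2G_HEADER + "".join(
            [_g2g_row(10090, g, "GO:0000001") for g in ("1", "2", "3")]
            + [_g2g_row(9606, g, "GO:0000001") for g in ("4", "5")]
        )
        assert len(read_gene2go(io.StringIO(text), taxon=10090)) == 3

    def test_not_qualified_row_excluded(self):
        text = G2G_HEADER + _g2g_row(10090, "1", "GO:0000001") + _g2g_row(
            10090, "2", "GO:0000001", qual="NOT"
        )
        assocs = read_gene2go(io.StringIO(text), taxon=10090)
        assert [a.gene_id for a in assocs] == ["1"]

    def test_empty_stream_warns_and_returns_empty(self, caplog):
        with caplog.at_level(logging.WARNING, logger="gosets"):
            assert read_gene2go(io.StringIO(""), taxon=10090) == []
        assert "no associations" in caplog.text

    def test_short_row_skipped_with_warning(self, caplog):
        text = G2G_HEADER + "10090\t1\n" + _g2g_row(10090, "2", "GO:0000001")
        with caplog.at_level(logging.WARNING, logger="gosets"):
            assocs = read_gene2go(io.StringIO(text), taxon=10090)
        assert [a.gene_id for a in assocs] == ["2"]
        assert "skipped" in caplog.text

    def test_symbol_request_is_rejected(self):
        with pytest.raises(GosetsError, match="id map"):
            read_gene2go(io.StringIO(G2G_HEADER), taxon=1, id_choice="symbol")


class TestReadGaf:
    def test_id_choice_selects_symbol_or_object_id(self):
        text = "!gaf-version: 2.2\n" + _gaf_row("ABC1", "GO:0000001")
        by_symbol = read_gaf(io.StringIO(text), id_choice="symbol")
        by_object = read_gaf(io.StringIO(text), id_choice="object_id")
        assert by_symbol[0].gene_id == "ABC1"
        assert by_object[0].gene_id == "DB:ABC1"

    def test_not_in_compound_qualifier_excludes_row(self):
        text = (
            _gaf_row("KEEP", "GO:0000001")
            + _gaf_row("DROP", "GO:0000001", qual="NOT|contributes_to")
        )
        assocs = read_gaf(io.StringIO(text))
        assert [a.gene_id for a in assocs] == ["KEEP"]

    def test_taxon_filter_on_column_13(self):
        text = (
            _gaf_row("MOUSE", "GO:0000001", taxon="taxon:10090")
            + _gaf_row("HUMAN", "GO:0000001", taxon="taxon:9606")
        )
        assocs = read_gaf(io.StringIO(text), taxon=10090)
        assert [a.gene_id for a in assocs] == ["MOUSE"]

    def test_unparseable_taxon_dropped_only_under_filter(self, caplog):
        text = _gaf_row("ODD", "GO:0000001", taxon="not-a-taxon")
        assert len(read_gaf(io.StringIO(text))) == 1
        with caplog.at_level(logging.WARNING, logger="gosets"):
            assert read_gaf(io.StringIO(text), taxon=10090) == []
        assert "unparseable taxon" in caplog.text

    def test_short_row_skipped(self, caplog):
        text = "a\tb\tc\n" + _gaf_row("OK", "GO:0000001")
        with caplog.at_level(logging.WARNING, logger="gosets"):
            assocs = read_gaf(io.StringIO(text))
        assert [a.gene_id for a in assocs] == ["OK"]


AFFY_HEADER = (
    "#%netaffx-annotation-format\n"
    '"Probe Set ID","Gene Symbol","Gene Ontology Biological Process",'
    '"Gene Ontology Cellular Component","Gene Ontology Molecular Function"\n'
)


class TestReadArrayAnnotation:
    def test_affymetrix_cell_grammar(self):
        text = AFFY_HEADER + '"100_at","X","0007155 // cell adhesion // IEA","---","---"\n'
        assocs = read_array_annotation(io.StringIO(text), "affymetrix")
        assert assocs == [Association("100_at", "GO:0007155", "IEA")]

    def test_affymetrix_multi_entry_cell(self):
        cell = "0007155 // cell adhesion // IEA /// 0000122 // transcription // TAS"
        text = AFFY_HEADER + f'"100_at","X","{cell}","---","---"\n'
        assocs = read_array_annotation(io.StringIO(text), "affymetrix")
        assert {(a.term_id, a.evidence) for a in assocs} == {
            ("GO:0007155", "IEA"), ("GO:0000122", "TAS"),
        }

    def test_affymetrix_null_marker_and_empty_cell(self):
        text = AFFY_HEADER + '"1_at","X","---","",""\n'
        assert read_array_annotation(io.StringIO(text), "affymetrix") == []

    def test_affymetrix_missing_go_columns_is_fatal(self):
        text = '"Probe Set ID","Gene Symbol"\n"1_at","X"\n'
        with pytest.raises(DialectError, match="GO columns"):
            read_array_annotation(io.StringIO(text), "affymetrix")

    def test_affymetrix_malformed_entry_skipped_with_warning(self, caplog):
        text = AFFY_HEADER + '"1_at","X","garbage entry","---","---"\n'
        with caplog.at_level(logging.WARNING, logger="gosets"):
            assert read_array_annotation(io.StringIO(text), "affymetrix") == []
        assert "malformed" in caplog.text

    def test_agilent_grammar_with_and_without_evidence(self):
        text = (
            "ProbeID\tGO\n"
            "A_1\tGO:0007155(IEA)|GO:0000122\n"
        )
        assocs = read_array_annotation(io.StringIO(text), "agilent")
        assert {(a.term_id, a.evidence) for a in assocs} == {
            ("GO:0007155", "IEA"), ("GO:0000122", None),
        }

    def test_agilent_column_override(self):
        text = "Probe\tGoTerms\nA_1\tGO:0007155(IEA)\n"
        assocs = read_array_annotation(
            io.StringIO(text), "agilent",
            probe_column="Probe", go_columns=["GoTerms"],
        )
        assert assocs[0].term_id == "GO:0007155"

    def test_unknown_dialect_rejected(self):
        with pytest.raises(DialectError):
            read_array_annotation(io.StringIO(""), "illumina")


class TestFilterByEvidence:
    ASSOCS = [
        Association("g1", "GO:0000001", "IEA"),
        Association("g2", "GO:0000001", "TAS"),
        Association("g3", "GO:0000001", None),
    ]

    def test_keeps_only_allowed_codes(self):
        kept = filter_by_evidence(self.ASSOCS, {"TAS"})
        assert [a.gene_id for a in kept] == ["g2"]

    def test_disabled_filter_is_identity(self):
        assert filter_by_evidence(self.ASSOCS, None) == self.ASSOCS

    def test_codeless_associations_excluded_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="gosets"):
            kept = filter_by_evidence(self.ASSOCS, {"TAS", "IEA"})
        assert all(a.evidence is not None for a in kept)
        assert "no evidence code" in caplog.text

    def test_unknown_code_warns_but_filters(self, caplog):
        with caplog.at_level(logging.WARNING, logger="gosets"):
            kept = filter_by_evidence(self.ASSOCS, {"TAS", "ZZZ"})
        assert [a.gene_id for a in kept] == ["g2"]
        assert "unrecognised" in caplog.text

    def test_empty_allowlist_is_config_error(self):
        with pytest.raises(GosetsError):
            filter_by_evidence(self.ASSOCS, set())

    def test_output_independent_of_input_order(self):
        shuffled = list(self.ASSOCS)
        random.Random(0).shuffle(shuffled)
        assert set(filter_by_evidence(shuffled, {"TAS", "IEA"})) == set(
            filter_by_evidence(self.ASSOCS, {"TAS", "IEA"})
        )


class TestIdMap:
    GENES = [Association("A", "GO:0000001"), Association("B", "GO:0000001")]

    def test_keep_unmapped(self):
        out = apply_id_map(self.GENES, IdMap({"A": "X"}, "keep_unmapped"))
        assert {a.gene_id for a in out} == {"X", "B"}

    def test_drop_unmapped(self):
        out = apply_id_map(self.GENES, IdMap({"A": "X"}, "drop_unmapped"))
        assert {a.gene_id for a in out} == {"X"}

    def test_empty_map_keep_is_identity(self):
        assert apply_id_map(self.GENES, IdMap({}, "keep_unmapped")) == self.GENES

    def test_load_rejects_duplicate_source_keys(self):
        with pytest.raises(GosetsError, match="duplicate"):
            load_id_map(io.StringIO("A\tX\nA\tY\n"))

    def test_load_skips_comments_and_blank_lines(self):
        id_map = load_id_map(io.StringIO("# c\n\nA\tX\n"))
        assert id_map.mapping == {"A": "X"}

    def test_output_independent_of_input_order(self):
        id_map = IdMap({"A": "X"}, "keep_unmapped")
        shuffled = list(reversed(self.GENES))
        assert set(apply_id_map(shuffled, id_map)) == set(
            apply_id_map(self.GENES, id_map)
        )


class TestResolveAssociations:
    def test_synonym_remapped_and_counted(self, minimal_dag):
        out, counters = resolve_associations(
            [Association("g1", "GO:0000008", "IEA")], minimal_dag
        )
        assert out == [Association("g1", "GO:0000002", "IEA")]
        assert counters.synonyms_remapped == 1

    def test_obsolete_dropped_and_counted(self, minimal_dag):
        out, counters = resolve_associations(
            [Association("g1", "GO:0000003", "IEA")], minimal_dag
        )
        assert out == [] and counters.obsoletes_dropped == 1

    def test_unknown_dropped_and_counted(self, minimal_dag):
        out, counters = resolve_associations(
            [Association("g1", "GO:9999999", "IEA")], minimal_dag
        )
        assert out == [] and counters.unknown_dropped == 1

    def test_idempotent_with_zero_counters_on_second_pass(self, minimal_dag):
        assocs = [
            Association("g1", "GO:0000008", "IEA"),
            Association("g2", "GO:0000002", "TAS"),
            Association("g3", "GO:0000003", "IEA"),
        ]
        once, _ = resolve_associations(assocs, minimal_dag)
        twice, counters = resolve_associations(once, minimal_dag)
        assert twice == once
        assert counters.as_dict() == {
            "synonyms_remapped": 0, "obsoletes_dropped": 0, "unknown_dropped": 0,
        }


class TestFixtureGroundTruth:
    """The generated association files, read back through the real
    readers, reproduce the generator's ground truth exactly."""

    @pytest.mark.parametrize("dialect", ["gene2go", "gaf", "affymetrix"])
    @pytest.mark.parametrize("seed", [0, 7])
    def test_readers_and_counters_match_ground_truth(self, dialect, seed):
        spec = FixtureSpec(n_terms=40, n_genes=50, n_assocs=150, seed=seed)
        obo_text, onto_truth = make_ontology(spec)
        dag = parse_obo(io.StringIO(obo_text))
        text, truth = make_associations(spec, onto_truth, dialect)
        if dialect == "gene2go":
            assocs = read_gene2go(io.StringIO(text), taxon=10090)
        elif dialect == "gaf":
            assocs = read_gaf(io.StringIO(text), id_choice="symbol")
        else:
            assocs = read_array_annotation(io.StringIO(text), "affymetrix")
        resolved, counters = resolve_associations(assocs, dag)
        assert sorted(resolved, key=str) == sorted(truth.associations, key=str)
        assert counters.as_dict() == truth.counters.as_dict()

    def test_row_accounting_conserved_for_gene2go(self):
        """Input rows = emitted + deduplicated + NOT-excluded + decoy-taxon."""
        spec = FixtureSpec(n_terms=40, n_genes=30, n_assocs=120, seed=2)
        obo_text, onto_truth = make_ontology(spec)
        text, truth = make_associations(spec, onto_truth, "gene2go")
        data_rows = [l for l in text.splitlines() if l and not l.startswith("#")]
        emitted = read_gene2go(io.StringIO(text), taxon=10090)
        unique_keys = set()
        n_dupes = 0
        for line in data_rows:
            cols = line.split("\t")
            if cols[4] == "NOT" or int(cols[0]) != 10090:
                continue
            key = (cols[1], cols[2], cols[3])
            if key in unique_keys:
                n_dupes += 1
            unique_keys.add(key)
        assert len(data_rows) == (
            len(emitted) + n_dupes + truth.n_not_rows + truth.n_decoy_taxon_rows
        )
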