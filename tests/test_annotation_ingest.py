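import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from goconverge.annotation_ingest import (
    AnnotationTable,
    GeneAnnotation,
    parse_gbff_annotations,
    parse_mapping_export,
    read_simple,
    summarize_annotation,
    write_simple,
)
from goconverge.errors import FormatError
from goconverge.representation import count_functions, to_profile


class TestGbff:
    def test_three_gene_fixture(self, gbff_stream):
        table = parse_gbff_annotations(gbff_stream, "synth")
        assert table.method == "curated"
        assert len(table.genes) == 3
        genes = table.gene_map
        assert genes["g001"] == {"GO:0004568"}
        assert genes["g003"] == frozenset()

    def test_repeated_code_across_qualifiers_deduplicated(self, gbff_stream):
        genes = parse_gbff_annotations(gbff_stream, "synth").gene_map
        # GO:0016298 appears in /db_xref and /note of g002; kept once, and
        # the extra code embedded in the note is harvested too
        assert genes["g002"] == {"GO:0016298", "GO:0006869"}

    def test_unparseable_input_raises_format_error(self):
        with pytest.raises(FormatError):
            parse_gbff_annotations(io.StringIO("FEATURES but no LOCUS\n"), "x")


class TestMappingExport:
    def test_two_token_row(self):
        table = parse_mapping_export(
            io.StringIO("orf_00017\tGO:0016298; GO:0006869\n"), "tx"
        )
        assert table.method == "mapped"
        assert table.gene_map["orf_00017"] == {"GO:0016298", "GO:0006869"}

    def test_duplicate_rows_merge_by_union(self):
        text = "orf_0002\tGO:0000001\norf_0002\tGO:0000002\n"
        table = parse_mapping_export(io.StringIO(text), "tx")
        assert table.gene_map["orf_0002"] == {"GO:0000001", "GO:0000002"}

    def test_five_row_fixture_with_codeless_row(self):
        text = (
            "a\tGO:0000001\nb\tGO:0000002\nc\tGO:0000003\nd\tGO:0000004\ne\t\n"
        )
        table = parse_mapping_export(io.StringIO(text), "tx")
        assert len(table.genes) == 5
        assert sum(1 for g in table.genes if g.codes) == 4

    def test_missing_identifier_raises(self):
        with pytest.raises(FormatError, match="line 1"):
            parse_mapping_export(io.StringIO("\tGO:0000001\n"), "tx")


gene_ids = st.text(
    alphabet=st.characters(whitelist_categories=("Ll", "Lu", "Nd"), whitelist_characters="_-."),
    min_size=1,
    max_size=12,
)
go_codes = st.integers(min_value=0, max_value=9_999_999).map(lambda n: f"GO:{n:07d}")
tables = st.builds(
    lambda ids, codesets, method: AnnotationTable(
        taxon_id="hyp",
        method=method,
        genes=[GeneAnnotation(g, frozenset(c)) for g, c in zip(ids, codesets)],
    ),
    st.lists(gene_ids, max_size=25, unique=True),
    st.lists(st.frozensets(go_codes, max_size=5), min_size=25, max_size=25),
    st.sampled_from(["curated", "mapped"]),
)


class TestSimpleFormat:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(table=tables)
    def test_round_trip_identity(self, table):
        again = read_simple(io.StringIO(write_simple(table)))
        assert again.taxon_id == table.taxon_id
        assert again.method == table.method
        assert again.gene_map == table.gene_map

    def test_empty_table_round_trips(self):
        table = AnnotationTable(taxon_id="t", method="curated", genes=[])
        assert read_simple(io.StringIO(write_simple(table))).genes == []

    def test_single_line_parse(self):
        table = read_simple(io.StringIO("#taxon=t method=curated\ng1\tGO:0005884\n"))
        assert table.gene_map == {"g1": frozenset({"GO:0005884"})}

    def test_malformed_line_reports_line_number(self):
        text = "#taxon=t method=curated\ng1\tGO:0005884\tsurplus\n"
        with pytest.raises(FormatError, match="line 2"):
            read_simple(io.StringIO(text))

    def test_n_total_predicted_preserved(self):
        table = AnnotationTable(
            taxon_id="t", method="mapped", genes=[], n_total_predicted=123
        )
        assert read_simple(io.StringIO(write_simple(table))).n_total_predicted == 123


class TestSummarize:
    def test_fixture_counts(self):
        codes = [
            {"GO:0000001", "GO:0000002"},
            {"GO:0000001"},
            set(),
            {"GO:0000003"},
        ]
        table = AnnotationTable(
            taxon_id="t",
            method="curated",
            genes=[GeneAnnotation(f"g{i}", frozenset(c)) for i, c in enumerate(codes)],
        )
        s = summarize_annotation(table)
        assert (s.n_genes, s.n_with_go, s.go_hits, s.unique_gos) == (4, 3, 4, 3)
        assert s.pct_results == pytest.approx(75.0)

    def test_empty_and_codeless_tables(self):
        empty = summarize_annotation(AnnotationTable(taxon_id="t", method="curated", genes=[]))
        assert (empty.n_genes, empty.pct_results, empty.go_hits) == (0, 0.0, 0)
        codeless = AnnotationTable(
            taxon_id="t",
            method="curated",
            genes=[GeneAnnotation(f"g{i}") for i in range(5)],
        )
        s = summarize_annotation(codeless)
        assert (s.pct_results, s.go_hits, s.unique_gos) == (0.0, 0, 0)

    def test_permutation_invariance(self, ten_gene_table):
        reversed_table = AnnotationTable(
            taxon_id="toy", method="curated", genes=list(reversed(ten_gene_table.genes))
        )
        assert summarize_annotation(ten_gene_table) == summarize_annotation(reversed_table)


def test_equivalent_content_differs_only_in_method_tag(ref):
    """The same gene->code map ingested via the two routes produces identical
    representation profiles up to the method tag."""
    mapping_text = "g1\tGO:0016298\ng2\tGO:0016298; GO:0006869\ng3\tGO:8000001\n"
    mapped = parse_mapping_export(io.StringIO(mapping_text), "tx")
    curated = AnnotationTable(
        taxon_id="tx", method="curated", genes=list(mapped.genes)
    )
    prof_m = to_profile(count_functions(mapped, ref), "control")
    prof_c = to_profile(count_functions(curated, ref), "control")
    assert prof_m.per_mille == prof_c.per_mille
    assert prof_m.method == "mapped" and prof_c.method == "curated"
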