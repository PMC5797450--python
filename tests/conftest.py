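import io
import textwrap

import pytest

from goconverge.annotation_ingest import AnnotationTable, GeneAnnotation
from goconverge.reference_set import default_reference_set


@pytest.fixture(scope="session")
def ref():
    return default_reference_set()


def _origin_block(seq: str) -> str:
    lines = []
    for start in range(0, len(seq), 60):
        chunk = seq[start : start + 60]
        groups = " ".join(chunk[i : i + 10] for i in range(0, len(chunk), 10))
        lines.append(f"{start + 1:>9} {groups}")
    return "\n".join(lines)


@pytest.fixture(scope="session")
def gbff_text():
    """Three-gene GenBank record: two genes with GO codes (one of them with a
    repeated code across qualifiers), one gene without any."""
    seq = "atgc" * 90  # 360 bp
    head = textwrap.dedent(
        """\
        LOCUS       SYNTH01                  360 bp    DNA     linear   PLN 01-JAN-2000
        DEFINITION  Synthetic three-gene record for parser tests.
        ACCESSION   SYNTH01
        VERSION     SYNTH01.1
        KEYWORDS    .
        SOURCE      synthetic construct
          ORGANISM  synthetic construct
                    Unclassified.
        FEATURES             Location/Qualifiers
             source          1..360
                             /organism="synthetic construct"
             gene            1..120
                             /locus_tag="g001"
             CDS             1..120
                             /locus_tag="g001"
                             /db_xref="GO:0004568"
             gene            121..240
                             /locus_tag="g002"
             CDS             121..240
                             /locus_tag="g002"
                             /db_xref="GO:0016298"
                             /note="lipase-like; GO:0016298 repeated, also GO:0006869"
             gene            241..360
                             /locus_tag="g003"
        ORIGIN
        """
    )
    return head + _origin_block(seq) + "\n//\n"


@pytest.fixture()
def gbff_stream(gbff_text):
    return io.StringIO(gbff_text)


@pytest.fixture()
def ten_gene_table():
    """Hand-built table: two genes carry the lipase code GO:0016298, one of
    which also carries the lipid-transport code GO:0006869; seven other genes
    have filler codes and one gene has none."""
    genes = [
        GeneAnnotation("g01", frozenset({"GO:0016298"})),
        GeneAnnotation("g02", frozenset({"GO:0016298", "GO:0006869"})),
        GeneAnnotation("g03", frozenset({"GO:8000001"})),
        GeneAnnotation("g04", frozenset({"GO:8000002"})),
        GeneAnnotation("g05", frozenset({"GO:8000003"})),
        GeneAnnotation("g06", frozenset({"GO:8000004"})),
        GeneAnnotation("g07", frozenset({"GO:8000005"})),
        GeneAnnotation("g08", frozenset({"GO:8000006"})),
        GeneAnnotation("g09", frozenset({"GO:8000007"})),
        GeneAnnotation("g10", frozenset()),
    ]
    return AnnotationTable(taxon_id="toy", method="curated", genes=genes)
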