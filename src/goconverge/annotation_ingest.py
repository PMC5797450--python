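"""Ingest per-taxon gene -> GO annotation tables.

Two upstream routes feed the pipeline:

* **curated** — genomes deposited with GO-coded annotations; gene/CDS
  features are harvested from GenBank flat files (GBFF).
* **mapped** — genomes annotated by sequence similarity, arriving as a
  tabular export of sequence name -> GO code list.

Both converge on the same simplified text format, one gene per line, which
every downstream stage consumes. GO codes are recognized by token
(``GO:`` + 7 digits) wherever they appear in a qualifier or cell, which is
robust to the many submitter-specific GenBank dialects (``/db_xref``,
``/GO_function``, ``/GO_process``, ``/GO_component``, free notes).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from Bio import SeqIO

from .errors import FormatError
from .reference_set import extract_go_codes, normalize_go_code

METHODS = ("curated", "mapped")

__all__ = [
    "GeneAnnotation",
    "AnnotationTable",
    "AnnotationSummary",
    "parse_gbff_annotations",
    "parse_mapping_export",
    "read_simple",
    "write_simple",
    "summarize_annotation",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene and its (possibly empty) set of GO codes."""

    gene_id: str
    codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise FormatError("gene_id must be non-empty")


@dataclass
class AnnotationTable:
    """All gene annotations for one taxon, tagged with the annotation route.

    ``n_total_predicted`` optionally records the number of putative genes
    before GO filtering, so that summary reports can show the fraction of
    genes that received any functional assignment.
    """

    taxon_id: str
    method: str
    genes: list[GeneAnnotation] = field(default_factory=list)
    n_total_predicted: Optional[int] = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise FormatError(f"method must be one of {METHODS}, got {self.method!r}")
        seen: set[str] = set()
        for gene in self.genes:
            if gene.gene_id in seen:
                raise FormatError(f"duplicate gene_id {gene.gene_id!r} in {self.taxon_id}")
            seen.add(gene.gene_id)

    @property
    def gene_map(self) -> dict[str, frozenset[str]]:
        return {g.gene_id: g.codes for g in self.genes}


def _merge(genes: dict[str, set[str]], gene_id: str, codes: set[str]) -> None:
    genes.setdefault(gene_id, set()).update(codes)


def parse_gbff_annotations(
    source: Union[str, Path, io.TextIOBase], taxon_id: str
) -> AnnotationTable:
    """Harvest gene -> GO assignments from a GenBank flat file.

    Every gene/CDS feature contributes one gene; its codes are all GO tokens
    found in any qualifier value. Features without GO tokens are retained
    with empty code sets. Features sharing a gene identifier (e.g. a gene
    and its CDS) are merged by code-set union.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            return parse_gbff_annotations(handle, taxon_id)
    text = source.read()
    genes: dict[str, set[str]] = {}
    try:
        records = list(SeqIO.parse(io.StringIO(text), "genbank"))
    except Exception as exc:  # biopython raises bare ValueError on bad records
        raise FormatError(f"unparseable GBFF for {taxon_id}: {exc}") from exc
    if not records and text.strip():
        raise FormatError(f"no GenBank records found in input for {taxon_id}")
    for record in records:
        anon = 0
        for feature in record.features:
            if feature.type not in ("gene", "CDS"):
                continue
            quals = feature.qualifiers
            gene_id = None
            for key in ("locus_tag", "gene", "protein_id"):
                if key in quals and quals[key]:
                    gene_id = quals[key][0]
                    break
            if gene_id is None:
                anon += 1
                gene_id = f"{record.id}:feature{anon}"
            codes: set[str] = set()
            for values in quals.values():
                for value in values:
                    codes |= extract_go_codes(str(value))
            _merge(genes, gene_id, codes)
    return AnnotationTable(
        taxon_id=taxon_id,
        method="curated",
        genes=[GeneAnnotation(g, frozenset(c)) for g, c in genes.items()],
    )


def parse_mapping_export(
    source: Union[str, Path, io.TextIOBase], taxon_id: str
) -> AnnotationTable:
    """Parse a similarity-mapping export: sequence name, then GO codes.

    Each row is a sequence identifier followed by zero or more GO tokens
    (any separator). Rows repeating an identifier are merged by union; rows
    without GO tokens yield genes with empty code sets.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            return parse_mapping_export(handle, taxon_id)
    genes: dict[str, set[str]] = {}
    for lineno, line in enumerate(source, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t", 1)
        gene_id = parts[0].strip()
        if not gene_id:
            raise FormatError(f"mapping export line {lineno}: missing sequence identifier")
        rest = parts[1] if len(parts) > 1 else ""
        _merge(genes, gene_id, extract_go_codes(rest))
    return AnnotationTable(
        taxon_id=taxon_id,
        method="mapped",
        genes=[GeneAnnotation(g, frozenset(c)) for g, c in genes.items()],
    )


def write_simple(table: AnnotationTable, target: Union[str, Path, io.TextIOBase, None] = None) -> str:
    """Serialize to the simplified annotation dialect.

    Header line ``#taxon=<id> method=<curated|mapped> [n_total_predicted=<n>]``,
    then one ``gene_id<TAB>code;code;...`` line per gene (codes sorted, empty
    field allowed). Returns the text; also writes it if a target is given.
    """
    lines = [
        "#taxon=%s method=%s%s"
        % (
            table.taxon_id,
            table.method,
            "" if table.n_total_predicted is None else f" n_total_predicted={table.n_total_predicted}",
        )
    ]
    for gene in sorted(table.genes, key=lambda g: g.gene_id):
        lines.append(f"{gene.gene_id}\t{';'.join(sorted(gene.codes))}")
    text = "\n".join(lines) + "\n"
    if isinstance(target, (str, Path)):
        Path(target).write_text(text, encoding="utf-8")
    elif target is not None:
        target.write(text)
    return text


def read_simple(source: Union[str, Path, io.TextIOBase]) -> AnnotationTable:
    """Read the simplified dialect written by :func:`write_simple`."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            return read_simple(handle)
    header = source.readline().rstrip("\n")
    if not header.startswith("#taxon="):
        raise FormatError(f"simple format line 1: expected '#taxon=...' header, got {header!r}")
    fields = dict(part.split("=", 1) for part in header[1:].split() if "=" in part)
    taxon_id = fields.get("taxon", "")
    method = fields.get("method", "")
    n_total = int(fields["n_total_predicted"]) if "n_total_predicted" in fields else None
    genes: list[GeneAnnotation] = []
    for lineno, line in enumerate(source, start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) > 2:
            raise FormatError(f"simple format line {lineno}: expected 'gene<TAB>codes'")
        gene_id = parts[0]
        cell = parts[1] if len(parts) == 2 else ""
        codes = set()
        for tok in cell.split(";"):
            if tok.strip():
                try:
                    codes.add(normalize_go_code(tok))
                except FormatError as exc:
                    raise FormatError(f"simple format line {lineno}: {exc}") from exc
        genes.append(GeneAnnotation(gene_id, frozenset(codes)))
    return AnnotationTable(
        taxon_id=taxon_id, method=method, genes=genes, n_total_predicted=n_total
    )


@dataclass(frozen=True)
class AnnotationSummary:
    """Genome-annotation overview: gene counts, assignment rate, GO tallies."""

    taxon_id: str
    method: str
    n_genes: int
    n_with_go: int
    pct_results: float  # % of genes with >=1 GO code
    go_hits: int  # sum of code-set sizes
    unique_gos: int  # size of the union of code sets
    n_total_predicted: Optional[int] = None


def summarize_annotation(table: AnnotationTable) -> AnnotationSummary:
    n_genes = len(table.genes)
    n_with = sum(1 for g in table.genes if g.codes)
    hits = sum(len(g.codes) for g in table.genes)
    unique: set[str] = set()
    for gene in table.genes:
        unique |= gene.codes
    pct = 100.0 * n_with / n_genes if n_genes else 0.0
    return AnnotationSummary(
        taxon_id=table.taxon_id,
        method=table.method,
        n_genes=n_genes,
        n_with_go=n_with,
        pct_results=pct,
        go_hits=hits,
        unique_gos=len(unique),
        n_total_predicted=table.n_total_predicted,
    )
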