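"""Score a taxon's annotations against the carnivory-function reference set.

The representation of a function in a genome is expressed in genes per
thousand: the number of genes carrying at least one of the function's GO
codes, divided by the number of genes that received *any* functional
assignment, times 1000. A gene matching several reference entries counts
once toward each, and the carnivory total is the sum of the per-function
values — the convention under which the total can be recomputed from
adjusted per-function values and decomposed additively into shares.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from .annotation_ingest import AnnotationTable
from .errors import DataError, FormatError
from .reference_set import ReferenceSet

CLASS_LABELS = ("carnivorous", "control")

__all__ = [
    "FunctionCounts",
    "RepresentationProfile",
    "count_functions",
    "to_profile",
    "function_shares",
    "write_profile_table",
    "read_profile_table",
]


@dataclass(frozen=True)
class FunctionCounts:
    """Per-function gene counts for one taxon, keyed by abbreviation."""

    taxon_id: str
    method: str
    per_function: dict[str, int]
    n_assigned: int  # genes with >=1 GO code of any kind

    def __post_init__(self) -> None:
        for abbrev, count in self.per_function.items():
            if count < 0 or count > self.n_assigned:
                raise DataError(
                    f"{self.taxon_id}/{abbrev}: count {count} outside [0, {self.n_assigned}]"
                )


@dataclass(frozen=True)
class RepresentationProfile:
    """Genes-per-thousand representation of each reference function.

    For profiles built by :func:`to_profile`, ``total_per_mille`` is the sum
    of the per-function values. Profiles loaded from a deposited table keep
    the file's own Total column, which may reflect rounding or a larger
    function set than the columns present.
    """

    taxon_id: str
    method: str
    class_label: str
    per_mille: dict[str, float]
    total_per_mille: float
    adjusted: bool = False

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise FormatError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )
        for abbrev, value in self.per_mille.items():
            if not 0.0 <= value <= 1000.0:
                raise DataError(f"{self.taxon_id}/{abbrev}: per-mille {value} outside [0, 1000]")

    def value_of(self, criterion: str) -> float:
        """Per-mille value of a function abbreviation, or of "Total"."""
        if criterion == "Total":
            return self.total_per_mille
        return self.per_mille[criterion]


def count_functions(table: AnnotationTable, ref: ReferenceSet) -> FunctionCounts:
    """Count genes hitting each reference entry (a gene counts at most once
    per entry but may count in several entries)."""
    counts = {entry.abbreviation: 0 for entry in ref}
    n_assigned = 0
    for gene in table.genes:
        if not gene.codes:
            continue
        n_assigned += 1
        for entry in ref:
            if entry.matches(gene.codes):
                counts[entry.abbreviation] += 1
    return FunctionCounts(
        taxon_id=table.taxon_id,
        method=table.method,
        per_function=counts,
        n_assigned=n_assigned,
    )


def to_profile(counts: FunctionCounts, class_label: str) -> RepresentationProfile:
    """Convert counts to genes-per-thousand proportions."""
    if counts.n_assigned == 0:
        raise DataError(
            f"{counts.taxon_id}: no gene received a functional assignment; "
            "representation profile undefined"
        )
    per_mille = {
        abbrev: 1000.0 * n / counts.n_assigned for abbrev, n in counts.per_function.items()
    }
    return RepresentationProfile(
        taxon_id=counts.taxon_id,
        method=counts.method,
        class_label=class_label,
        per_mille=per_mille,
        total_per_mille=sum(per_mille.values()),
        adjusted=False,
    )


def function_shares(profile: RepresentationProfile) -> dict[str, float]:
    """Each function's fraction of the carnivory total (shares sum to 1)."""
    total = sum(profile.per_mille.values())
    if total <= 0.0:
        raise DataError(f"{profile.taxon_id}: carnivory total is zero; shares undefined")
    return {abbrev: value / total for abbrev, value in profile.per_mille.items()}


def write_profile_table(
    profiles: list[RepresentationProfile],
    target: Union[str, Path, io.TextIOBase, None] = None,
    columns: Optional[list[str]] = None,
    decimals: Optional[int] = None,
) -> str:
    """Write profiles as TSV: one row per taxon, one column per function
    abbreviation, plus "Total", "Class", "Method" and "Adjusted".

    ``decimals`` rounds at report time only; internal values stay full
    precision.
    """
    if not profiles:
        raise DataError("no profiles to write")
    if columns is None:
        columns = list(profiles[0].per_mille)
    def fmt(x: float) -> str:
        return repr(float(x)) if decimals is None else f"{x:.{decimals}f}"

    lines = ["Taxon\t" + "\t".join(columns) + "\tTotal\tClass\tMethod\tAdjusted"]
    for prof in profiles:
        cells = [prof.taxon_id]
        cells += [fmt(prof.per_mille[c]) for c in columns]
        cells.append(fmt(prof.total_per_mille))
        cells += [prof.class_label, prof.method, "yes" if prof.adjusted else "no"]
        lines.append("\t".join(cells))
    text = "\n".join(lines) + "\n"
    if isinstance(target, (str, Path)):
        Path(target).write_text(text, encoding="utf-8")
    elif target is not None:
        target.write(text)
    return text


def read_profile_table(
    source: Union[str, Path, io.TextIOBase], ref: Optional[ReferenceSet] = None
) -> list[RepresentationProfile]:
    """Read a per-taxon profile TSV (the layout written by
    :func:`write_profile_table`, or a deposited table with a subset of
    function columns).

    Columns other than Taxon/Total/Class/Method/Adjusted must resolve to
    reference abbreviations when a reference set is supplied. The Total
    column is kept as read. Missing Method defaults to "curated"; missing
    Adjusted defaults to adjusted=True (deposited tables hold the values
    used for testing).
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            return read_profile_table(handle, ref)
    header = source.readline().rstrip("\n")
    if not header:
        raise FormatError("empty profile table")
    cols = header.split("\t")
    if cols[0] != "Taxon":
        raise FormatError(f"profile table must start with a 'Taxon' column, got {cols[0]!r}")
    special = {"Taxon", "Total", "Class", "Method", "Adjusted"}
    func_cols = [c for c in cols[1:] if c not in special]
    if ref is not None:
        known = set(ref.abbreviations)
        unknown = [c for c in func_cols if c not in known]
        if unknown:
            raise FormatError(f"unknown function column(s): {', '.join(unknown)}")
    if "Class" not in cols or "Total" not in cols:
        raise FormatError("profile table requires 'Total' and 'Class' columns")
    idx = {c: i for i, c in enumerate(cols)}
    profiles: list[RepresentationProfile] = []
    for lineno, line in enumerate(source, start=2):
        if not line.strip():
            continue
        cells = line.rstrip("\n").split("\t")
        if len(cells) != len(cols):
            raise FormatError(f"profile table line {lineno}: expected {len(cols)} cells")
        try:
            per_mille = {c: float(cells[idx[c]]) for c in func_cols}
            total = float(cells[idx["Total"]])
        except ValueError as exc:
            raise FormatError(f"profile table line {lineno}: {exc}") from exc
        profiles.append(
            RepresentationProfile(
                taxon_id=cells[idx["Taxon"]],
                method=cells[idx["Method"]] if "Method" in idx else "curated",
                class_label=cells[idx["Class"]],
                per_mille=per_mille,
                total_per_mille=total,
                adjusted=(cells[idx["Adjusted"]] == "yes") if "Adjusted" in idx else True,
            )
        )
    return profiles
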