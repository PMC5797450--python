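"""The literature-derived reference set of carnivory-associated functions.

Each entry pairs a named molecular function implicated in plant carnivory
(digestive enzymes, nutrient transporters, trap-related activities) with one
or more Gene Ontology codes. Entries carrying several codes treat them as
aliases: the alternates are equivalent to, or deprecated ancestors of, the
best-matching current term, and a gene matching *any* of them counts for the
entry. Matching is by literal code only — no ontology-graph propagation.

The packaged fixture (``data/carnivory_reference.tsv``) holds the 36 curated
entries (39 codes in total) used throughout the pipeline, including the short
abbreviations under which functions appear in report tables.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional, Union

from .errors import FormatError

GO_CODE_PATTERN = re.compile(r"GO:\d{7}", re.IGNORECASE)

__all__ = [
    "GO_CODE_PATTERN",
    "normalize_go_code",
    "extract_go_codes",
    "FunctionEntry",
    "ReferenceSet",
    "load_reference_set",
    "write_reference_set",
    "default_reference_set",
]


def normalize_go_code(token: str) -> str:
    """Validate and canonicalize a GO code ("go:0005884" -> "GO:0005884")."""
    token = token.strip()
    if not GO_CODE_PATTERN.fullmatch(token):
        raise FormatError(f"not a valid GO code: {token!r}")
    return "GO:" + token[3:]


def extract_go_codes(text: str) -> set[str]:
    """All GO codes embedded anywhere in ``text``, canonicalized."""
    return {"GO:" + m.group(0)[3:] for m in GO_CODE_PATTERN.finditer(text)}


@dataclass(frozen=True)
class FunctionEntry:
    """One carnivory-associated function and its GO code aliases."""

    label: str
    abbreviation: str
    codes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.label:
            raise FormatError("function label must be non-empty")
        if not self.abbreviation:
            raise FormatError(f"entry {self.label!r}: abbreviation must be non-empty")
        if not self.codes:
            raise FormatError(f"entry {self.label!r}: needs at least one GO code")

    def matches(self, codes: set[str] | frozenset[str]) -> bool:
        """Does a gene's code set hit any alias of this entry?"""
        return not self.codes.isdisjoint(codes)


@dataclass(frozen=True)
class ReferenceSet:
    """Ordered collection of function entries with unique labels, abbreviations
    and globally unique GO codes."""

    entries: tuple[FunctionEntry, ...]
    _by_code: dict[str, FunctionEntry] = field(
        init=False, repr=False, compare=False, hash=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        by_code: dict[str, FunctionEntry] = {}
        labels: set[str] = set()
        abbrevs: set[str] = set()
        for entry in self.entries:
            if entry.label in labels:
                raise FormatError(f"duplicate function label: {entry.label!r}")
            if entry.abbreviation in abbrevs:
                raise FormatError(f"duplicate abbreviation: {entry.abbreviation!r}")
            labels.add(entry.label)
            abbrevs.add(entry.abbreviation)
            for code in entry.codes:
                if code in by_code:
                    raise FormatError(
                        f"GO code {code} appears in both {by_code[code].label!r} "
                        f"and {entry.label!r}"
                    )
                by_code[code] = entry
        object.__setattr__(self, "_by_code", by_code)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[FunctionEntry]:
        return iter(self.entries)

    @property
    def n_codes(self) -> int:
        return len(self._by_code)

    @property
    def abbreviations(self) -> tuple[str, ...]:
        return tuple(e.abbreviation for e in self.entries)

    def function_of(self, code: str) -> Optional[FunctionEntry]:
        """The unique entry listing ``code`` as an alias, or None."""
        return self._by_code.get(normalize_go_code(code))

    def by_abbreviation(self, abbreviation: str) -> FunctionEntry:
        for entry in self.entries:
            if entry.abbreviation == abbreviation:
                return entry
        raise KeyError(abbreviation)


def load_reference_set(source: Union[str, Path, io.TextIOBase]) -> ReferenceSet:
    """Read a reference set from tab-separated text.

    Expected header: ``label<TAB>abbreviation<TAB>codes`` with codes
    ";"-separated. Duplicate codes across rows are rejected.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            return load_reference_set(handle)
    entries: list[FunctionEntry] = []
    header = source.readline()
    if header and header.strip() and header.strip().split("\t")[0] != "label":
        raise FormatError(f"unexpected reference header: {header.strip()!r}")
    for lineno, line in enumerate(source, start=2):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise FormatError(f"reference row {lineno}: expected 3 columns, got {len(parts)}")
        label, abbreviation, code_cell = (p.strip() for p in parts)
        try:
            codes = frozenset(
                normalize_go_code(tok) for tok in code_cell.split(";") if tok.strip()
            )
            entry = FunctionEntry(label=label, abbreviation=abbreviation, codes=codes)
        except FormatError as exc:
            raise FormatError(f"reference row {lineno}: {exc}") from exc
        entries.append(entry)
    return ReferenceSet(entries=tuple(entries))


def write_reference_set(ref: ReferenceSet, target: Union[str, Path, io.TextIOBase]) -> None:
    """Serialize in the same three-column dialect ``load_reference_set`` reads."""
    if isinstance(target, (str, Path)):
        with open(target, "w", encoding="utf-8") as handle:
            write_reference_set(ref, handle)
        return
    target.write("label\tabbreviation\tcodes\n")
    for entry in ref:
        codes = ";".join(sorted(entry.codes))
        target.write(f"{entry.label}\t{entry.abbreviation}\t{codes}\n")


def default_reference_set() -> ReferenceSet:
    """The packaged 36-entry carnivory-associated function set."""
    text = resources.files("goconverge.data").joinpath("carnivory_reference.tsv").read_text(
        encoding="utf-8"
    )
    return load_reference_set(io.StringIO(text))
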