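"""Cross-method calibration of representation profiles.

Similarity-based ("mapped") annotation detects some functions more or less
readily than curated GenBank annotation. A single calibration taxon
annotated by *both* routes yields per-function adjustment factors — the
quotient of the curated and mapped per-mille values — which are multiplied
into every mapped-method profile. Functions where either route detected
zero genes have no defined quotient ("nullset"); they are flagged and their
values pass through unadjusted (or are zeroed, by configuration), with
exclusion deferred to the testing stage. The carnivory total is recomputed
from the adjusted per-function values.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

from .errors import DataError, FormatError
from .representation import RepresentationProfile

__all__ = [
    "AdjustmentFactors",
    "compute_adjustment",
    "apply_adjustment",
    "write_factor_table",
    "read_factor_table",
]


@dataclass(frozen=True)
class AdjustmentFactors:
    """Per-function curated/mapped calibration multipliers.

    ``factor`` holds the defined (positive) multipliers keyed by function
    abbreviation; ``undefined_set`` lists the nullset functions, for which
    one or both methods detected zero genes.
    """

    calibration_taxon: str
    factor: dict[str, float]
    undefined_set: frozenset[str]

    def __post_init__(self) -> None:
        overlap = set(self.factor) & self.undefined_set
        if overlap:
            raise DataError(f"functions both defined and nullset: {sorted(overlap)}")
        bad = {k: v for k, v in self.factor.items() if not v > 0}
        if bad:
            raise DataError(f"non-positive adjustment factors: {bad}")

    def is_defined(self, abbreviation: str) -> bool:
        return abbreviation in self.factor


def compute_adjustment(
    curated: RepresentationProfile, mapped: RepresentationProfile
) -> AdjustmentFactors:
    """Factors from a dual-annotated calibration taxon: curated / mapped
    per-mille, per function; nullset where either value is zero."""
    if curated.taxon_id != mapped.taxon_id:
        raise DataError(
            f"calibration requires one taxon annotated both ways, got "
            f"{curated.taxon_id!r} and {mapped.taxon_id!r}"
        )
    if curated.method != "curated" or mapped.method != "mapped":
        raise DataError("compute_adjustment expects (curated, mapped) profiles in that order")
    if set(curated.per_mille) != set(mapped.per_mille):
        raise DataError("calibration profiles cover different function sets")
    factor: dict[str, float] = {}
    undefined: set[str] = set()
    for abbrev, cur in curated.per_mille.items():
        map_val = mapped.per_mille[abbrev]
        if cur > 0 and map_val > 0:
            factor[abbrev] = cur / map_val
        else:
            undefined.add(abbrev)
    return AdjustmentFactors(
        calibration_taxon=curated.taxon_id,
        factor=factor,
        undefined_set=frozenset(undefined),
    )


def apply_adjustment(
    profile: RepresentationProfile,
    factors: AdjustmentFactors,
    undefined_policy: str = "passthrough",
) -> RepresentationProfile:
    """Apply calibration to one profile.

    Curated profiles need no correction and are returned with only the
    adjusted flag set. Mapped profiles are multiplied function-wise by the
    defined factors; nullset functions pass through unchanged
    (``undefined_policy="passthrough"``) or are zeroed (``"zero"``). The
    total is recomputed as the sum of post-adjustment values.
    """
    if profile.adjusted:
        raise DataError(f"{profile.taxon_id}: profile is already adjusted")
    if undefined_policy not in ("passthrough", "zero"):
        raise DataError(f"unknown undefined_policy {undefined_policy!r}")
    if profile.method == "curated":
        return replace(profile, adjusted=True)
    per_mille = {}
    for abbrev, value in profile.per_mille.items():
        if factors.is_defined(abbrev):
            per_mille[abbrev] = value * factors.factor[abbrev]
        elif undefined_policy == "zero" and abbrev in factors.undefined_set:
            per_mille[abbrev] = 0.0
        else:
            per_mille[abbrev] = value
    return replace(
        profile,
        per_mille=per_mille,
        total_per_mille=sum(per_mille.values()),
        adjusted=True,
    )


def write_factor_table(
    factors: AdjustmentFactors, target: Union[str, Path, io.TextIOBase, None] = None
) -> str:
    """TSV with one row per function: abbreviation, factor (or NA), defined flag."""
    lines = [f"#calibration_taxon={factors.calibration_taxon}", "function\tfactor\tdefined"]
    for abbrev in sorted(set(factors.factor) | set(factors.undefined_set)):
        if factors.is_defined(abbrev):
            lines.append(f"{abbrev}\t{factors.factor[abbrev]!r}\tyes")
        else:
            lines.append(f"{abbrev}\tNA\tno")
    text = "\n".join(lines) + "\n"
    if isinstance(target, (str, Path)):
        Path(target).write_text(text, encoding="utf-8")
    elif target is not None:
        target.write(text)
    return text


def read_factor_table(source: Union[str, Path, io.TextIOBase]) -> AdjustmentFactors:
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            return read_factor_table(handle)
    first = source.readline().strip()
    if not first.startswith("#calibration_taxon="):
        raise FormatError("factor table must start with '#calibration_taxon=<id>'")
    taxon = first.split("=", 1)[1]
    header = source.readline().strip()
    if header != "function\tfactor\tdefined":
        raise FormatError(f"unexpected factor table header: {header!r}")
    factor: dict[str, float] = {}
    undefined: set[str] = set()
    for lineno, line in enumerate(source, start=3):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise FormatError(f"factor table line {lineno}: expected 3 columns")
        abbrev, value, defined = parts
        if defined == "yes":
            factor[abbrev] = float(value)
        else:
            undefined.add(abbrev)
    return AdjustmentFactors(
        calibration_taxon=taxon, factor=factor, undefined_set=frozenset(undefined)
    )
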