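"""End-to-end orchestration: ingest -> score -> calibrate -> test -> report.

A run is driven by a taxon manifest (taxon id, carnivorous/control class,
annotation method, input path, calibration flag) plus options. When a
calibration taxon with both annotation routes is present, both the adjusted
and the raw analyses are produced along with a change summary; otherwise the
pipeline warns and runs raw-only. Reproduction mode skips ingestion and
scoring entirely and consumes a deposited per-taxon profile table.

The run is a pure function of its inputs: identical manifests, options and
files give identical outputs, and every silent choice (excluded functions,
nullset events, pi0 estimates) is recorded in the result log.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from . import calibration as cal
from . import convergence_stats as cs
from .annotation_ingest import AnnotationTable, read_simple
from .errors import ConfigError, FormatError
from .reference_set import ReferenceSet, default_reference_set
from .representation import (
    RepresentationProfile,
    count_functions,
    read_profile_table,
    to_profile,
)

__all__ = [
    "ManifestRow",
    "TaxonManifest",
    "PipelineOptions",
    "PipelineResult",
    "load_profile_table",
    "run_pipeline",
    "run_reproduction",
]


@dataclass(frozen=True)
class ManifestRow:
    taxon_id: str
    class_label: str  # carnivorous | control
    method: str  # curated | mapped
    path: str
    is_calibration: bool = False


@dataclass
class TaxonManifest:
    """Validated list of taxa entering a run.

    At most one calibration taxon; it must appear twice (once per method).
    Testing requires at least two taxa per class.
    """

    rows: list[ManifestRow]

    def __post_init__(self) -> None:
        cal_taxa = {r.taxon_id for r in self.rows if r.is_calibration}
        if len(cal_taxa) > 1:
            raise ConfigError(f"at most one calibration taxon allowed, got {sorted(cal_taxa)}")
        if cal_taxa:
            (taxon,) = cal_taxa
            methods = {r.method for r in self.rows if r.taxon_id == taxon}
            if methods != {"curated", "mapped"}:
                raise ConfigError(
                    f"calibration taxon {taxon!r} needs both curated and mapped inputs"
                )
        study = [(r.taxon_id, r.method) for r in self.rows]
        if len(set(study)) != len(study):
            raise ConfigError("duplicate (taxon, method) rows in manifest")
        for label in ("carnivorous", "control"):
            n = len({r.taxon_id for r in self.rows if r.class_label == label})
            if n < 2:
                raise ConfigError(f"need >=2 {label} taxa for testing, got {n}")

    @property
    def calibration_taxon(self) -> Optional[str]:
        for row in self.rows:
            if row.is_calibration:
                return row.taxon_id
        return None

    @classmethod
    def from_tsv(cls, source: Union[str, Path, io.TextIOBase]) -> "TaxonManifest":
        """Columns: taxon_id, class, method, path, calibration(yes/no)."""
        if isinstance(source, (str, Path)):
            with open(source, encoding="utf-8") as handle:
                return cls.from_tsv(handle)
        header = source.readline().strip().split("\t")
        expected = ["taxon_id", "class", "method", "path", "calibration"]
        if header != expected:
            raise FormatError(f"manifest header must be {expected}, got {header}")
        rows = []
        for line in source:
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 5:
                raise FormatError(f"manifest row needs 5 cells: {line!r}")
            rows.append(
                ManifestRow(
                    taxon_id=cells[0],
                    class_label=cells[1],
                    method=cells[2],
                    path=cells[3],
                    is_calibration=cells[4].strip().lower() in ("yes", "true", "1"),
                )
            )
        return cls(rows=rows)


@dataclass
class PipelineOptions:
    equal_var_ttest: bool = False
    storey: cs.StoreyConfig = field(default_factory=cs.StoreyConfig)
    undefined_policy: str = "passthrough"  # nullset handling during adjustment


@dataclass
class PipelineResult:
    profiles_raw: list[RepresentationProfile]
    profiles_adjusted: Optional[list[RepresentationProfile]]
    factors: Optional[cal.AdjustmentFactors]
    criteria: list[str]
    excluded: dict[str, str]
    analysis1: list[cs.TestResult]
    analysis2: dict[str, list[cs.TestResult]]
    analysis1_raw: Optional[list[cs.TestResult]] = None
    analysis2_raw: Optional[dict[str, list[cs.TestResult]]] = None
    change_summary: Optional[cs.ChangeSummary] = None
    log: list[str] = field(default_factory=list)


def load_profile_table(
    source: Union[str, Path, io.TextIOBase], ref: Optional[ReferenceSet] = None
) -> list[RepresentationProfile]:
    """Read a deposited per-taxon profile table (reproduction mode input)."""
    if ref is None:
        ref = default_reference_set()
    return read_profile_table(source, ref)


def _flatten(analysis2: dict[str, list[cs.TestResult]]) -> list[cs.TestResult]:
    return [r for results in analysis2.values() for r in results]


def run_reproduction(
    profiles: Sequence[RepresentationProfile],
    options: Optional[PipelineOptions] = None,
    criteria: Optional[Sequence[str]] = None,
) -> PipelineResult:
    """Run the statistical analyses directly on given (already adjusted)
    profiles; criteria default to the profile columns plus the total."""
    options = options or PipelineOptions()
    if criteria is None:
        criteria, excluded = cs.select_criteria(profiles)
    else:
        criteria, excluded = list(criteria), {}
    analysis1 = cs.run_analysis_1(
        profiles, criteria, storey=options.storey, equal_var=options.equal_var_ttest
    )
    analysis2 = cs.run_analysis_2(profiles, criteria, storey=options.storey)
    return PipelineResult(
        profiles_raw=list(profiles),
        profiles_adjusted=list(profiles),
        factors=None,
        criteria=list(criteria),
        excluded=excluded,
        analysis1=analysis1,
        analysis2=analysis2,
        log=[f"reproduction mode: {len(profiles)} profiles, {len(criteria)} criteria"],
    )


def run_pipeline(
    manifest: TaxonManifest,
    ref: Optional[ReferenceSet] = None,
    options: Optional[PipelineOptions] = None,
    tables: Optional[dict[tuple[str, str], AnnotationTable]] = None,
) -> PipelineResult:
    """Score, calibrate and test every manifest taxon.

    Annotation tables are read from the manifest paths (simple dialect)
    unless pre-parsed tables are supplied keyed by (taxon_id, method) —
    the hook the simulator and the tests use.
    """
    ref = ref or default_reference_set()
    options = options or PipelineOptions()
    log: list[str] = []

    def table_for(row: ManifestRow) -> AnnotationTable:
        if tables is not None:
            return tables[(row.taxon_id, row.method)]
        return read_simple(row.path)

    profiles_raw: list[RepresentationProfile] = []
    cal_profiles: dict[str, RepresentationProfile] = {}
    for row in manifest.rows:
        profile = to_profile(count_functions(table_for(row), ref), row.class_label)
        if row.is_calibration:
            cal_profiles[row.method] = profile
            log.append(f"calibration input: {row.taxon_id} ({row.method})")
            if row.method == "mapped":
                continue  # the duplicate mapped profile does not enter testing
        profiles_raw.append(profile)

    factors = None
    profiles_adjusted = None
    if cal_profiles:
        factors = cal.compute_adjustment(cal_profiles["curated"], cal_profiles["mapped"])
        log.append(
            f"adjustment factors from {factors.calibration_taxon}: "
            f"{len(factors.factor)} defined, {len(factors.undefined_set)} nullset"
        )
        profiles_adjusted = [
            cal.apply_adjustment(p, factors, options.undefined_policy) for p in profiles_raw
        ]
    else:
        mapped_present = any(r.method == "mapped" for r in manifest.rows)
        if mapped_present:
            log.append(
                "warning: mapped inputs present but no calibration taxon; raw-only mode"
            )

    criteria, excluded = cs.select_criteria(profiles_raw, factors)
    for abbrev, reason in excluded.items():
        log.append(f"excluded {abbrev}: {reason}")

    test_profiles = profiles_adjusted if profiles_adjusted is not None else profiles_raw
    analysis1 = cs.run_analysis_1(
        test_profiles, criteria, storey=options.storey, equal_var=options.equal_var_ttest
    )
    analysis2 = cs.run_analysis_2(test_profiles, criteria, storey=options.storey)

    analysis1_raw = analysis2_raw = change = None
    if profiles_adjusted is not None:
        analysis1_raw = cs.run_analysis_1(
            profiles_raw, criteria, storey=options.storey, equal_var=options.equal_var_ttest
        )
        analysis2_raw = cs.run_analysis_2(profiles_raw, criteria, storey=options.storey)
        change = cs.compare_significance(
            analysis1_raw + _flatten(analysis2_raw), analysis1 + _flatten(analysis2)
        )
        log.append(
            f"adjusted-vs-raw: {change.n_no_change} unchanged, "
            f"{change.n_increase} up, {change.n_decrease} down, "
            f"{change.n_change_gt1} moved >1 level"
        )
    return PipelineResult(
        profiles_raw=profiles_raw,
        profiles_adjusted=profiles_adjusted,
        factors=factors,
        criteria=criteria,
        excluded=excluded,
        analysis1=analysis1,
        analysis2=analysis2,
        analysis1_raw=analysis1_raw,
        analysis2_raw=analysis2_raw,
        change_summary=change,
        log=log,
    )
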