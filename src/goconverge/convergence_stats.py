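"""Inferential layer: group t-tests, per-taxon Z-tests, Storey q-values.

Two complementary designs probe overrepresentation of carnivory-associated
functions:

* **Analysis 1 (group)** — carnivorous vs. control taxa compared on each of
  the 25 criteria (24 functions + the carnivory total) with upper-tailed
  unequal-variance (Welch) t-tests, corrected as one 25-test family.
* **Analysis 2 (per taxon)** — each carnivorous taxon Z-tested against a
  reference normal distribution per criterion, parameterized by the median
  (location) and sample standard deviation (scale) of the control taxa's
  values; each taxon's 25 tests form their own correction family.

Multiple testing is controlled with Storey q-values: the proportion of true
nulls pi0 is estimated on a lambda grid with a df-3 cubic smoothing spline
(numerically identical to R's ``smooth.spline``) evaluated at the largest
grid point, and q_i = min over {j : p_j >= p_i} of pi0 * m * p_j / rank(p_j).
With pi0 fixed at 1 the procedure reduces to Benjamini-Hochberg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import make_smoothing_spline

from .errors import ConfigError, DataError
from .representation import RepresentationProfile

TOTAL = "Total"

#: Six-level significance coding; strict-inequality bins, boundaries fall in
#: the less significant bin.
LEVELS = ("NS", ".", "*", "**", "***", "****")
_LEVEL_THRESHOLDS = (0.10, 0.05, 0.01, 0.001, 0.0001)

__all__ = [
    "TOTAL",
    "LEVELS",
    "ReferenceDistribution",
    "TestResult",
    "StoreyConfig",
    "ChangeSummary",
    "group_ttest",
    "build_reference_distribution",
    "ztest",
    "estimate_pi0",
    "storey_qvalues",
    "significance_level",
    "attach_qvalues",
    "compare_significance",
    "power_effect_size",
    "select_criteria",
    "run_analysis_1",
    "run_analysis_2",
    "results_to_rows",
]


@dataclass(frozen=True)
class ReferenceDistribution:
    """Normal reference for one criterion: control median and sample SD."""

    criterion: str
    location: float
    scale: float

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise DataError(f"{self.criterion}: reference scale must be positive")


@dataclass
class TestResult:
    """One test: a t or Z statistic, its upper-tail p, and (after correction)
    the Storey q and six-level significance code."""

    comparison: str  # "group" or the carnivorous taxon id
    criterion: str
    statistic_kind: str  # "t" | "Z"
    statistic: float
    p: float
    df: Optional[float] = None
    q: Optional[float] = None
    level: Optional[str] = None


@dataclass(frozen=True)
class StoreyConfig:
    """Settings for pi0 estimation.

    The default lambda grid runs 0.05-0.90 in steps of 0.05 — the grid of
    the original q-value software — with the df-3 smoother evaluated at the
    largest grid point. Families smaller than ``min_m_for_estimation``
    p-values fall back to pi0 = 1 (Benjamini-Hochberg).
    """

    lambda_grid: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.901, 0.05), 2))
    pi0_method: str = "smoother"
    pi0_fixed: float = 1.0
    min_m_for_estimation: int = 10

    def __post_init__(self) -> None:
        grid = np.asarray(self.lambda_grid, dtype=float)
        if grid.ndim != 1 or len(grid) < 4:
            raise ConfigError("lambda_grid needs at least 4 points")
        if np.any(np.diff(grid) <= 0) or grid[0] < 0 or grid[-1] >= 1:
            raise ConfigError("lambda_grid must be strictly increasing within [0, 1)")
        if not 0 < self.pi0_fixed <= 1:
            raise ConfigError("pi0_fixed must be in (0, 1]")
        if self.pi0_method not in ("smoother", "fixed"):
            raise ConfigError(f"unknown pi0_method {self.pi0_method!r}")


@dataclass(frozen=True)
class ChangeSummary:
    """Tally of significance-level movements between two paired result sets."""

    n_no_change: int
    n_increase: int
    n_decrease: int
    n_change_gt1: int
    by_comparison: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return self.n_no_change + self.n_increase + self.n_decrease


def group_ttest(
    carn_values: Sequence[float],
    ctrl_values: Sequence[float],
    criterion: str = "",
    equal_var: bool = False,
) -> TestResult:
    """Upper-tailed (carnivorous > control) two-sample t-test.

    Welch's unequal-variance form by default, with Welch-Satterthwaite
    degrees of freedom; ``equal_var=True`` selects the pooled-variance form.
    """
    carn = np.asarray(carn_values, dtype=float)
    ctrl = np.asarray(ctrl_values, dtype=float)
    if len(carn) < 2 or len(ctrl) < 2:
        raise DataError(f"{criterion or 'group test'}: need >=2 values per group")
    res = stats.ttest_ind(carn, ctrl, equal_var=equal_var, alternative="greater")
    return TestResult(
        comparison="group",
        criterion=criterion,
        statistic_kind="t",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        df=float(res.df),
    )


def build_reference_distribution(
    ctrl_values: Sequence[float], criterion: str = ""
) -> ReferenceDistribution:
    """Reference normal from control values: median location, sample (n-1) SD."""
    values = np.asarray(ctrl_values, dtype=float)
    if len(values) < 2:
        raise DataError(f"{criterion}: need >=2 control values")
    scale = float(np.std(values, ddof=1))
    if scale == 0.0:
        raise DataError(f"{criterion}: all control values equal; reference scale is zero")
    return ReferenceDistribution(
        criterion=criterion, location=float(np.median(values)), scale=scale
    )


def ztest(value: float, dist: ReferenceDistribution, comparison: str = "") -> TestResult:
    """Upper-tailed Z-test of one taxon's value against a reference normal."""
    z = (value - dist.location) / dist.scale
    return TestResult(
        comparison=comparison,
        criterion=dist.criterion,
        statistic_kind="Z",
        statistic=float(z),
        p=float(stats.norm.sf(z)),
    )


def _spline_df3(x: np.ndarray, y: np.ndarray) -> float:
    """Value at x[-1] of a cubic smoothing spline with 3 effective degrees of
    freedom (penalty calibrated so the smoother matrix has trace 3)."""

    def trace_for(lam: float) -> float:
        tr = 0.0
        for i in range(len(x)):
            e = np.zeros(len(x))
            e[i] = 1.0
            tr += float(make_smoothing_spline(x, e, lam=lam)(x[i]))
        return tr

    lo, hi = 1e-9, 1e5
    for _ in range(60):
        mid = math.sqrt(lo * hi)
        if trace_for(mid) > 3.0:
            lo = mid
        else:
            hi = mid
    lam = math.sqrt(lo * hi)
    return float(make_smoothing_spline(x, y, lam=lam)(x[-1]))


def estimate_pi0(pvalues: Sequence[float], cfg: StoreyConfig = StoreyConfig()) -> float:
    """Estimate the proportion of true null hypotheses.

    For each lambda, pi0(lambda) = #{p > lambda} / (m (1 - lambda)); the
    smoother extrapolates the trend to the largest lambda, where the
    estimate is least biased. Estimates outside (0, 1] are clamped to the
    nearest attainable value.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise DataError("cannot estimate pi0 from an empty p-value list")
    if cfg.pi0_method == "fixed" or p.size < cfg.min_m_for_estimation:
        return cfg.pi0_fixed if cfg.pi0_method == "fixed" else 1.0
    grid = np.asarray(cfg.lambda_grid, dtype=float)
    pi0_lambda = np.array([(p > lam).sum() / (p.size * (1.0 - lam)) for lam in grid])
    pi0 = _spline_df3(grid, pi0_lambda)
    if pi0 > 1.0:
        pi0 = 1.0
    if pi0 <= 0.0:
        # degenerate extrapolation; smallest sensible estimate is one null test
        pi0 = 1.0 / p.size
    return float(pi0)


def storey_qvalues(
    pvalues: Sequence[float], cfg: StoreyConfig = StoreyConfig()
) -> np.ndarray:
    """Storey q-values for one correction family.

    q_i = min over {j : p_j >= p_i} of pi0 * m * p_j / rank(p_j), with tied
    p-values sharing their maximum rank; the result is monotone in p and
    clipped to (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise DataError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise DataError("p-values must lie in (0, 1]")
    pi0 = estimate_pi0(p, cfg)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    # maximum rank among ties
    ranks = np.searchsorted(sorted_p, sorted_p, side="right").astype(float)
    q_sorted = pi0 * m * sorted_p / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, None, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def significance_level(q: float) -> str:
    """Six-level code for a q-value; strict thresholds, so a boundary value
    (e.g. exactly 0.05) falls in the less significant bin."""
    if not 0 < q <= 1:
        raise DataError(f"q-value {q} outside (0, 1]")
    level = LEVELS[0]
    for threshold, name in zip(_LEVEL_THRESHOLDS, LEVELS[1:]):
        if q < threshold:
            level = name
    return level


def attach_qvalues(
    results: list[TestResult], cfg: StoreyConfig = StoreyConfig()
) -> list[TestResult]:
    """Correct one family of results in place-order: fill q and level."""
    q = storey_qvalues([r.p for r in results], cfg)
    return [
        replace(r, q=float(qi), level=significance_level(float(qi)))
        for r, qi in zip(results, q)
    ]


def compare_significance(
    results_a: Iterable[TestResult], results_b: Iterable[TestResult]
) -> ChangeSummary:
    """Count level changes from family A to family B, paired by
    (comparison, criterion); "increase" means B is more significant."""
    def keyed(results: Iterable[TestResult]) -> dict[tuple[str, str], TestResult]:
        return {(r.comparison, r.criterion): r for r in results}

    a, b = keyed(results_a), keyed(results_b)
    if set(a) != set(b):
        missing = set(a) ^ set(b)
        raise DataError(f"unpaired results: {sorted(missing)[:5]}")
    no_change = increase = decrease = gt1 = 0
    by_comp: dict[str, list[int]] = {}
    for key in a:
        ra, rb = a[key], b[key]
        if ra.level is None or rb.level is None:
            raise DataError(f"results for {key} lack significance levels")
        delta = LEVELS.index(rb.level) - LEVELS.index(ra.level)
        tallies = by_comp.setdefault(key[0], [0, 0, 0, 0])
        if delta == 0:
            no_change += 1
            tallies[0] += 1
        elif delta > 0:
            increase += 1
            tallies[1] += 1
        else:
            decrease += 1
            tallies[2] += 1
        if abs(delta) > 1:
            gt1 += 1
            tallies[3] += 1
    return ChangeSummary(
        n_no_change=no_change,
        n_increase=increase,
        n_decrease=decrease,
        n_change_gt1=gt1,
        by_comparison={k: tuple(v) for k, v in by_comp.items()},
    )


def power_effect_size(n1: int, n2: int, alpha: float, beta: float) -> float:
    """Smallest detectable mean shift, in control-SD units, of the two-group
    design at the given error rates (normal approximation):

        d = (z_{1-alpha} + z_{1-beta}) * sqrt(1/n1 + 1/n2)
    """
    if n1 < 1 or n2 < 1:
        raise ConfigError("group sizes must be >= 1")
    if not (0 < alpha < 1 and 0 < beta < 1):
        raise ConfigError("alpha and beta must lie in (0, 1)")
    return float(
        (stats.norm.ppf(1 - alpha) + stats.norm.ppf(1 - beta)) * math.sqrt(1 / n1 + 1 / n2)
    )


def _split_classes(
    profiles: Sequence[RepresentationProfile],
) -> tuple[list[RepresentationProfile], list[RepresentationProfile]]:
    carn = [p for p in profiles if p.class_label == "carnivorous"]
    ctrl = [p for p in profiles if p.class_label == "control"]
    if len(carn) < 2 or len(ctrl) < 2:
        raise ConfigError(
            f"need >=2 taxa per class for testing, got {len(carn)} carnivorous "
            f"and {len(ctrl)} control"
        )
    return carn, ctrl


def select_criteria(
    profiles: Sequence[RepresentationProfile],
    factors: Optional["AdjustmentFactors"] = None,  # noqa: F821
) -> tuple[list[str], dict[str, str]]:
    """Choose the criteria entering testing, plus an exclusion report.

    A function is tested when its adjustment factor is defined (when a
    calibration was performed) and it was detected in at least one taxon;
    the carnivory total is always the final criterion.
    """
    if not profiles:
        raise ConfigError("no profiles")
    functions = list(profiles[0].per_mille)
    excluded: dict[str, str] = {}
    criteria: list[str] = []
    for abbrev in functions:
        if factors is not None and not factors.is_defined(abbrev):
            excluded[abbrev] = "nullset: no defined adjustment factor"
            continue
        if all(p.per_mille[abbrev] == 0.0 for p in profiles):
            excluded[abbrev] = "zero count in every taxon"
            continue
        criteria.append(abbrev)
    criteria.append(TOTAL)
    return criteria, excluded


def run_analysis_1(
    profiles: Sequence[RepresentationProfile],
    criteria: Sequence[str],
    storey: StoreyConfig = StoreyConfig(),
    equal_var: bool = False,
) -> list[TestResult]:
    """Group comparison: one Welch t-test per criterion, corrected as a
    single Storey family."""
    carn, ctrl = _split_classes(profiles)
    results = [
        group_ttest(
            [p.value_of(c) for p in carn],
            [p.value_of(c) for p in ctrl],
            criterion=c,
            equal_var=equal_var,
        )
        for c in criteria
    ]
    return attach_qvalues(results, storey)


def run_analysis_2(
    profiles: Sequence[RepresentationProfile],
    criteria: Sequence[str],
    storey: StoreyConfig = StoreyConfig(),
) -> dict[str, list[TestResult]]:
    """Per-taxon Z-tests against control-derived reference distributions;
    Storey correction runs within each taxon's family of tests."""
    carn, ctrl = _split_classes(profiles)
    dists = {
        c: build_reference_distribution([p.value_of(c) for p in ctrl], criterion=c)
        for c in criteria
    }
    out: dict[str, list[TestResult]] = {}
    for taxon in carn:
        results = [
            ztest(taxon.value_of(c), dists[c], comparison=taxon.taxon_id) for c in criteria
        ]
        out[taxon.taxon_id] = attach_qvalues(results, storey)
    return out


def _fmt_sig(x: float, sig: int = 3) -> str:
    """Three-significant-figure formatting matching report conventions:
    scientific notation below 0.001."""
    if x < 0.001:
        return f"{x:.{sig - 1}E}"
    return f"{float(f'%.{sig}g' % x):g}"


def results_to_rows(results: Sequence[TestResult]) -> list[dict[str, str]]:
    """Report rows with presentation rounding: statistics to 2 dp, p and q to
    3 significant figures."""
    rows = []
    for r in results:
        rows.append(
            {
                "comparison": r.comparison,
                "criterion": r.criterion,
                r.statistic_kind: f"{r.statistic:.2f}",
                "p": _fmt_sig(r.p),
                "q": _fmt_sig(r.q) if r.q is not None else "",
                "sig": r.level or "",
            }
        )
    return rows
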