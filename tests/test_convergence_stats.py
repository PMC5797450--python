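import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from goconverge import convergence_stats as cs
from goconverge.errors import ConfigError, DataError
from goconverge.representation import RepresentationProfile


def make_profiles(values_by_taxon, carnivorous):
    profiles = []
    for taxon, values in values_by_taxon.items():
        profiles.append(
            RepresentationProfile(
                taxon_id=taxon,
                method="curated",
                class_label="carnivorous" if taxon in carnivorous else "control",
                per_mille=dict(values),
                total_per_mille=sum(values.values()),
                adjusted=True,
            )
        )
    return profiles


class TestGroupTtest:
    def test_identical_groups(self):
        r = cs.group_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(0.5)

    def test_lower_mean_gives_p_above_half(self):
        r = cs.group_ttest([1.0, 1.1, 0.9], [2.0, 2.2, 1.9])
        assert r.statistic < 0
        assert r.p > 0.5

    def test_location_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        carn, ctrl = rng.normal(1, 1, 4), rng.normal(0, 1, 6)
        base = cs.group_ttest(carn, ctrl)
        shifted = cs.group_ttest(carn + 7.5, ctrl + 7.5)
        scaled = cs.group_ttest(carn * 3.2, ctrl * 3.2)
        assert shifted.p == pytest.approx(base.p)
        assert scaled.p == pytest.approx(base.p)

    def test_insufficient_group_size(self):
        with pytest.raises(DataError):
            cs.group_ttest([1.0], [1.0, 2.0])

    def test_welch_vs_pooled_differ(self):
        carn, ctrl = [5.0, 9.0, 2.0, 8.0], [1.0, 1.1, 0.9, 1.2, 1.05, 0.95]
        welch = cs.group_ttest(carn, ctrl)
        pooled = cs.group_ttest(carn, ctrl, equal_var=True)
        assert welch.df < pooled.df
        assert welch.p != pooled.p


class TestReferenceDistribution:
    def test_small_examples(self):
        d = cs.build_reference_distribution([1.0, 2.0, 3.0])
        assert (d.location, d.scale) == (2.0, pytest.approx(1.0))
        d = cs.build_reference_distribution([0.0, 0.0, 0.0, 4.0])
        assert (d.location, d.scale) == (0.0, pytest.approx(2.0))

    def test_matches_direct_formulas(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            values = rng.gamma(2.0, 1.5, 6)
            d = cs.build_reference_distribution(values)
            assert d.location == pytest.approx(np.median(values))
            assert d.scale == pytest.approx(np.std(values, ddof=1))

    def test_degenerate_inputs(self):
        with pytest.raises(DataError, match="zero"):
            cs.build_reference_distribution([2.0, 2.0, 2.0])
        with pytest.raises(DataError):
            cs.build_reference_distribution([1.0])


class TestZtest:
    def test_at_location(self):
        d = cs.ReferenceDistribution("f", location=3.0, scale=1.5)
        r = cs.ztest(3.0, d)
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(0.5)

    @pytest.mark.parametrize("z,p3sf", [(2.76, 2.89e-3), (3.72, 1.01e-4)])
    def test_upper_tail_values(self, z, p3sf):
        # reported p-values come from unrounded statistics, so allow ~2%
        d = cs.ReferenceDistribution("f", location=0.0, scale=1.0)
        assert cs.ztest(z, d).p == pytest.approx(p3sf, rel=0.02)

    def test_p_strictly_decreasing_in_value(self):
        d = cs.ReferenceDistribution("f", location=1.0, scale=2.0)
        values = np.linspace(-3, 5, 30)
        ps = [cs.ztest(v, d).p for v in values]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestStorey:
    def test_single_p_with_fixed_pi0(self):
        cfg = cs.StoreyConfig(pi0_method="fixed", pi0_fixed=1.0)
        assert cs.storey_qvalues([0.037], cfg)[0] == pytest.approx(0.037)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        p=st.lists(
            st.floats(min_value=1e-8, max_value=1.0, exclude_min=False),
            min_size=1,
            max_size=60,
        )
    )
    def test_fixed_pi0_equals_benjamini_hochberg(self, p):
        cfg = cs.StoreyConfig(pi0_method="fixed", pi0_fixed=1.0)
        q = cs.storey_qvalues(p, cfg)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, bh)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        p=st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=12, max_size=40)
    )
    def test_q_monotone_in_p(self, p):
        q = cs.storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(DataError):
            cs.storey_qvalues([])
        with pytest.raises(DataError):
            cs.storey_qvalues([0.0, 0.5])
        with pytest.raises(DataError):
            cs.storey_qvalues([0.5, 1.2])

    def test_small_family_falls_back_to_bh(self):
        p = [0.01, 0.2, 0.9]  # below min_m_for_estimation
        q = cs.storey_qvalues(p)
        assert np.allclose(q, multipletests(p, method="fdr_bh")[1])

    def test_pi0_estimate_on_null_uniform_near_one(self):
        rng = np.random.default_rng(21)
        p = rng.random(500)
        pi0 = cs.estimate_pi0(p)
        assert 0.8 <= pi0 <= 1.0


class TestSignificanceLevels:
    @pytest.mark.parametrize(
        "q,level",
        [
            (0.5, "NS"),
            (0.10, "NS"),  # boundary -> less significant bin
            (0.099, "."),
            (0.05, "."),
            (0.047, "*"),
            (0.01, "*"),
            (0.009, "**"),
            (0.001, "**"),
            (0.0009, "***"),
            (0.0001, "***"),
            (0.00009, "****"),
        ],
    )
    def test_binning(self, q, level):
        assert cs.significance_level(q) == level

    def test_invalid_q(self):
        with pytest.raises(DataError):
            cs.significance_level(0.0)


class TestCompareSignificance:
    def _result(self, comparison, criterion, level):
        return cs.TestResult(
            comparison=comparison,
            criterion=criterion,
            statistic_kind="Z",
            statistic=0.0,
            p=0.5,
            q=0.5,
            level=level,
        )

    def test_identical_sets_all_unchanged(self):
        a = [self._result("g", f"f{i}", "NS") for i in range(5)]
        summary = cs.compare_significance(a, list(a))
        assert summary.n_no_change == 5
        assert summary.n_increase == summary.n_decrease == summary.n_change_gt1 == 0

    def test_two_level_jump(self):
        a = [self._result("g", "f", "NS"), self._result("g", "f2", "*")]
        b = [self._result("g", "f", "**"), self._result("g", "f2", ".")]
        summary = cs.compare_significance(a, b)
        assert summary.n_increase == 1
        assert summary.n_decrease == 1
        assert summary.n_change_gt1 == 1  # NS -> ** jumps 3 levels

    def test_unpaired_results_rejected(self):
        with pytest.raises(DataError, match="unpaired"):
            cs.compare_significance(
                [self._result("g", "f", "NS")], [self._result("g", "other", "NS")]
            )


class TestPower:
    @pytest.mark.parametrize(
        "beta,expected", [(0.50, 1.06), (0.05, 2.12)]
    )
    def test_design_effect_sizes(self, beta, expected):
        assert cs.power_effect_size(6, 4, 0.05, beta) == pytest.approx(expected, abs=0.005)

    def test_alpha_beta_half_gives_zero(self):
        assert cs.power_effect_size(6, 4, 0.5, 0.5) == pytest.approx(0.0)

    def test_invalid_inputs(self):
        with pytest.raises(ConfigError):
            cs.power_effect_size(0, 4, 0.05, 0.5)
        with pytest.raises(ConfigError):
            cs.power_effect_size(6, 4, 1.5, 0.5)


class TestAnalyses:
    def _profiles(self, rng, n_funcs=12):
        criteria = [f"f{i}" for i in range(n_funcs)]
        taxa = {}
        for i in range(6):
            taxa[f"ctrl{i}"] = {c: float(rng.gamma(4, 0.5)) for c in criteria}
        for i in range(4):
            taxa[f"carn{i}"] = {c: float(rng.gamma(4, 0.5)) for c in criteria}
        return make_profiles(taxa, carnivorous={f"carn{i}" for i in range(4)})

    def test_analysis_shapes(self):
        profiles = self._profiles(np.random.default_rng(2))
        criteria = list(profiles[0].per_mille) + [cs.TOTAL]
        a1 = cs.run_analysis_1(profiles, criteria)
        a2 = cs.run_analysis_2(profiles, criteria)
        assert len(a1) == len(criteria)
        assert len(a2) == 4
        assert all(len(v) == len(criteria) for v in a2.values())
        assert sum(len(v) for v in a2.values()) == 4 * len(criteria)
        assert all(r.q is not None and r.level is not None for r in a1)

    def test_single_class_is_config_error(self):
        profiles = [p for p in self._profiles(np.random.default_rng(2)) if
                    p.class_label == "control"]
        with pytest.raises(ConfigError):
            cs.run_analysis_1(profiles, ["f0"])

    def test_select_criteria_excludes_nullset_and_undetected(self):
        from goconverge.calibration import AdjustmentFactors

        profiles = make_profiles(
            {
                "c1": {"A": 1.0, "B": 0.0, "C": 2.0},
                "c2": {"A": 1.1, "B": 0.0, "C": 2.2},
                "x1": {"A": 0.9, "B": 0.0, "C": 2.1},
                "x2": {"A": 1.2, "B": 0.0, "C": 1.9},
            },
            carnivorous={"x1", "x2"},
        )
        factors = AdjustmentFactors(
            calibration_taxon="cal",
            factor={"A": 1.0, "B": 1.0},
            undefined_set=frozenset({"C"}),
        )
        criteria, excluded = cs.select_criteria(profiles, factors)
        assert criteria == ["A", cs.TOTAL]
        assert set(excluded) == {"B", "C"}


def test_report_rounding():
    r = cs.TestResult(
        comparison="group",
        criterion="AltOx",
        statistic_kind="t",
        statistic=3.14159,
        p=0.011234,
        q=0.04678,
        level="*",
    )
    (row,) = cs.results_to_rows([r])
    assert row["t"] == "3.14"
    assert row["p"] == "0.0112"
    assert row["q"] == "0.0468"
    low = cs.TestResult(
        comparison="g", criterion="x", statistic_kind="Z", statistic=3.716,
        p=1.012e-4, q=2.45e-3, level="**",
    )
    (row,) = cs.results_to_rows([low])
    assert row["p"] == "1.01E-04"
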