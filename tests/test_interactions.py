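import math

import numpy as np
import pytest
import scipy.stats as sstats
from hypothesis import given, settings
from hypothesis import strategies as st

from cocult.growth import GroupStats
from cocult.interactions import (
    NEGATIVE,
    NEUTRAL,
    POSITIVE,
    AnalysisConfig,
    call_utilization,
    classify_all,
    classify_case,
    classify_interaction,
    coculture_ratio,
    fdr_adjust,
    shapiro_wilk,
    student_t_test,
    summarize,
)
from cocult.simulate import generate_null_dataset

from conftest import make_triad
from oracles import bh_oracle, pooled_t_oracle, shapiro3_oracle


class TestShapiroWilk:
    def test_symmetric_triple_is_exactly_normal(self):
        # n=3 closed form: W = (a1*(x(3)-x(1)))^2 / sum((x-mean)^2), a1=1/sqrt(2)
        for sample in ([1, 2, 3], [0.20, 0.21, 0.19]):
            w, _ = shapiro_wilk(sample)
            assert w == pytest.approx(1.0, abs=1e-6)

    def test_matches_closed_form_at_n3(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            x = rng.normal(size=3)
            w, _ = shapiro_wilk(x)
            assert w == pytest.approx(shapiro3_oracle(x), abs=1e-4)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(-10_000, 10_000), min_size=4, max_size=10,
                    unique=True),
           st.floats(0.1, 5), st.floats(-3, 3))
    def test_affine_invariance(self, ints, scale, shift):
        x = [i / 7 for i in ints]
        w1, _ = shapiro_wilk(x)
        w2, _ = shapiro_wilk([scale * v + shift for v in x])
        assert w1 == pytest.approx(w2, rel=1e-6)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1, 2])
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 1.0, 1.0])


class TestStudentT:
    def test_worked_example(self):
        t, p = student_t_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert p == pytest.approx(0.288, abs=1e-3)

    def test_identical_groups(self):
        assert student_t_test([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_swap_negates_t_preserves_p(self):
        t1, p1 = student_t_test([1, 2, 3], [2, 3, 5])
        t2, p2 = student_t_test([2, 3, 5], [1, 2, 3])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_zero_variance_contract(self):
        assert student_t_test([1, 1], [1, 1]) == (0.0, 1.0)
        t, p = student_t_test([2, 2], [1, 1])
        assert t == math.inf and p == 0.0

    def test_agrees_with_direct_formula_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            x = rng.normal(size=rng.integers(2, 8))
            y = rng.normal(loc=rng.normal(), size=rng.integers(2, 8))
            t, p = student_t_test(x, y)
            to, po = pooled_t_oracle(x, y)
            assert abs(t - to) < 1e-10
            assert abs(p - po) < 1e-8


class TestFdrAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged_and_all_ones(self):
        assert fdr_adjust([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    def test_agrees_with_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(fdr_adjust(p), bh_oracle(p), atol=1e-12)

    def test_corrected_at_least_raw_and_order_preserving(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=30)
        q = fdr_adjust(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestUtilizationAndRatio:
    @pytest.mark.parametrize("values,expected", [
        ([0.30, 0.30, 0.30], True),
        ([0.02, 0.02, 0.02], False),
        ([0.04, 0.06], False),  # mean exactly at the 0.05 floor: strict >
    ])
    def test_floor_is_strict(self, values, expected):
        ds = make_triad([0.1] * 3, values, [0.1] * 3)
        assert call_utilization(ds, "A", "c1") is expected

    @pytest.mark.parametrize("co,ma,mb,expected", [
        (0.5, 0.2, 0.02, 2.5),
        (0.3, 0.3, 0.05, 1.0),
        (0.1, 0.3, 0.05, 1 / 3),
    ])
    def test_ratio(self, co, ma, mb, expected):
        assert coculture_ratio(co, ma, mb) == pytest.approx(expected, abs=1e-3)

    def test_ratio_undefined_when_both_monos_zero(self):
        assert math.isnan(coculture_ratio(0.5, 0.0, 0.0))


class TestClassifyInteraction:
    def cfg(self):
        return AnalysisConfig()

    def test_clear_positive(self):
        call = classify_interaction(GroupStats.from_values([0.50, 0.52, 0.48]),
                                    GroupStats.from_values([0.20, 0.21, 0.19]),
                                    GroupStats.from_values([0.02, 0.02, 0.02]),
                                    self.cfg())
        assert call.label == POSITIVE
        assert call.ratio > 1

    def test_identical_groups_are_neutral(self):
        g = GroupStats.from_values([0.20, 0.21, 0.19])
        assert classify_interaction(g, g, g, self.cfg()).label == NEUTRAL

    def test_clear_negative_against_one_mono(self):
        call = classify_interaction(GroupStats.from_values([0.10, 0.11, 0.09]),
                                    GroupStats.from_values([0.30, 0.31, 0.29]),
                                    GroupStats.from_values([0.04, 0.04, 0.04]),
                                    self.cfg())
        assert call.label == NEGATIVE

    def test_floor_blocks_sub_noise_differences(self):
        # strong relative difference, but everything below 0.05 OD
        call = classify_interaction(GroupStats.from_values([0.030, 0.031, 0.029]),
                                    GroupStats.from_values([0.010, 0.011, 0.009]),
                                    GroupStats.from_values([0.010, 0.012, 0.008]),
                                    self.cfg())
        assert call.label == NEUTRAL

    def test_requires_three_replicates(self):
        g2 = GroupStats.from_values([0.1, 0.2])
        g3 = GroupStats.from_values([0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="n=2"):
            classify_interaction(g2, g3, g3, self.cfg())


class TestClassifyCase:
    @pytest.mark.parametrize("label,use_a,use_b,expected", [
        (POSITIVE, True, False, "single_use"),
        (POSITIVE, True, True, "both_use"),
        (NEGATIVE, False, False, "neither_use"),
        (NEUTRAL, True, True, "not_applicable"),
    ])
    def test_cases(self, label, use_a, use_b, expected):
        from cocult.interactions import InteractionCall
        call = InteractionCall(pair=("A", "B"), carbon="c", label=label, ratio=1.0)
        assert classify_case(call, use_a, use_b) == expected


class TestClassifyAll:
    def test_strain_relabeling_symmetry(self):
        ds1 = make_triad([0.5, 0.52, 0.48], [0.2, 0.21, 0.19], [0.02, 0.02, 0.02],
                         pair=("A", "B"))
        ds2 = make_triad([0.5, 0.52, 0.48], [0.02, 0.02, 0.02], [0.2, 0.21, 0.19],
                         pair=("B", "A"))
        c1 = classify_all(ds1)[0]
        c2 = classify_all(ds2)[0]
        assert c1.label == c2.label
        assert c1.ratio == pytest.approx(c2.ratio)

    def test_replicate_permutation_invariance(self):
        ds1 = make_triad([0.5, 0.52, 0.48], [0.2, 0.21, 0.19], [0.02, 0.02, 0.02])
        ds2 = make_triad([0.48, 0.5, 0.52], [0.19, 0.2, 0.21], [0.02, 0.02, 0.02])
        assert classify_all(ds1)[0].label == classify_all(ds2)[0].label

    def test_single_neutral_triad(self):
        ds = make_triad([0.2, 0.21, 0.19], [0.2, 0.21, 0.19], [0.2, 0.21, 0.19])
        calls = classify_all(ds)
        assert len(calls) == 1 and calls[0].label == NEUTRAL

    def test_positive_calls_have_ratio_above_one(self, pattern_calls):
        for call in pattern_calls:
            if call.label == POSITIVE:
                assert call.ratio > 1

    def test_null_false_call_rate_controlled(self):
        # small version of the null calibration; the acceptance suite runs 500
        ds = generate_null_dataset(n_triads=100, sd=0.01, seed=17)
        calls = classify_all(ds)
        assert sum(c.label != NEUTRAL for c in calls) / len(calls) <= 0.07

    def test_empty_design_errors(self):
        from cocult.growth import GrowthCurve, GrowthDataset
        curves = [GrowthCurve(strains={"a"}, carbon="c", replicate=r,
                              times=(1,), od=(0.1,)) for r in (1, 2, 3)]
        with pytest.raises(ValueError, match="complete"):
            classify_all(GrowthDataset(curves=curves))


class TestSummarize:
    def test_percentages_one_decimal(self, pattern_calls):
        s = summarize(pattern_calls)
        assert s.n_total == s.n_positive + s.n_negative + s.n_neutral == 84
        assert s.pct_positive == round(100 * s.n_positive / 84, 1)
        assert s.per_carbon.to_numpy().sum() == 84
        assert s.per_pair.to_numpy().sum() == 84

    def test_no_positive_calls(self):
        ds = make_triad([0.2, 0.21, 0.19], [0.2, 0.21, 0.19], [0.2, 0.21, 0.19])
        s = summarize(classify_all(ds))
        assert s.pct_positive == 0.0

    def test_nonparametric_fallback_policy_runs(self):
        cfg = AnalysisConfig(normality_policy="fallback_nonparametric")
        ds = make_triad([0.5, 0.52, 0.48], [0.2, 0.21, 0.19], [0.02, 0.02, 0.02])
        calls = classify_all(ds, cfg)
        assert calls[0].label in (POSITIVE, NEUTRAL)


def test_config_validation():
    with pytest.raises(ValueError):
        AnalysisConfig(alpha=1.5)
    with pytest.raises(ValueError):
        AnalysisConfig(normality_policy="ignore")
    with pytest.raises(ValueError):
        AnalysisConfig(fdr_method="bonferroni")
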