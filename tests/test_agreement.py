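"""Error rule, fourth-observer correction, chi-square, ICC, Bland-Altman."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from pectus.agreement import (
    BlandAltman, ai_error, agreement_report, bland_altman, dice,
    error_rate_report, flag_error, fourth_person_correction, icc_single, iou,
    pearson_chi2, pooled_error_rate, simulate_observer_table,
)
from pectus.errors import DataError, ParameterError


class TestOverlapMetrics:
    def test_identical_masks_score_one(self):
        m = np.random.default_rng(0).random((32, 32)) > 0.5
        assert dice(m, m) == 1.0
        assert iou(m, m) == 1.0

    def test_half_overlapping_squares(self):
        a = np.zeros((10, 20), bool)
        b = np.zeros((10, 20), bool)
        a[:, :10] = True
        b[:, 5:15] = True
        assert dice(a, b) == pytest.approx(0.5)
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_both_empty_agree(self):
        e = np.zeros((8, 8), bool)
        assert dice(e, e) == 1.0 and iou(e, e) == 1.0

    def test_dice_iou_identity_on_random_pairs(self, rng):
        for _ in range(20):
            a = rng.random((24, 24)) > rng.uniform(0.2, 0.8)
            b = rng.random((24, 24)) > rng.uniform(0.2, 0.8)
            j = iou(a, b)
            assert dice(a, b) == pytest.approx(2 * j / (1 + j), abs=1e-12)

    def test_shape_mismatch_is_an_error(self):
        with pytest.raises(ParameterError):
            dice(np.zeros((4, 4), bool), np.zeros((4, 5), bool))


class TestErrorRule:
    def test_equal_triple_is_no_error(self):
        assert not flag_error([10, 10, 10]).is_error

    def test_worked_example_above_threshold(self):
        # mean 10.667, worst deviation 1.333 > 1.067
        flag = flag_error([10, 10, 12])
        assert flag.is_error and flag.worst_observer == 3

    def test_worked_example_below_threshold(self):
        # mean 10.333, worst deviation 0.667 <= 1.033
        assert not flag_error([10, 10, 11]).is_error

    def test_deviation_tie_prefers_lowest_observer(self):
        flag = flag_error([8, 12, 10])
        assert flag.worst_observer == 1 and flag.tie

    @settings(max_examples=50, deadline=None)
    @given(
        v=st.tuples(*[st.floats(1.0, 100.0)] * 3),
        k=st.floats(0.01, 1000.0),
    )
    def test_decision_is_scale_invariant(self, v, k):
        assert flag_error(v).is_error == flag_error([k * x for x in v]).is_error

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ParameterError):
            flag_error([10, 0, 10])


class TestFourthPersonCorrection:
    def test_flagged_row_is_repaired(self):
        row = {"obs1": 10, "obs2": 10, "obs3": 12, "obs4": 10}
        corrected, changed = fourth_person_correction(row)
        assert corrected == (10, 10, 10) and changed
        assert not flag_error(corrected).is_error

    def test_unflagged_row_passes_through(self):
        row = {"obs1": 10, "obs2": 10, "obs3": 11, "obs4": 99}
        corrected, changed = fourth_person_correction(row)
        assert corrected == (10, 10, 11) and not changed

    def test_bad_fourth_observer_may_leave_an_error(self):
        row = {"obs1": 10, "obs2": 10, "obs3": 13, "obs4": 20}
        corrected, changed = fourth_person_correction(row)
        assert changed and flag_error(corrected).is_error

    def test_missing_fourth_observer_on_flagged_row(self):
        row = {"patient_id": "P1", "index_name": "haller",
               "obs1": 10, "obs2": 10, "obs3": 13, "obs4": None}
        with pytest.raises(DataError, match="P1"):
            fourth_person_correction(row)


class TestAiError:
    def test_exact_agreement_is_no_error(self):
        assert not ai_error(10.0, [10, 10, 10])

    def test_eleven_percent_deviation_is_an_error(self):
        assert ai_error(1.11 * 10.0, [10, 10, 10])

    def test_decision_flips_exactly_at_the_threshold(self):
        m = 10.0
        eps = 1e-9
        assert not ai_error(m * 1.1, [m, m, m])        # boundary: not > 10 %
        assert ai_error(m * 1.1 + eps, [m, m, m])
        assert not ai_error(m * 0.9, [m, m, m])
        assert ai_error(m * 0.9 - eps, [m, m, m])


class TestErrorRateReport:
    def test_all_agree_table_has_zero_errors(self):
        table = simulate_observer_table(12, seed=0, observer_cv=0.0, ai_cv=0.0)
        rep = error_rate_report(table)
        assert rep["pooled_counts"] == {"manual_pre": 0, "manual_post": 0,
                                        "ai_pre": 0, "ai_post": 0}
        assert rep["pooled_denominator"] == 36

    def test_pooled_counts_are_sums_of_per_index_counts(self):
        table = simulate_observer_table(30, seed=4, observer_cv=0.08)
        rep = error_rate_report(table)
        for key in ("manual_pre", "manual_post", "ai_pre", "ai_post"):
            assert rep["pooled_counts"][key] == sum(
                c[key] for c in rep["counts"].values())

    def test_duplicate_rows_rejected(self):
        table = simulate_observer_table(5, seed=0)
        with pytest.raises(DataError, match="duplicate"):
            error_rate_report(pd.concat([table, table.iloc[:1]]))

    def test_pooled_rate_requires_consistent_denominators(self):
        with pytest.raises(ParameterError):
            pooled_error_rate([10, 5], [8, 164])  # count exceeds denominator


class TestPearsonChi2:
    def test_equal_proportions_give_zero_statistic(self):
        s, p = pearson_chi2([[10, 90], [10, 90]])
        assert s == 0.0 and p == 1.0

    def test_matches_independent_implementation(self):
        tables = [[[26, 138], [7, 157]], [[78, 414], [43, 449]],
                  [[5, 12], [9, 3]]]
        for t in tables:
            s, p = pearson_chi2(t)
            s_ref, p_ref, _, _ = chi2_contingency(np.asarray(t), correction=False)
            assert s == pytest.approx(s_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_yates_correction_matches_scipy(self):
        t = [[26, 138], [7, 157]]
        s, _ = pearson_chi2(t, yates=True)
        s_ref, _, _, _ = chi2_contingency(np.asarray(t), correction=True)
        assert s == pytest.approx(s_ref, abs=1e-10)

    def test_transposing_rows_and_columns_preserves_statistic(self):
        t = np.array([[26, 138], [7, 157]])
        s0, _ = pearson_chi2(t)
        s1, _ = pearson_chi2(t[::-1, ::-1])
        assert s1 == pytest.approx(s0, abs=1e-12)

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ParameterError, match="margin"):
            pearson_chi2([[0, 0], [5, 7]])


class TestIcc:
    def test_duplicated_raters_give_perfect_agreement(self):
        r = np.column_stack([np.arange(10.0, 20.0)] * 2)
        icc, p = icc_single(r)
        assert icc == pytest.approx(1.0)

    def test_recovers_variance_ratio_from_simulation(self):
        rng = np.random.default_rng(5)
        subject = rng.normal(0, 1.0, 500)
        ratings = np.column_stack([
            10 + subject + rng.normal(0, 0.5, 500),
            10 + subject + rng.normal(0, 0.5, 500),
        ])
        icc, p = icc_single(ratings)
        assert icc == pytest.approx(0.8, abs=0.05)  # sigma_s^2/(sigma_s^2+sigma_e^2)
        assert p < 0.01

    def test_rater_permutation_invariance(self):
        rng = np.random.default_rng(6)
        r = rng.normal(10, 2, (20, 3))
        icc_a, _ = icc_single(r)
        icc_b, _ = icc_single(r[:, [2, 0, 1]])
        assert icc_b == pytest.approx(icc_a, abs=1e-12)

    def test_zero_case_variance_is_degenerate(self):
        r = np.ones((10, 2))
        icc, p = icc_single(r)
        assert np.isnan(icc) and np.isnan(p)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ParameterError):
            icc_single(np.ones((3, 2)))


class TestBlandAltman:
    def test_identical_methods_have_zero_bias_and_limits(self):
        x = np.linspace(2, 5, 10)
        ba = bland_altman(x, x)
        assert ba.bias == 0.0 and ba.lo == 0.0 and ba.hi == 0.0

    def test_constant_two_percent_offset(self):
        x = np.full(10, 10.0)
        ba = bland_altman(x, 1.02 * x)
        assert ba.bias == pytest.approx(100 * 0.02 / 1.01, rel=1e-9)
        assert ba.lo == pytest.approx(ba.bias) and ba.hi == pytest.approx(ba.bias)

    def test_bias_invariant_under_pair_reordering(self, rng):
        x = rng.uniform(2, 6, 30)
        y = x * rng.uniform(0.9, 1.1, 30)
        perm = rng.permutation(30)
        assert bland_altman(x[perm], y[perm]).bias == pytest.approx(
            bland_altman(x, y).bias, abs=1e-12)

    def test_absolute_mode(self):
        x = np.array([10.0, 10.0, 10.0])
        ba = bland_altman(x, x + 1.0, relative=False)
        assert ba.bias == pytest.approx(1.0)

    def test_fewer_than_three_pairs_rejected(self):
        with pytest.raises(ParameterError, match="3 pairs"):
            bland_altman([1.0, 2.0], [1.0, 2.0])


def test_full_agreement_report_is_self_consistent():
    table = simulate_observer_table(40, seed=9, observer_cv=0.06, ai_cv=0.04)
    rep = agreement_report(table)
    assert set(rep["icc"]) == {"haller", "correction", "asymmetry"}
    for section in rep["icc"].values():
        assert 0 <= section["icc"] <= 1
    for section in rep["bland_altman"].values():
        assert section["lo_pct"] <= section["bias_pct"] <= section["hi_pct"]
    errs = rep["errors"]
    assert errs["pooled_denominator"] == 120
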