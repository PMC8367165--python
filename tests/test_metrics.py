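"""Study metrics: ratios, summaries, robust filtering, rank-sum, trend."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from woundqc.metrics import (
    AssessmentRecord,
    ccdr,
    compliance_ratio,
    duration_trend,
    filter_duration_outliers,
    group_summary,
    per_patient_summaries,
    performed_days,
    rank_sum_test,
)
from woundqc.synthetic import CohortSpec, generate_cohort


def rec(pid="P1", group="feedback", idx=1, detected=True, usable=None,
        ccs=None, duration=None, ts=None):
    return AssessmentRecord(patient_id=pid, group=group, assessment_index=idx,
                            timestamp=ts, checker_detected=detected,
                            usable_label=usable, ccs=ccs, duration_s=duration)


def permutation_pvalue(a, b):
    """Exact two-sided rank-sum p by enumerating group assignments."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1, n = len(a), len(pooled)
    observed = abs(ranks[:n1].sum() - n1 * (n + 1) / 2)
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        if abs(w - n1 * (n + 1) / 2) >= observed - 1e-9:
            hits += 1
        total += 1
    return hits / total


class TestCcdr:
    @pytest.mark.parametrize("detected,total,expected", [
        (191, 199, 0.96),  # feedback arm of the study
        (158, 183, 0.86),  # basic arm
        (0, 50, 0.0),
    ])
    def test_worked_examples(self, detected, total, expected):
        assert round(ccdr(detected, total), 2) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ccdr(1, 0)
        with pytest.raises(ValueError):
            ccdr(5, 4)


class TestGroupSummary:
    def test_detection_flags_to_ccdr(self):
        records = [rec(detected=f) for f in (True, True, True, False)]
        assert group_summary(records, "feedback").ccdr == 0.75

    def test_single_ccs_degenerate_quantiles(self):
        s = group_summary([rec(ccs=700.0)], "feedback")
        assert s.ccs_q25 == s.ccs_median == s.ccs_q75 == 700.0

    def test_usable_ratio_matches_study_arithmetic(self):
        # 199 images of which 180 labeled usable -> 90%
        records = [rec(usable=(i < 180)) for i in range(199)]
        s = group_summary(records, "feedback")
        assert round(s.usable_ratio * 100) == 90

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError, match="no records"):
            group_summary([rec(group="feedback")], "basic")

    def test_quartiles_ordered(self):
        rng = np.random.default_rng(0)
        records = [rec(ccs=float(v)) for v in rng.lognormal(6.8, 0.3, 50)]
        s = group_summary(records, "feedback")
        assert s.ccs_q25 <= s.ccs_median <= s.ccs_q75


class TestPerPatientSummaries:
    def test_single_patient_all_detected(self):
        out = per_patient_summaries([rec(), rec(idx=2)])
        assert len(out) == 1 and out[0].ccdr == 1.0

    def test_group_ccdr_pools_counts_not_patient_means(self):
        records = ([rec(pid="A", detected=True)]
                   + [rec(pid="B", detected=d) for d in (True, False)])
        per = {s.patient_id: s.ccdr for s in per_patient_summaries(records)}
        assert per == {"A": 1.0, "B": 0.5}
        # pooled: 2 detected / 3 images, not mean(1.0, 0.5)
        assert group_summary(records, "feedback").ccdr == pytest.approx(2 / 3)

    def test_matches_pandas_groupby_oracle(self):
        records = generate_cohort(CohortSpec(seed=17))
        df = pd.DataFrame({
            "pid": [r.patient_id for r in records],
            "det": [r.checker_detected for r in records],
            "ccs": [r.ccs for r in records],
        })
        expected_ccdr = df.groupby("pid")["det"].mean()
        expected_med = df.groupby("pid")["ccs"].median()
        for s in per_patient_summaries(records):
            assert s.ccdr == pytest.approx(expected_ccdr[s.patient_id])
            assert s.ccs_median == pytest.approx(expected_med[s.patient_id])


class TestCompliance:
    @pytest.mark.parametrize("performed,assigned,expected", [
        (16, 16, 1.0),
        (20, 16, 1.0),  # more days than assigned -> capped at 1
        (8, 16, 0.5),
        (0, 16, 0.0),
    ])
    def test_ratio_with_cap(self, performed, assigned, expected):
        assert compliance_ratio(performed, assigned) == expected

    def test_zero_assigned_days_undefined(self):
        with pytest.raises(ValueError):
            compliance_ratio(4, 0)

    def test_performed_days_counts_distinct_dates(self):
        records = [rec(ts="2021-03-01T10:00:00"),
                   rec(ts="2021-03-01T10:01:00", idx=1),
                   rec(ts="2021-03-04T09:00:00", idx=2)]
        assert performed_days(records) == 2


class TestDurationOutliers:
    def test_empty_input(self):
        assert filter_duration_outliers([]) == ([], [])

    def test_all_equal_degenerate_mad_keeps_everything(self):
        kept, removed = filter_duration_outliers([40, 40, 40, 40])
        assert kept == [40, 40, 40, 40] and removed == []

    def test_hand_computed_removal(self):
        # median 42, MAD 1, bound 3 * 1.4826 * 1 = 4.45 -> only 400 is out
        kept, removed = filter_duration_outliers([40, 41, 42, 43, 400])
        assert kept == [40, 41, 42, 43]
        assert removed == [400]

    def test_partition_preserves_order_and_multiset(self):
        rng = np.random.default_rng(3)
        data = list(rng.normal(45, 8, 40)) + [400.0, 2.0]
        kept, removed = filter_duration_outliers(data)
        assert sorted(kept + removed) == sorted(data)
        assert kept == [d for d in data if d in kept]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_refilter_removes_no_more_on_symmetric_samples(self, seed):
        rng = np.random.default_rng(seed)
        data = list(rng.normal(50, 5, 60))
        kept, removed = filter_duration_outliers(data)
        kept2, removed2 = filter_duration_outliers(kept)
        assert len(removed2) <= len(removed)


class TestRankSum:
    def test_exchangeable_samples_near_null(self):
        a = [3, 1, 5, 2, 4]
        b = [1, 2, 3, 4, 5]
        res = rank_sum_test(a, b)
        assert abs(res.statistic) < 0.1
        assert res.p_value > 0.9

    def test_separated_samples_reject_by_exact_oracle(self):
        a = list(range(1, 9))
        b = [x + 100 for x in a]
        res = rank_sum_test(a, b)
        assert res.p_value < 0.01
        assert permutation_pvalue(np.array(a, float), np.array(b, float)) < 0.01

    def test_close_to_exact_permutation_p_on_small_samples(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n1, n2 = rng.integers(3, 8, size=2)
            a = rng.normal(0, 1, n1)
            b = rng.normal(rng.uniform(-1.5, 1.5), 1, n2)
            approx = rank_sum_test(a, b).p_value
            exact = permutation_pvalue(a, b)
            assert abs(approx - exact) <= 0.02

    def test_swap_flips_sign_and_keeps_p(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 10)
        r1, r2 = rank_sum_test(a, b), rank_sum_test(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_agrees_with_scipy_asymptotic(self):
        rng = np.random.default_rng(5)
        a = np.round(rng.normal(50, 5, 30), 0)  # rounding induces ties
        b = np.round(rng.normal(54, 5, 25), 0)
        mine = rank_sum_test(a, b).p_value
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic").pvalue
        assert mine == pytest.approx(ref, rel=1e-9)

    def test_identical_constant_samples(self):
        res = rank_sum_test([5, 5, 5], [5, 5])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestDurationTrend:
    def test_constant_durations_have_zero_slope(self):
        fit = duration_trend([(i, 45.0) for i in range(1, 6)])
        assert fit.slope == pytest.approx(0.0)
        assert fit.intercept == pytest.approx(45.0)

    def test_two_point_line(self):
        fit = duration_trend([(1, 60.0), (2, 50.0)])
        assert fit.slope == pytest.approx(-10.0)
        assert fit.intercept == pytest.approx(70.0)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(9)
        x = np.arange(1, 17, dtype=float)
        y = 52 - 0.5 * x + rng.normal(0, 3, x.size)
        fit = duration_trend(list(zip(x, y)))
        beta = np.cov(x, y, bias=True)[0, 1] / np.var(x)
        assert fit.slope == pytest.approx(beta)
        assert fit.intercept == pytest.approx(y.mean() - beta * x.mean())

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            duration_trend([(1, 60.0)])
        with pytest.raises(ValueError):
            duration_trend([(1, 60.0), (1, 50.0)])


def test_records_validate_their_fields():
    with pytest.raises(ValueError):
        rec(group="control")
    with pytest.raises(ValueError):
        rec(idx=0)
    with pytest.raises(ValueError):
        rec(duration=-3.0)
    with pytest.raises(ValueError):
        rec(ccs=-1.0)
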