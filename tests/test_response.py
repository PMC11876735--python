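"""Tumor size change statistics, dose-response, and toxicity flags."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prrtdose.response import (
    ToxicityThresholds,
    TumorMeasurement,
    best_change,
    diameter_change_pct,
    dose_response_association,
    incidence_proportion,
    renal_decline_rate,
    shrinkage_fraction,
    size_change_pct,
    summarize_cohort,
    threshold_flags,
)


def meas(L, W, week=12, node=False, lid="t"):
    return TumorMeasurement(lid, week, L, W, is_lymph_node=node)


class TestSizeChange:
    def test_identity_is_zero(self):
        assert size_change_pct(400.0, 400.0) == 0.0

    def test_reduction(self):
        assert size_change_pct(300.0, 400.0) == pytest.approx(-25.0)

    def test_doubling(self):
        assert size_change_pct(800.0, 400.0) == pytest.approx(100.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            size_change_pct(100.0, 0.0)

    @given(scale=st.floats(0.1, 10.0), L=st.floats(5.0, 100.0),
           ratio=st.floats(0.3, 1.0), change=st.floats(-0.9, 2.0))
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance(self, scale, L, ratio, change):
        """Rescaling both axes at all times leaves the percentage unchanged."""
        W = L * ratio
        base_area = L * W
        t_area = base_area * (1 + change)
        a = size_change_pct(t_area, base_area)
        b = size_change_pct(t_area * scale**2, base_area * scale**2)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-9)


class TestBestChange:
    def test_greatest_reduction(self):
        assert best_change([(12, 10.0), (24, -20.0), (36, -5.0)]) == -20.0

    def test_lowest_increase_when_never_shrinking(self):
        assert best_change([(12, 10.0), (24, 4.0)]) == 4.0

    def test_single_point(self):
        assert best_change([(12, -3.6)]) == -3.6

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            best_change([])

    @given(st.lists(st.floats(-90.0, 300.0), min_size=1, max_size=7))
    @settings(max_examples=50, derandomize=True)
    def test_best_is_lower_bound_of_series(self, changes):
        series = list(enumerate(changes))
        bc = best_change(series)
        assert all(bc <= c for c in changes)


class TestDiameterChange:
    def test_node_uses_short_axis(self):
        assert diameter_change_pct(
            meas(15.0, 8.0, node=True), meas(15.0, 10.0, week=0, node=True)
        ) == pytest.approx(-20.0)

    def test_non_node_uses_long_axis(self):
        assert diameter_change_pct(
            meas(25.0, 10.0), meas(20.0, 10.0, week=0)
        ) == pytest.approx(25.0)

    def test_node_ignores_long_axis_change(self):
        assert diameter_change_pct(
            meas(30.0, 10.0, node=True), meas(20.0, 10.0, week=0, node=True)
        ) == 0.0

    def test_sign_agrees_with_area_for_proportional_axes(self):
        base = meas(40.0, 25.0, week=0)
        shrunk = meas(40.0 * 0.8, 25.0 * 0.8)
        area = size_change_pct(shrunk.area, base.area)
        diam = diameter_change_pct(shrunk, base)
        assert area < 0 and diam < 0


class TestShrinkageFraction:
    def test_study_count_structure_above_floor(self):
        lesions = [(-10.0, 100.0)] * 35 + [(5.0, 80.0)] * 3 + [(-5.0, 20.0)] * 14
        n, total, pct = shrinkage_fraction(lesions, dose_floor=50.0)
        assert (n, total, pct) == (35, 38, 92)

    def test_overall_structure_without_floor(self):
        lesions = [(-10.0, 100.0)] * 47 + [(5.0, 80.0)] * 5
        assert shrinkage_fraction(lesions) == (47, 52, 90)

    def test_small_cohort_rounding(self):
        lesions = [(-1.0, 60.0), (-2.0, 70.0), (3.0, 80.0)]
        assert shrinkage_fraction(lesions)[2] == 67

    def test_empty_after_filter_rejected(self):
        with pytest.raises(ValueError):
            shrinkage_fraction([(-1.0, 10.0)], dose_floor=50.0)


def brute_force_spearman(x, y):
    """Rank correlation from the definition, with mid-ranks for ties."""
    def midranks(v):
        v = np.asarray(v, float)
        ranks = np.empty_like(v)
        order = np.argsort(v, kind="stable")
        sv = v[order]
        i = 0
        while i < len(sv):
            j = i
            while j < len(sv) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j - 1) / 2.0 + 1.0
            i = j
        return ranks
    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean(); ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


class TestDoseResponse:
    def test_perfectly_monotone_decreasing(self):
        pairs = [(10.0, 5.0), (50.0, -5.0), (100.0, -20.0), (300.0, -40.0)]
        res = dose_response_association(pairs)
        assert res.rho == pytest.approx(-1.0)

    def test_tied_doses_match_brute_force_midranks(self):
        rng = np.random.default_rng(2)
        doses = np.round(rng.uniform(0, 5, size=30))  # many ties
        changes = rng.normal(size=30)
        res = dose_response_association(list(zip(doses, changes)))
        assert res.rho == pytest.approx(brute_force_spearman(doses, changes), rel=1e-10)

    def test_independent_pairs_rarely_look_correlated(self):
        """Null |rho| stays below 0.28 for n=52 in at least 95% of seeds."""
        rng = np.random.default_rng(0)
        n_ok = 0
        trials = 1000
        for _ in range(trials):
            doses = rng.lognormal(4.0, 1.0, size=52)
            changes = rng.normal(-20.0, 15.0, size=52)
            res = dose_response_association(list(zip(doses, changes)))
            n_ok += abs(res.rho) < 0.28
        assert n_ok / trials >= 0.95

    def test_constant_vector_flagged_undefined(self):
        res = dose_response_association([(50.0, -1.0), (50.0, -2.0), (50.0, 3.0)])
        assert res.undefined and np.isnan(res.rho)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            dose_response_association([(1.0, 2.0), (3.0, 4.0)])


class TestRenalDecline:
    def test_two_point_slope_hits_threshold(self):
        slope, flag = renal_decline_rate([0.0, 0.5], [100.0, 90.0])
        assert slope == pytest.approx(-20.0) and flag

    def test_constant_series_not_flagged(self):
        slope, flag = renal_decline_rate([0.0, 1.0, 2.0], [80.0, 80.0, 80.0])
        assert slope == 0.0 and not flag

    def test_noisy_mild_decline_recovered_not_flagged(self):
        rng = np.random.default_rng(6)
        t = np.arange(0, 3.1, 0.25)
        crcl = 100.0 * (1 - 0.10 * t) * rng.lognormal(0, 0.02, size=t.size)
        slope, flag = renal_decline_rate(t, crcl)
        assert slope == pytest.approx(-10.0, abs=3.0)
        assert not flag

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            renal_decline_rate([0.0, 1.0], [0.0, 10.0])


class TestThresholdFlags:
    def test_below_thresholds_unflagged(self):
        flags = threshold_flags(19.4, 1.0)
        assert not flags["kidney"] and not flags["marrow"]

    def test_kidney_28Gy_flagged(self):
        assert threshold_flags(28.0, 1.0)["kidney"]

    def test_marrow_3p2Gy_flagged(self):
        assert threshold_flags(10.0, 3.2)["marrow"]

    def test_exact_threshold_not_flagged(self):
        flags = threshold_flags(23.0, 2.0)
        assert not flags["kidney"] and not flags["marrow"]


class TestIncidence:
    @pytest.mark.parametrize(
        "events,n,expected", [(3, 133, 2.3), (0, 50, 0.0), (50, 50, 100.0)]
    )
    def test_rounded_percent(self, events, n, expected):
        assert incidence_proportion(events, n) == expected

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            incidence_proportion(0, 0)


class TestSummarizeCohort:
    def test_basic_statistics(self):
        s = summarize_cohort([10.0, 20.0, 30.0])
        assert (s.mean, s.sd, s.median, s.min, s.max) == (20.0, 10.0, 20.0, 10.0, 30.0)

    def test_single_value_flagged(self):
        s = summarize_cohort([5.0])
        assert s.sd == 0.0 and s.single_value

    def test_matches_brute_force_formulas(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=37)
        s = summarize_cohort(x)
        mean = sum(x) / len(x)
        sd = (sum((v - mean) ** 2 for v in x) / (len(x) - 1)) ** 0.5
        assert s.mean == pytest.approx(mean, rel=1e-12)
        assert s.sd == pytest.approx(sd, rel=1e-12)
        assert s.min <= s.median <= s.max

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])


def test_measurement_invariants():
    with pytest.raises(ValueError):
        TumorMeasurement("x", 12, 10.0, 12.0)  # W > L
    with pytest.raises(ValueError):
        TumorMeasurement("x", 13, 12.0, 10.0)  # off-grid week
    with pytest.raises(ValueError):
        ToxicityThresholds(kidney_course=0.0)
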