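"""CGM outcome metrics against closed-form and brute-force oracles."""

import itertools

import numpy as np
import pytest

from postmeal.metrics import (
    cohort_summarize,
    detect_hypoglycemia,
    excursions_30min,
    incremental_auc,
    mage,
    mean_glucose,
    peak_glucose,
    summarize,
    time_in_ranges,
    total_auc,
)
from postmeal.trace import GlucoseTrace

from conftest import GRID, make_trace, random_trace


class TestMeanGlucose:
    def test_symmetric_mean(self):
        tr = make_trace([6.0, 8.0, 10.0])
        assert mean_glucose(tr, 0, 30) == pytest.approx(8.0)

    def test_constant(self, constant_trace):
        assert mean_glucose(constant_trace, 45, 180) == 7.0

    def test_ramp_full_window(self, ramp_trace):
        assert mean_glucose(ramp_trace, 0, 300) == pytest.approx(8.0)

    def test_closed_interval_includes_endpoints(self, ramp_trace):
        # reading at 120 belongs to both the 0-120 and the 120-240 window
        lo = mean_glucose(ramp_trace, 0, 120)
        hi = mean_glucose(ramp_trace, 120, 240)
        v120 = ramp_trace.value_at(120)
        assert lo == pytest.approx(np.mean(ramp_trace.values[:9]))
        assert hi == pytest.approx(np.mean(ramp_trace.values[8:17]))
        assert v120 <= hi and v120 >= lo

    def test_empty_window_rejected(self, constant_trace):
        with pytest.raises(ValueError):
            mean_glucose(constant_trace, 301, 310)


class TestPeak:
    def test_unique_max(self):
        tr = make_trace([6, 9, 12, 8], times=[0, 60, 120, 180])
        assert peak_glucose(tr) == (12.0, 120.0)

    def test_tie_goes_to_earliest(self):
        tr = make_trace([6, 10, 10], times=[0, 60, 120])
        assert peak_glucose(tr) == (10.0, 60.0)

    def test_baseline_excluded_on_decreasing_trace(self):
        tr = make_trace([10, 9, 8, 7], times=[0, 15, 30, 45])
        assert peak_glucose(tr) == (9.0, 15.0)


class TestAuc:
    def test_constant_rectangle(self, constant_trace):
        assert total_auc(constant_trace, 300) == pytest.approx(2100.0)

    def test_ramp_trapezoid(self, ramp_trace):
        assert total_auc(ramp_trace, 300) == pytest.approx(2400.0)

    def test_single_interval(self):
        tr = make_trace([6.0, 8.0], times=[0, 15])
        assert total_auc(tr, 15) == pytest.approx(105.0)

    def test_t_end_off_trace_rejected(self, constant_trace):
        with pytest.raises(ValueError):
            total_auc(constant_trace, 299)

    def test_agrees_with_fine_riemann_sum(self, ramp_trace):
        # piecewise-linear, so a fine midpoint Riemann sum is exact too
        t_fine = np.linspace(0, 300, 300001)
        v_fine = np.interp(t_fine, ramp_trace.times, ramp_trace.values)
        riemann = float(np.sum(0.5 * (v_fine[1:] + v_fine[:-1]) * np.diff(t_fine)))
        assert total_auc(ramp_trace, 300) == pytest.approx(riemann, rel=1e-9)


class TestIncrementalAuc:
    def test_constant_is_zero(self, constant_trace):
        for policy in ("net", "positive_only"):
            assert incremental_auc(constant_trace, 300, policy) == 0.0

    def test_ramp_triangle(self, ramp_trace):
        assert incremental_auc(ramp_trace, 300, "net") == pytest.approx(600.0)

    def test_v_trace_below_baseline(self):
        tr = make_trace([6, 4, 6], times=[0, 150, 300])
        assert incremental_auc(tr, 300, "net") == pytest.approx(-300.0)
        assert incremental_auc(tr, 300, "positive_only") == 0.0

    def test_crossing_interpolation(self):
        # one segment from +1 to -1 crosses baseline midway
        tr = make_trace([5, 6, 4], times=[0, 15, 30])
        pos = incremental_auc(tr, 30, "positive_only")
        # ramp up 0->1 over 15 min (7.5) plus triangle 1->0 over 7.5 min (3.75)
        assert pos == pytest.approx(7.5 + 3.75)

    def test_net_identity_and_policy_order_on_random_traces(self):
        rng = np.random.default_rng(11)
        for _ in range(150):
            tr = random_trace(rng)
            t_end = tr.t_end
            net = incremental_auc(tr, t_end, "net")
            pos = incremental_auc(tr, t_end, "positive_only")
            assert net == pytest.approx(total_auc(tr, t_end) - tr.g0 * t_end, abs=1e-8)
            assert pos >= net - 1e-12
            if np.all(tr.values >= tr.g0):
                assert pos == pytest.approx(net)

    def test_positive_policy_monotone_in_t_end(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            tr = random_trace(rng, n_min=6)
            vals = [incremental_auc(tr, t, "positive_only") for t in tr.times[1:]]
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestRanges:
    def test_direct_count(self):
        tr = make_trace([3.5, 5, 11, 7])
        assert time_in_ranges(tr) == pytest.approx((50.0, 25.0, 25.0))

    def test_constant_in_range(self):
        tr = make_trace([6.5] * 5)
        assert time_in_ranges(tr) == (100.0, 0.0, 0.0)

    def test_boundary_reading_counts_in_range(self):
        tr = make_trace([10.0, 10.0])
        tir, tar, tbr = time_in_ranges(tr)
        assert (tir, tar) == (100.0, 0.0)

    def test_sums_to_100_on_random_traces(self):
        rng = np.random.default_rng(13)
        for _ in range(150):
            tir, tar, tbr = time_in_ranges(random_trace(rng))
            assert tir + tar + tbr == pytest.approx(100.0, abs=1e-9)

    def test_invalid_bounds(self, constant_trace):
        with pytest.raises(ValueError):
            time_in_ranges(constant_trace, low=10.0, high=3.9)


class TestHypoglycemia:
    def test_single_reading_episode(self):
        v = np.full(21, 6.0)
        v[3] = 3.5  # t = 45
        eps = detect_hypoglycemia(make_trace(v))
        assert len(eps) == 1
        assert eps[0].onset_min == 45.0
        assert eps[0].end_min == 45.0
        assert eps[0].nadir_mmol_l == 3.5

    def test_no_episode_at_threshold(self):
        assert detect_hypoglycemia(make_trace(np.full(21, 3.9))) == []

    def test_two_separated_runs(self):
        v = np.full(21, 6.0)
        v[4:6] = 3.0  # t = 60, 75
        v[12] = 3.8  # t = 180
        eps = detect_hypoglycemia(make_trace(v))
        assert [(e.onset_min, e.end_min) for e in eps] == [(60.0, 75.0), (180.0, 180.0)]

    def test_count_matches_brute_force_run_scan(self):
        rng = np.random.default_rng(14)
        for _ in range(150):
            tr = random_trace(rng)
            expected = sum(
                1 for below, _ in itertools.groupby(tr.values < 3.9) if below
            )
            assert len(detect_hypoglycemia(tr)) == expected


class TestExcursions:
    def test_constant_all_zero(self, constant_trace):
        assert np.allclose(excursions_30min(constant_trace), 0.0)

    def test_uniform_ramp(self, ramp_trace):
        d = excursions_30min(ramp_trace)
        assert d.shape == (10,)
        assert np.allclose(d, 0.4)

    def test_first_difference(self):
        tr = make_trace([6, 7, 8], times=[0, 15, 30])
        assert excursions_30min(tr)[0] == pytest.approx(2.0)

    def test_missing_grid_point_rejected(self):
        tr = make_trace([6, 7, 8], times=[0, 15, 45])  # no reading at 30
        with pytest.raises(ValueError):
            excursions_30min(tr)


def brute_force_mage(values):
    """Independent turning-point scan used as the MAGE oracle."""
    v = np.asarray(values, dtype=float)
    sd = np.std(v, ddof=1)
    dedup = [v[0]]
    for x in v[1:]:
        if x != dedup[-1]:
            dedup.append(x)
    ext = [dedup[0]] + [
        dedup[i]
        for i in range(1, len(dedup) - 1)
        if (dedup[i] > dedup[i - 1]) != (dedup[i + 1] > dedup[i])
    ] + ([dedup[-1]] if len(dedup) > 1 else [])
    amps = [b - a for a, b in zip(ext, ext[1:])]
    qual = [a for a in amps if abs(a) > sd]
    if not qual:
        return 0.0
    sign = 1.0 if qual[0] > 0 else -1.0
    chosen = [abs(a) for a in qual if (a > 0) == (sign > 0)]
    return float(np.mean(chosen))


class TestMage:
    def test_constant_is_zero(self, constant_trace):
        assert mage(constant_trace) == 0.0

    def test_sampled_sine(self):
        v = 8.0 + 2.0 * np.sin(2 * np.pi * GRID / 150.0)
        tr = make_trace(v)
        assert mage(tr) == pytest.approx(2.536151, abs=1e-5)
        assert mage(tr) == pytest.approx(brute_force_mage(v))

    def test_single_rise_then_flat(self):
        v = np.array([6.0, 8.0, 10.0, 12.0, 12.0, 12.0])
        assert mage(make_trace(v)) == pytest.approx(6.0)

    def test_matches_brute_force_on_random_traces(self):
        rng = np.random.default_rng(15)
        for _ in range(150):
            tr = random_trace(rng)
            assert mage(tr) == pytest.approx(brute_force_mage(tr.values))

    def test_shift_invariance_and_positive_scaling(self):
        rng = np.random.default_rng(16)
        for _ in range(100):
            tr = random_trace(rng)
            shifted = make_trace(tr.values + 5.0, times=tr.times)
            scaled = make_trace(tr.values * 2.0, times=tr.times)
            assert mage(shifted) == pytest.approx(mage(tr), abs=1e-9)
            assert mage(scaled) == pytest.approx(2.0 * mage(tr), abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mage(make_trace([6.0, 7.0], times=[0, 15]))


class TestSummarize:
    def test_constant_trace(self, constant_trace):
        s = summarize(constant_trace)
        assert s.peak == 7.0
        assert s.delta_peak == 0.0
        assert s.delta_low == 0.0
        assert all(v == 0.0 for v in s.iauc.values())
        assert s.tir_pct == 100.0
        assert s.episodes == []

    def test_ramp_trace_matches_component_oracles(self, ramp_trace):
        s = summarize(ramp_trace)
        assert s.peak == pytest.approx(10.0)
        assert s.time_to_peak == 300.0
        assert s.auc_total == pytest.approx(2400.0)
        assert s.iauc[300] == pytest.approx(600.0)
        assert s.means[(0, 120)] == pytest.approx(6.8)
        assert s.delta_peak == pytest.approx(4.0)
        assert s.scalars()["excursion_270_300"] == pytest.approx(0.4)

    def test_dip_gives_episode_and_below_range_time(self):
        v = np.full(21, 6.0)
        v[10] = 3.2
        s = summarize(make_trace(v))
        assert s.episodes and s.tbr_pct > 0


class TestCohort:
    def test_identical_traces_have_zero_se(self, constant_trace):
        a = make_trace(constant_trace.values, subject_id="S01", arm="NPM-CC")
        b = make_trace(constant_trace.values, subject_id="S02", arm="NPM-CC")
        cohort = cohort_summarize([a, b])
        assert (cohort.metrics[("NPM-CC", "se")].fillna(0) == 0).all()
        assert cohort.metrics.loc["peak_glucose", ("NPM-CC", "mean")] == 7.0

    def test_known_mean_and_se(self):
        a = make_trace(np.full(21, 6.0), subject_id="S01", arm="NPM-CC")
        b = make_trace(np.full(21, 8.0), subject_id="S02", arm="NPM-CC")
        cohort = cohort_summarize([a, b])
        assert cohort.metrics.loc["fasting_glucose", ("NPM-CC", "mean")] == 7.0
        # SE = sample SD / sqrt(n) = sqrt(2)/sqrt(2) = 1
        assert cohort.metrics.loc["fasting_glucose", ("NPM-CC", "se")] == pytest.approx(1.0)

    def test_single_trace_arm_rejected(self, constant_trace):
        with pytest.raises(ValueError):
            cohort_summarize([constant_trace])


class TestTraceValidation:
    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError):
            GlucoseTrace(times=np.array([15.0, 30.0]), values=np.array([6.0, 7.0]))

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            GlucoseTrace(times=np.array([0.0, 15.0, 15.0]), values=np.array([6.0, 7.0, 8.0]))

    def test_non_positive_glucose_rejected(self):
        with pytest.raises(ValueError):
            GlucoseTrace(times=np.array([0.0, 15.0]), values=np.array([6.0, -1.0]))
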