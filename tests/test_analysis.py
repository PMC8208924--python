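"""Reward-rate signals, leave-time detection, analytic optimum, metrics."""

import numpy as np
import pytest

from patchforage import (
    GainFunction,
    analytic_optimal_residence,
    compute_arr,
    compute_crr,
    compute_foraging_metrics,
    compute_ltd,
    detect_crr_peaks,
    detect_olts,
)
from patchforage.analysis import RewardTimeSeries
from patchforage.records import PatchVisit, extract_visits
from .conftest import harvest_visit_events, make_log


def brute_force_crr(log, window_s):
    """Independent per-sample count of rewards in the trailing window."""
    rt = log.reward_times()
    return np.array(
        [
            sum(1 for r in rt if s.t - window_s < r <= s.t) / window_s
            for s in log.samples
        ]
    )


class TestCRR:
    def test_single_reward_occupies_one_window(self):
        log = make_log(harvest_visit_events(9.0, [10.0], 30.0), duration=40.0)
        crr = compute_crr(log, 9.0)
        inside = (crr.times >= 10.0) & (crr.times < 19.0)
        assert np.allclose(crr.values[inside], 1.0 / 9.0)
        assert np.all(crr.values[crr.times < 10.0] == 0.0)
        assert np.all(crr.values[crr.times >= 19.0] == 0.0)

    def test_no_rewards_gives_zero_signal(self):
        crr = compute_crr(make_log([], duration=20.0), 5.0)
        assert np.all(crr.values == 0.0)

    def test_steady_stream_matches_brute_force_count(self):
        rewards = list(np.arange(0.5, 40.0, 0.5))
        log = make_log(harvest_visit_events(0.25, rewards, 40.0), duration=40.0)
        crr = compute_crr(log, 9.0)
        assert np.allclose(crr.values, brute_force_crr(log, 9.0))
        after = crr.values[crr.times >= 9.0]
        assert abs(after.mean() - 2.0) < 0.07

    def test_nonpositive_window_raises(self, giveup_log):
        with pytest.raises(ValueError):
            compute_crr(giveup_log, 0.0)

    def test_integral_equals_total_rewards(self, giveup_log):
        # each reward contributes 1/W over W seconds (interior case)
        crr = compute_crr(giveup_log, 9.0)
        total = len(giveup_log.reward_times())
        assert abs(np.trapezoid(crr.values, crr.times) - total) < 0.05 * total + 0.5


class TestARR:
    def test_cumulative_average(self):
        rewards = [5.0, 20.0, 40.0, 70.0, 90.0]
        log = make_log(harvest_visit_events(1.0, rewards, 99.0), duration=100.0)
        arr = compute_arr(log)
        at_100 = arr.values[np.searchsorted(arr.times, 100.0)]
        assert at_100 == pytest.approx(0.05)
        assert arr.values[0] == 0.0

    def test_product_with_time_recovers_cumulative_count(self, giveup_log):
        arr = compute_arr(giveup_log)
        rt = np.asarray(giveup_log.reward_times())
        counts = np.searchsorted(rt, arr.times, side="right")
        assert np.allclose(arr.values * arr.times, counts)

    def test_uniform_stream_converges_to_rate(self):
        rewards = list(np.arange(0.5, 199.9, 0.5))
        log = make_log(harvest_visit_events(0.25, rewards, 199.95), duration=200.0)
        arr = compute_arr(log)
        assert arr.values[-1] == pytest.approx(2.0, rel=0.01)


def series(times, values, kind="CRR", window_s=1.0):
    return RewardTimeSeries(np.asarray(times, float), np.asarray(values, float), kind, window_s)


class TestPeaks:
    def test_simple_peak(self):
        crr = series([0, 1, 2, 3], [0, 1, 2, 1])
        visit = PatchVisit(0, 0.0, 3.0, 1)
        assert detect_crr_peaks(crr, visit) == [2.0]

    def test_monotone_signal_has_no_peak(self):
        crr = series([0, 1, 2, 3], [0, 1, 1, 2])
        assert detect_crr_peaks(crr, PatchVisit(0, 0.0, 3.0, 1)) == []

    def test_plateau_peak_reports_first_sample(self):
        crr = series([0, 1, 2, 3, 4], [0, 2, 2, 2, 1])
        assert detect_crr_peaks(crr, PatchVisit(0, 0.0, 4.0, 1)) == [1.0]

    def test_two_bumps_match_exhaustive_scan(self, rng):
        t = np.arange(0.0, 30.0, 0.5)
        v = np.round(np.sin(t / 3.0) + np.sin(t / 1.3) + 2.0, 3)
        crr = series(t, v)
        visit = PatchVisit(0, 0.0, 29.5, 1)
        got = detect_crr_peaks(crr, visit)
        # oracle: exhaustive scan for strict local maxima w/ plateau-first rule
        expected = []
        i = 1
        while i < len(v) - 1:
            j = i
            while j + 1 < len(v) and v[j + 1] == v[i]:
                j += 1
            if v[i] > v[i - 1] and j < len(v) - 1 and v[j + 1] < v[i]:
                expected.append(t[i])
            i = max(j, i) + 1
        assert got == expected and len(got) >= 2


class TestOLTs:
    def test_linear_interpolation_of_crossing(self):
        t = [10.0, 11.0, 12.0, 13.0, 14.0]
        crr = series(t, [0.5, 2.0, 1.0, 0.6, 0.5])
        arr = series(t, [0.8] * 5, kind="ARR")
        olts = detect_olts(crr, arr, peaks=[11.0], search_end=14.0)
        assert olts == [pytest.approx(12.5)]

    def test_no_crossing_when_crr_stays_below_arr(self):
        t = [0.0, 1.0, 2.0]
        crr = series(t, [0.1, 0.3, 0.2])
        arr = series(t, [0.8] * 3, kind="ARR")
        assert detect_olts(crr, arr, peaks=[1.0], search_end=2.0) == []

    def test_matches_brute_force_pair_scan(self):
        t = np.arange(0.0, 40.0, 0.25)
        crr_v = np.maximum(0.0, np.sin(t / 4.0)) + 0.4
        arr_v = np.full_like(t, 0.9)
        crr, arr = series(t, crr_v), series(t, arr_v, kind="ARR")
        peaks = [float(t[np.argmax(crr_v)])]
        got = detect_olts(crr, arr, peaks, search_end=40.0)
        d = crr_v - arr_v
        expected = None
        i0 = int(np.searchsorted(t, peaks[0]))
        for i in range(i0, len(t) - 1):
            if d[i] > 0 and d[i + 1] <= 0:
                expected = t[i] + d[i] * (t[i + 1] - t[i]) / (d[i] - d[i + 1])
                break
        assert got == [pytest.approx(expected)]

    def test_shared_crossing_collapses_to_one_olt(self):
        t = np.arange(0.0, 10.0, 1.0)
        crr_v = np.array([0.0, 1.0, 0.9, 1.1, 0.8, 0.4, 0.3, 0.2, 0.1, 0.0])
        arr_v = np.full_like(t, 0.5)
        olts = detect_olts(series(t, crr_v), series(t, arr_v, "ARR"), [1.0, 3.0], 10.0)
        assert len(olts) == 1


class TestComputeLTD:
    def test_zero_reward_run_has_no_score(self):
        log = make_log(harvest_visit_events(5.0, [], 15.0), duration=30.0)
        res = compute_ltd(log, 9.0)
        assert res.participant_ltd is None and res.n_excluded == len(res.per_visit)

    def test_censored_visit_excluded(self):
        log = make_log([(290.0, "patch_enter", 0)], duration=300.0)
        res = compute_ltd(log, 9.0)
        assert res.per_visit[0].ltd is None

    def test_ltd_is_olt_minus_alt(self):
        rewards = list(np.arange(10.5, 20.0, 0.8))
        log = make_log(harvest_visit_events(10.0, rewards, 26.0), duration=60.0)
        res = compute_ltd(log, 9.0)
        for v in res.per_visit:
            if v.ltd is not None:
                assert v.ltd == pytest.approx(v.olt - v.alt)


class TestAnalyticOptimum:
    @pytest.mark.parametrize("A", [20.0, 40.0, 60.0])
    @pytest.mark.parametrize("lam", [0.05, 0.1, 0.2])
    @pytest.mark.parametrize("travel", [10.0, 20.0, 40.0])
    def test_matches_grid_maximization(self, A, lam, travel):
        f = GainFunction(A, lam)
        T = analytic_optimal_residence(f, travel)
        grid = np.arange(1e-4, 200.0, 1e-4)
        T_brute = grid[np.argmax(f(grid) / (travel + grid))]
        assert abs(T - T_brute) < 1e-3

    def test_longer_travel_increases_residence(self):
        f = GainFunction(40.0, 0.1)
        assert analytic_optimal_residence(f, 40.0) > analytic_optimal_residence(f, 20.0)

    def test_instant_saturation_drives_residence_to_zero(self):
        f = GainFunction(40.0, 50.0)
        assert analytic_optimal_residence(f, 20.0) < 0.2

    def test_invalid_gain_rejected(self):
        with pytest.raises(ValueError):
            GainFunction(-1.0, 0.1)


class TestForagingMetrics:
    def test_repeat_visits_halve_unique_ratio(self):
        events = harvest_visit_events(5.0, [6.0], 10.0, patch_id=3) + harvest_visit_events(
            20.0, [], 30.0, patch_id=3
        )
        m = compute_foraging_metrics(make_log(events, duration=40.0))
        assert m["unique_total_patch_ratio"] == 0.5
        assert m["total_rewards"] == 1

    def test_median_residence(self):
        events = (
            harvest_visit_events(0.0, [], 10.0, 0)
            + harvest_visit_events(15.0, [], 35.0, 1)
            + harvest_visit_events(40.0, [], 70.0, 2)
        )
        m = compute_foraging_metrics(make_log(events, duration=80.0))
        assert m["median_residence_s"] == 20.0
        assert m["mean_travel_s"] == 5.0
        assert m["time_to_first_patch_s"] == 0.0

    def test_stationary_agent_reveals_one_disk(self):
        log = make_log([], duration=10.0)  # stationary at (300, 300)
        m = compute_foraging_metrics(log)
        analytic = np.pi * 15.0**2 / 360_000.0
        assert m["arena_revealed_fraction"] == pytest.approx(analytic, rel=0.05)

    def test_full_run_metrics_are_populated(self, giveup_log):
        m = compute_foraging_metrics(giveup_log)
        assert 0.0 < m["unique_total_patch_ratio"] <= 1.0
        assert m["arena_revealed_fraction"] > 0.01
        assert m["total_rewards"] == len(giveup_log.reward_times())
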