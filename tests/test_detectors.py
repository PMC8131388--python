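import numpy as np
import pytest

import neobrady as nb
from conftest import random_rr_series
from oracles import oracle_adaptive_levels, oracle_fixed_levels, oracle_ph_levels


def make_series(rr_values):
    rr = np.asarray(rr_values, dtype=float)
    return nb.RRSeries(beat_time=np.cumsum(rr) / 1000.0, rr=rr)


class TestFixedThreshold:
    def test_red_step_detected_at_fifth_slow_beat(self):
        """20 beats at 500 ms then 810 ms: cumulative 4.05 s > 4 s at beat 5."""
        s = make_series([500.0] * 20 + [810.0] * 10)
        trace = nb.detect_fixed(s, nb.RED.fixed)
        assert trace.detections.size >= 1
        # detection at the 5th above-threshold beat (index 24)
        assert trace.detections[0] == pytest.approx(s.beat_time[24])
        assert np.all(trace.level[:24] == 0) and trace.level[24] == 1

    def test_confirmation_clause_blocks_between_thresholds(self):
        """RR forever between U0=750 and U1=800: the 2-occurrence rule fails."""
        s = make_series([760.0] * 100)
        trace = nb.detect_fixed(s, nb.RED.fixed)
        assert trace.detections.size == 0

    def test_constant_fast_series_never_alarms(self):
        s = make_series([500.0] * 200)
        assert nb.detect_fixed(s, nb.RED.fixed).detections.size == 0

    def test_level_releases_on_recovery(self):
        s = make_series([500.0] * 10 + [810.0] * 8 + [500.0] * 10)
        trace = nb.detect_fixed(s, nb.RED.fixed)
        assert trace.level[17] == 1 and np.all(trace.level[18:] == 0)


class TestAdaptiveThreshold:
    def test_detects_step_against_fast_baseline(self):
        """Baseline 375 ms (160 bpm) for 60 s then 810 ms steps.

        U0' ~= 1.33 * 375 = 498.75 ms at the change; the run rule then
        fires at the 5th post-change beat (cumulative 4.05 s, all above
        U1' = 800).
        """
        n_base = int(60.0 / 0.375) + 1
        s = make_series([375.0] * n_base + [810.0] * 10)
        trace = nb.detect_adaptive(s, nb.RED.adaptive)
        assert trace.detections.size == 1
        assert trace.detections[0] == pytest.approx(s.beat_time[n_base + 4])

    def test_constant_series_never_alarms(self):
        for rr in (350.0, 500.0, 700.0):
            s = make_series([rr] * 300)
            assert nb.detect_adaptive(s, nb.RED.adaptive).detections.size == 0

    def test_slow_drift_tracked_without_alarm(self):
        """+0.5 ms/beat drift from 375 ms over ~10 min stays silent."""
        rr = 375.0 + 0.5 * np.arange(1200)
        s = make_series(rr)
        trace = nb.detect_adaptive(
            s, nb.AdaptiveThresholdParams(u1=800.0)
        )
        assert trace.detections.size == 0

    def test_disarmed_during_warmup(self):
        """A slow stretch inside the first 20 s cannot raise the alarm."""
        s = make_series([810.0] * 30)  # record starts bradycardic
        trace = nb.detect_adaptive(s, nb.RED.adaptive)
        in_warmup = s.beat_time < s.beat_time[0] + 20.0
        assert np.all(trace.level[in_warmup] == 0)


class TestPageHinkley:
    def test_stationary_series_never_alarms(self):
        s = make_series([400.0] * 500)
        assert nb.detect_page_hinkley(s, nb.PageHinkleyParams()).detections.size == 0

    def test_step_alarm_at_second_post_step_beat(self):
        """400 -> 1000 ms step: increments ~392 ms/beat, 2 beats >= 717.

        With a long 400 ms history the trailing baseline stays ~400
        through the first post-step beats, so the cumulative sum crosses
        the threshold at the second one.
        """
        n_base = 200
        s = make_series([400.0] * n_base + [1000.0] * 10)
        trace = nb.detect_page_hinkley(s, nb.PageHinkleyParams())
        assert trace.detections.size >= 1
        assert trace.detections[0] == pytest.approx(s.beat_time[n_base + 1])

    def test_step_of_half_nu_is_undetectable(self):
        """A jump of exactly nu/2 gives zero increments: no alarm ever."""
        s = make_series([400.0] * 50 + [607.5] * 50)
        params = nb.PageHinkleyParams(baseline_window=1e6)  # frozen-ish baseline
        trace = nb.detect_page_hinkley(s, params)
        assert trace.detections.size == 0

    def test_level_holds_until_recovery(self):
        s = make_series([400.0] * 200 + [1000.0] * 20 + [400.0] * 20)
        trace = nb.detect_page_hinkley(s, nb.PageHinkleyParams())
        assert trace.detections.size == 1
        k = np.searchsorted(s.beat_time, trace.detections[0])
        assert np.all(trace.level[k : 219 + 1] == 1)  # through the slow stretch
        assert trace.level[220] == 0  # first recovered beat releases


class TestStreamingMatchesOracle:
    """Streaming state machines equal offline per-beat re-scans."""

    @pytest.mark.parametrize("detector", ["fixed", "adaptive", "page_hinkley"])
    def test_on_random_series(self, detector, rng):
        for i in range(30):
            s = random_rr_series(rng, int(rng.integers(50, 200)))
            if detector == "fixed":
                got = nb.detect_fixed(s, nb.RED.fixed).level
                exp = oracle_fixed_levels(s.beat_time, s.rr, 750.0, 800.0)
            elif detector == "adaptive":
                got = nb.detect_adaptive(s, nb.RED.adaptive).level
                exp = oracle_adaptive_levels(s.beat_time, s.rr, u1=800.0)
            else:
                got = nb.detect_page_hinkley(s, nb.PageHinkleyParams()).level
                exp = oracle_ph_levels(s.beat_time, s.rr)
            np.testing.assert_array_equal(got, exp, err_msg=f"{detector} series {i}")


class TestDetectorProperties:
    def test_raising_thresholds_never_detects_earlier(self, rng):
        """Monotonicity: larger U0 (or lambda) => detection no earlier."""
        for _ in range(20):
            s = random_rr_series(rng, 150)
            lo = nb.detect_fixed(s, nb.FixedThresholdParams(u0=700.0, u1=800.0))
            hi = nb.detect_fixed(s, nb.FixedThresholdParams(u0=760.0, u1=800.0))
            if hi.detections.size:
                assert lo.detections.size
                assert lo.detections[0] <= hi.detections[0]
            ph_lo = nb.detect_page_hinkley(s, nb.PageHinkleyParams(lam=500.0))
            ph_hi = nb.detect_page_hinkley(s, nb.PageHinkleyParams(lam=717.0))
            if ph_hi.detections.size:
                assert ph_lo.detections.size
                assert ph_lo.detections[0] <= ph_hi.detections[0]

    def test_causality_under_truncation(self, rng):
        """Truncating the series after beat k never changes level(1..k)."""
        s = random_rr_series(rng, 120)
        full = {
            "fixed": nb.detect_fixed(s, nb.RED.fixed).level,
            "adaptive": nb.detect_adaptive(s, nb.RED.adaptive).level,
            "ph": nb.detect_page_hinkley(s, nb.PageHinkleyParams()).level,
        }
        for k in (10, 40, 80, 119):
            trunc = nb.RRSeries(beat_time=s.beat_time[: k + 1], rr=s.rr[: k + 1])
            assert np.array_equal(
                nb.detect_fixed(trunc, nb.RED.fixed).level, full["fixed"][: k + 1]
            )
            assert np.array_equal(
                nb.detect_adaptive(trunc, nb.RED.adaptive).level,
                full["adaptive"][: k + 1],
            )
            assert np.array_equal(
                nb.detect_page_hinkley(trunc, nb.PageHinkleyParams()).level,
                full["ph"][: k + 1],
            )
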