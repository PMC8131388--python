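import numpy as np
import pytest
from scipy import stats

import neobrady as nb
from oracles import oracle_match

NO_LATENCY = nb.MatchRules(latency_compensation=0.0)


class TestMatching:
    def test_detection_up_to_5s_early_is_tp(self):
        res = nb.match([100.0], [97.0], NO_LATENCY)
        assert len(res.tp) == 1
        assert res.tp[0][2] == pytest.approx(-3.0)
        assert res.fp == [] and res.fn == []

    def test_detection_past_30s_window_is_fp(self):
        res = nb.match([100.0], [131.0], NO_LATENCY)
        assert res.tp == []
        assert res.fp == [131.0]
        assert res.fn == [100.0]

    def test_second_detection_in_window_ignored(self):
        res = nb.match([100.0], [98.0, 105.0], NO_LATENCY)
        assert len(res.tp) == 1 and res.tp[0][1] == pytest.approx(98.0)
        assert res.ignored_detections == [105.0]
        assert res.fp == []

    def test_shared_detection_ignores_second_annotation(self):
        res = nb.match([100.0, 110.0], [108.0], NO_LATENCY)
        assert len(res.tp) == 1 and res.tp[0][0] == pytest.approx(100.0)
        assert res.ignored_annotations == [110.0]
        assert res.fn == []

    def test_unsorted_inputs_rejected(self):
        with pytest.raises(ValueError):
            nb.match([100.0, 50.0], [60.0], NO_LATENCY)

    def test_matches_brute_force_oracle_on_random_inputs(self, rng):
        for _ in range(300):
            n_ann = int(rng.integers(0, 12))
            n_det = int(rng.integers(0, 20))
            ann = np.sort(rng.uniform(0.0, 600.0, n_ann))
            det = np.sort(rng.uniform(0.0, 600.0, n_det))
            got = nb.match(list(ann), list(det), NO_LATENCY)
            tp, fp, fn = oracle_match(list(ann), list(det))
            assert [(a, d) for a, d, _ in got.tp] == tp
            assert got.fp == fp
            assert got.fn == fn

    def test_out_of_window_detection_adds_exactly_one_fp(self, rng):
        ann = [100.0, 200.0, 300.0]
        det = [101.0, 199.0, 305.0]
        base = nb.match(ann, det, NO_LATENCY)
        extra = nb.match(ann, sorted(det + [450.0]), NO_LATENCY)
        assert len(extra.fp) == len(base.fp) + 1
        assert extra.tp == base.tp and extra.fn == base.fn

    def test_latency_compensation_shifts_every_delay(self):
        ann = [100.0, 200.0]
        det = [102.0, 204.0]
        raw = nb.match(ann, det, NO_LATENCY)
        comp = nb.match(ann, det, nb.MatchRules())
        for (_, _, d0), (_, _, d1) in zip(raw.tp, comp.tp):
            assert d1 - d0 == pytest.approx(1.512)

    def test_latency_compensation_flips_status_at_window_edge(self):
        # 104.3 s before onset 100: inside +30 raw; compensated 105.81 -> ok;
        # 129.0 -> compensated 130.51 leaves the window and becomes FP
        res = nb.match([100.0], [129.0], nb.MatchRules())
        assert res.fp == [pytest.approx(130.512)]
        assert nb.match([100.0], [129.0], NO_LATENCY).tp


class TestMetrics:
    def test_percentage_arithmetic(self):
        res = nb.MatchResult(
            tp=[(0.0, 1.0, 1.0), (10.0, 11.0, 1.0)],
            fp=[50.0],
            fn=[70.0],
            ignored_detections=[],
            ignored_annotations=[],
        )
        rep = nb.metrics(res)
        assert rep.sensitivity_pct == pytest.approx(66.7, abs=0.05)
        assert rep.far_pct == pytest.approx(33.3, abs=0.05)

    def test_zero_fp_gives_zero_far(self):
        res = nb.MatchResult(
            tp=[(0.0, 1.0, 1.0)], fp=[], fn=[],
            ignored_detections=[], ignored_annotations=[],
        )
        assert nb.metrics(res).far_pct == 0.0

    def test_delay_mean_and_sample_sd(self):
        res = nb.MatchResult(
            tp=[(0.0, 0.0, -1.0), (0.0, 0.0, 3.0)], fp=[], fn=[],
            ignored_detections=[], ignored_annotations=[],
        )
        rep = nb.metrics(res)
        assert rep.delay_mean_s == pytest.approx(1.0)
        assert rep.delay_sd_s == pytest.approx(2.8284, abs=1e-3)

    def test_empty_denominators_are_nan(self):
        res = nb.MatchResult(tp=[], fp=[], fn=[],
                             ignored_detections=[], ignored_annotations=[])
        rep = nb.metrics(res)
        assert np.isnan(rep.sensitivity_pct) and np.isnan(rep.far_pct)


class TestCompareDelays:
    def test_identical_vectors_degenerate(self):
        stat, p = nb.compare_delays([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert np.isnan(stat) and np.isnan(p)

    def test_constant_shift_highly_significant(self, rng):
        a = rng.normal(10.0, 2.0, 30)
        stat, p = nb.compare_delays(a, a + 3.0)
        assert p < 1e-3

    def test_type_i_error_near_alpha_under_null(self):
        """1000 paired-null replicates: rejection rate ~5 % at alpha=0.05."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(0.0, 1.0, 20)
            b = rng.normal(0.0, 1.0, 20)
            _, p = nb.compare_delays(a, b)
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)

    def test_matches_scipy_directly(self, rng):
        a = rng.normal(10.0, 2.0, 25)
        b = a + rng.normal(0.5, 1.0, 25)
        stat, p = nb.compare_delays(a, b)
        ref = stats.wilcoxon(a, b, alternative="two-sided")
        assert stat == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))


@pytest.fixture(scope="module")
def cohort():
    return nb.simulate_cohort(
        nb.CohortConfig(n_records=8, record_duration=1200.0, seed=42)
    )


class TestBenchmark:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            nb.benchmark([])

    def test_table_shape_and_ranges(self, cohort):
        res = nb.benchmark(cohort)
        table = res.table()
        assert list(table["detector"]) == ["monitor", "fusion"]
        for col in ("sensitivity_pct", "far_pct"):
            vals = table[col].dropna()
            assert ((vals >= 0) & (vals <= 100)).all()
        assert res.n_fused_detections >= 1
        assert sum(res.fusion_fractions.values()) == pytest.approx(100.0, abs=0.1)

    def test_fusion_not_worse_and_earlier(self, cohort):
        """Fusion keeps sensitivity and FAR while detecting earlier."""
        res = nb.benchmark(cohort)
        mon, fus = res.reports
        assert fus.sensitivity_pct >= mon.sensitivity_pct
        assert fus.far_pct <= mon.far_pct + 2.0
        assert fus.delay_mean_s < mon.delay_mean_s
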