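"""Alarm evaluation: annotation/detection matching, metrics, comparison.

The matching protocol:

* a detection is a true positive (TP) when it falls 5 s before to 30 s
  after an annotated event onset; everything else is a false positive;
* when several detections fall in one annotation's window, only the
  first is the TP (the others are ignored, not FPs);
* when one detection matches two annotations, it yields a single TP and
  the second annotation is ignored (not an FN);
* sensitivity = TP/(TP+FN); false alarm rate = FP/(FP+TP);
* the delay is measured from the event's ADJUSTED onset to the detection
  instant, after adding the real-time acquisition/QRS-chain latency
  (1512 ms) to algorithmic detection instants.

Paired delay comparisons between two detectors use the two-sided
Wilcoxon signed-rank test (delays are not normally distributed),
significance level 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .detectors import DetectorConfig, RED, detect_fixed, run_all
from .events import B80_10, BradycardiaDefinition, BradycardiaEvent
from .fusion import attribute_detections, fuse_majority
from .onset import adjust_onset
from .series import RRSeries

__all__ = [
    "MatchRules",
    "MatchResult",
    "EvaluationReport",
    "match",
    "metrics",
    "compare_delays",
    "benchmark",
    "BenchmarkResult",
]


@dataclass(frozen=True)
class MatchRules:
    pre_window: float = 5.0            # s before the onset
    post_window: float = 30.0          # s after the onset
    latency_compensation: float = 1.512  # s added to algorithmic detections

    def __post_init__(self) -> None:
        if self.pre_window < 0 or self.post_window < 0:
            raise ValueError("match windows must be non-negative")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one detector's detections against annotations.

    ``tp`` holds (annotation onset, compensated detection, delay)
    triples; ``ignored_detections`` are extra detections inside an
    already-matched window, ``ignored_annotations`` second annotations
    consumed by a shared detection.
    """

    tp: list[tuple[float, float, float]]
    fp: list[float]
    fn: list[float]
    ignored_detections: list[float]
    ignored_annotations: list[float]

    @property
    def delays(self) -> np.ndarray:
        return np.array([d for _, _, d in self.tp])


def match(
    annotations: list[float],
    detections: list[float],
    rules: MatchRules = MatchRules(),
    compensate: bool = True,
) -> MatchResult:
    """Greedy first-detection-wins matching in time order.

    ``annotations`` are (adjusted) event onsets, ``detections`` raw
    detector instants; with ``compensate`` the latency compensation is
    added to every detection before matching.  Both lists must be
    time-sorted.
    """
    ann = np.asarray(annotations, dtype=float)
    det = np.asarray(detections, dtype=float)
    if np.any(np.diff(ann) < 0) or np.any(np.diff(det) < 0):
        raise ValueError("annotations and detections must be time-sorted")
    if compensate:
        det = det + rules.latency_compensation
    matched = np.zeros(ann.size, dtype=bool)
    ignored_ann = np.zeros(ann.size, dtype=bool)
    tp: list[tuple[float, float, float]] = []
    fp: list[float] = []
    ignored_det: list[float] = []
    for d in det:
        in_window = (ann - rules.pre_window <= d) & (d <= ann + rules.post_window)
        candidates = np.flatnonzero(in_window & ~matched & ~ignored_ann)
        if candidates.size:
            first = candidates[0]
            matched[first] = True
            tp.append((float(ann[first]), float(d), float(d - ann[first])))
            # one detection covering further annotations: they are ignored
            ignored_ann[candidates[1:]] = True
        elif np.any(in_window):
            ignored_det.append(float(d))  # later detection in a matched window
        else:
            fp.append(float(d))
    fn = [float(a) for a in ann[~matched & ~ignored_ann]]
    return MatchResult(
        tp=tp,
        fp=fp,
        fn=fn,
        ignored_detections=ignored_det,
        ignored_annotations=[float(a) for a in ann[ignored_ann]],
    )


@dataclass(frozen=True)
class EvaluationReport:
    """One detector-vs-definition row of a performance table."""

    detector: str
    definition: str
    n_events: int
    n_tp: int
    n_fp: int
    n_fn: int
    sensitivity_pct: float      # nan when no events
    far_pct: float              # nan when no detections
    delay_mean_s: float
    delay_sd_s: float           # nan with < 2 TPs
    p_wilcoxon: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "detector": self.detector,
            "definition": self.definition,
            "n_events": self.n_events,
            "sensitivity_pct": self.sensitivity_pct,
            "far_pct": self.far_pct,
            "delay_mean_s": self.delay_mean_s,
            "delay_sd_s": self.delay_sd_s,
            "p_wilcoxon": self.p_wilcoxon,
        }


def metrics(result: MatchResult, detector: str = "", definition: str = "") -> EvaluationReport:
    """Summary metrics of a match: sensitivity, FAR, delay mean +/- sd."""
    n_tp, n_fp, n_fn = len(result.tp), len(result.fp), len(result.fn)
    sens = 100.0 * n_tp / (n_tp + n_fn) if (n_tp + n_fn) else float("nan")
    far = 100.0 * n_fp / (n_fp + n_tp) if (n_fp + n_tp) else float("nan")
    delays = result.delays
    mean = float(np.mean(delays)) if n_tp else float("nan")
    sd = float(np.std(delays, ddof=1)) if n_tp >= 2 else float("nan")
    return EvaluationReport(
        detector=detector,
        definition=definition,
        n_events=n_tp + n_fn,
        n_tp=n_tp,
        n_fp=n_fp,
        n_fn=n_fn,
        sensitivity_pct=sens,
        far_pct=far,
        delay_mean_s=mean,
        delay_sd_s=sd,
    )


def compare_delays(delays_a, delays_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired delays.

    Returns (statistic, p).  All-zero differences are degenerate (no
    signed ranks exist): returns (nan, nan).
    """
    a = np.asarray(delays_a, dtype=float)
    b = np.asarray(delays_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired delay vectors must have equal length")
    if a.size == 0 or np.allclose(a, b):
        return float("nan"), float("nan")
    res = stats.wilcoxon(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def _adjusted_onsets(record_rr: RRSeries, events: list[BradycardiaEvent]) -> list[float]:
    """Onsets to match against: adjusted when available, else fitted."""
    onsets = []
    for ev in events:
        if ev.onset_adj is not None:
            onsets.append(ev.onset_adj)
        else:
            onsets.append(adjust_onset(record_rr, ev.onset_raw))
    return onsets


@dataclass
class BenchmarkResult:
    """Cohort-level comparison of the fusion detector vs the monitor-like
    fixed-threshold baseline, in the shape of a performance table."""

    reports: list[EvaluationReport]
    paired_delays: dict[str, np.ndarray]  # detector -> delays on common events
    wilcoxon_p: float
    fusion_fractions: dict[tuple[str, ...], float]
    n_fused_detections: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_dict() for r in self.reports])


def benchmark(
    records,
    definition: BradycardiaDefinition = B80_10,
    config: DetectorConfig = RED,
    rules: MatchRules = MatchRules(),
    compensate_monitor: bool = True,
) -> BenchmarkResult:
    """Run monitor-like baseline and fusion over a cohort and compare.

    For each record the fixed-threshold detector (the monitor-like
    baseline) and the three-detector fusion are run on the same RR
    stream and matched against the record's ground-truth annotations
    (events carrying the definition's label, at their adjusted onsets).
    TP/FP/FN pools are aggregated over the cohort; delays of events
    detected by BOTH arms enter the paired Wilcoxon test.  Both arms
    consume the identical real-time RR stream, so by default both
    receive the same latency compensation (``compensate_monitor=False``
    models an externally captured monitor alarm that already embeds its
    own latency).
    """
    records = list(records)
    if not records:
        raise ValueError("benchmark requires a non-empty cohort")
    all_results: dict[str, list[MatchResult]] = {"monitor": [], "fusion": []}
    paired_a: list[float] = []
    paired_b: list[float] = []
    fraction_counts: dict[tuple[str, ...], float] = {}
    n_fused = 0
    for rec in records:
        truth = [ev for ev in rec.events if definition.label in ev.labels]
        onsets = _adjusted_onsets(rec.rr, truth)
        traces = run_all(rec.rr, config)
        fused = fuse_majority(traces)
        mon = detect_fixed(rec.rr, config.fixed)
        bd = attribute_detections(fused, traces)
        n_fused += bd.n_detections
        for subset, pct in bd.fractions.items():
            fraction_counts[subset] = (
                fraction_counts.get(subset, 0.0) + pct * bd.n_detections / 100.0
            )
        m_mon = match(onsets, list(mon.detections), rules, compensate=compensate_monitor)
        m_fus = match(onsets, list(fused.detections), rules, compensate=True)
        all_results["monitor"].append(m_mon)
        all_results["fusion"].append(m_fus)
        mon_by_ann = {a: d for a, _, d in m_mon.tp}
        fus_by_ann = {a: d for a, _, d in m_fus.tp}
        for a in mon_by_ann.keys() & fus_by_ann.keys():
            paired_a.append(mon_by_ann[a])
            paired_b.append(fus_by_ann[a])
    reports = []
    for name in ("monitor", "fusion"):
        merged = MatchResult(
            tp=[t for r in all_results[name] for t in r.tp],
            fp=[t for r in all_results[name] for t in r.fp],
            fn=[t for r in all_results[name] for t in r.fn],
            ignored_detections=[
                t for r in all_results[name] for t in r.ignored_detections
            ],
            ignored_annotations=[
                t for r in all_results[name] for t in r.ignored_annotations
            ],
        )
        reports.append(metrics(merged, detector=name, definition=definition.label))
    _, p = compare_delays(paired_a, paired_b)
    reports[0] = replace(reports[0], p_wilcoxon=p)
    reports[1] = replace(reports[1], p_wilcoxon=p)
    fractions = {
        k: 100.0 * v / n_fused for k, v in fraction_counts.items()
    } if n_fused else {}
    return BenchmarkResult(
        reports=reports,
        paired_delays={
            "monitor": np.array(paired_a),
            "fusion": np.array(paired_b),
        },
        wilcoxon_p=p,
        fusion_fractions=fractions,
        n_fused_detections=n_fused,
    )
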