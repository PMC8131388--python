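"""Online bradycardia detectors operating beat-by-beat on an RR series.

Three detectors are implemented, each producing an :class:`AlarmTrace`
(a binary alarm level per beat plus the discrete detection instants, the
rising edges of that level):

Fixed threshold
    A monitor-like rule: an alarm when consecutive RR intervals stay
    above a threshold ``U0`` for a cumulative duration of more than 4 s,
    with at least 2 of those intervals above a confirmation threshold
    ``U1``.  Yellow (100 bpm) tier: U0 = 600 ms, U1 = 640 ms; red
    (80 bpm) tier: U0 = 750 ms, U1 = 800 ms.

Relative adaptive threshold
    The same run rule, but with a per-beat threshold
    ``U0'(k) = 1.33 * RR_mean(k)``, where ``RR_mean(k)`` is the mean RR
    over the 20 s preceding beat k.  This tracks a drifting basal heart
    rate; the confirmation threshold ``U1'`` stays fixed (640/800 ms).

Page-Hinkley (CUSUM) abrupt-change detector
    Treats a bradycardia as a jump of magnitude nu in the mean of the RR
    series.  The generalized-likelihood test for an unknown jump instant
    reduces to accumulating ``Lambda += RR(k) - RRbar0(k) - nu/2``
    (RRbar0: trailing 290 s baseline mean), tracking the running minimum
    ``m``, and alarming when ``Lambda - m >= lambda``.  Printed operating
    point: 290 s window, lambda = 717, nu = 415 (ms units).

All detectors are strictly causal: the decision at beat k uses only
intervals stamped at or before beat k.  The run-duration clock is
beat-driven (the sum of the run's RR intervals, in seconds); no
wall-clock is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import RRSeries, trailing_means

__all__ = [
    "AlarmTrace",
    "FixedThresholdParams",
    "AdaptiveThresholdParams",
    "PageHinkleyParams",
    "DetectorConfig",
    "detect_fixed",
    "detect_adaptive",
    "detect_page_hinkley",
    "run_all",
    "YELLOW",
    "RED",
]


@dataclass(frozen=True)
class AlarmTrace:
    """Per-beat binary alarm level and its rising-edge detection instants."""

    beat_time: np.ndarray  # seconds, one per beat
    level: np.ndarray      # 0/1 per beat
    detections: np.ndarray  # seconds; beat times where level rises 0 -> 1

    @classmethod
    def from_level(cls, beat_time: np.ndarray, level: np.ndarray) -> "AlarmTrace":
        beat_time = np.asarray(beat_time, dtype=float)
        level = np.asarray(level, dtype=np.uint8)
        if beat_time.shape != level.shape:
            raise ValueError("beat_time and level must have equal length")
        prev = np.concatenate([[0], level[:-1]])
        rising = (level == 1) & (prev == 0)
        return cls(beat_time=beat_time, level=level, detections=beat_time[rising])

    def __len__(self) -> int:
        return self.level.size


@dataclass(frozen=True)
class FixedThresholdParams:
    u0: float               # primary RR threshold, ms
    u1: float               # confirmation threshold, ms
    min_duration: float = 4.0       # run duration bound, s
    min_occurrences: int = 2        # intervals above u1 required

    def __post_init__(self) -> None:
        if not (self.u1 >= self.u0 > 0):
            raise ValueError("thresholds must satisfy u1 >= u0 > 0")
        if self.min_duration <= 0 or self.min_occurrences < 1:
            raise ValueError("invalid run-rule parameters")


@dataclass(frozen=True)
class AdaptiveThresholdParams:
    factor: float = 1.33            # multiplier on the trailing mean
    mean_window: float = 20.0       # trailing-mean window, s
    u1: float = 800.0               # confirmation threshold, ms
    min_duration: float = 4.0
    min_occurrences: int = 2
    warmup: float = 20.0            # disarmed until this much record elapsed, s

    def __post_init__(self) -> None:
        if self.factor <= 1:
            raise ValueError("factor must exceed 1")
        if self.mean_window <= 0 or self.min_duration <= 0:
            raise ValueError("windows must be positive")


@dataclass(frozen=True)
class PageHinkleyParams:
    baseline_window: float = 290.0  # trailing baseline-mean window, s
    lam: float = 717.0              # alarm threshold on Lambda - m, ms
    nu: float = 415.0               # modelled jump magnitude, ms

    def __post_init__(self) -> None:
        if min(self.baseline_window, self.lam, self.nu) <= 0:
            raise ValueError("all Page-Hinkley parameters must be positive")


@dataclass(frozen=True)
class DetectorConfig:
    """One alarm tier's full parameter set for the three detectors."""

    color: str
    fixed: FixedThresholdParams
    adaptive: AdaptiveThresholdParams
    page_hinkley: PageHinkleyParams


# Printed operating points for the two monitor alarm tiers.  The
# Page-Hinkley triple is shared between tiers (a single set is defined).
YELLOW = DetectorConfig(
    color="yellow",
    fixed=FixedThresholdParams(u0=600.0, u1=640.0),
    adaptive=AdaptiveThresholdParams(u1=640.0),
    page_hinkley=PageHinkleyParams(),
)
RED = DetectorConfig(
    color="red",
    fixed=FixedThresholdParams(u0=750.0, u1=800.0),
    adaptive=AdaptiveThresholdParams(u1=800.0),
    page_hinkley=PageHinkleyParams(),
)


def _run_rule_levels(
    rr: np.ndarray,
    u0: np.ndarray,
    u1: float,
    min_duration: float,
    min_occurrences: int,
) -> np.ndarray:
    """Shared run logic of the fixed and adaptive detectors.

    A "run" is an uninterrupted streak of intervals with RR(k) > u0(k).
    The alarm level is 1 while the current run's cumulative duration
    exceeds ``min_duration`` seconds AND at least ``min_occurrences`` of
    its intervals exceed ``u1``; the run (and the level) resets at the
    first interval at or below u0.  A non-finite u0(k) disarms the
    detector at beat k (adaptive warm-up / undefined trailing mean).
    """
    n = rr.size
    level = np.zeros(n, dtype=np.uint8)
    run_dur = 0.0
    n_above_u1 = 0
    for k in range(n):
        thr = u0[k]
        if np.isfinite(thr) and rr[k] > thr:
            run_dur += rr[k] / 1000.0
            if rr[k] > u1:
                n_above_u1 += 1
            if run_dur > min_duration and n_above_u1 >= min_occurrences:
                level[k] = 1
        else:
            run_dur = 0.0
            n_above_u1 = 0
    return level


def detect_fixed(series: RRSeries, params: FixedThresholdParams) -> AlarmTrace:
    """Fixed-threshold detector (monitor-like rule)."""
    u0 = np.full(len(series), params.u0)
    level = _run_rule_levels(
        series.rr, u0, params.u1, params.min_duration, params.min_occurrences
    )
    return AlarmTrace.from_level(series.beat_time, level)


def detect_adaptive(series: RRSeries, params: AdaptiveThresholdParams) -> AlarmTrace:
    """Relative adaptive-threshold detector.

    ``U0'(k) = factor * RR_mean(k)`` with RR_mean the trailing
    ``mean_window`` mean (strictly preceding beat k).  Until ``warmup``
    seconds of record have elapsed the detector is disarmed (level 0,
    runs do not accumulate): the trailing mean is not yet representative.
    """
    n = len(series)
    if n == 0:
        return AlarmTrace.from_level(series.beat_time, np.zeros(0, dtype=np.uint8))
    u0 = params.factor * trailing_means(series, params.mean_window)
    armed_from = series.beat_time[0] + params.warmup
    u0[series.beat_time < armed_from] = np.nan
    level = _run_rule_levels(
        series.rr, u0, params.u1, params.min_duration, params.min_occurrences
    )
    return AlarmTrace.from_level(series.beat_time, level)


def detect_page_hinkley(series: RRSeries, params: PageHinkleyParams) -> AlarmTrace:
    """Page-Hinkley abrupt-change detector on the RR mean.

    Recursion per beat (armed state)::

        Lambda += RR(k) - RRbar0(k) - nu/2
        m       = min(m, Lambda)
        alarm when Lambda - m >= lambda

    ``RRbar0(k)`` is the trailing ``baseline_window`` mean, updated
    causally every beat (no freezing during a suspected event; the 290 s
    window keeps contamination small).  Where the baseline is undefined
    (record start) the current interval stands in, making the increment
    ``-nu/2``.  After an alarm Lambda and m reset to zero and the level
    holds at 1 until the first beat with ``RR < RRbar0 + nu/2`` (the
    series back in the baseline regime), at which point the detector
    re-arms and the level returns to 0.  This release rule is a
    monitor-like behaviour choice preventing continuous re-alarming
    within one event.
    """
    n = len(series)
    level = np.zeros(n, dtype=np.uint8)
    if n == 0:
        return AlarmTrace.from_level(series.beat_time, level)
    baseline = trailing_means(series, params.baseline_window)
    lam_stat = 0.0
    m = 0.0
    armed = True
    half_nu = params.nu / 2.0
    rr = series.rr
    for k in range(n):
        b = baseline[k] if np.isfinite(baseline[k]) else rr[k]
        if not armed and rr[k] < b + half_nu:
            armed = True
            lam_stat = 0.0
            m = 0.0
        if armed:
            lam_stat += rr[k] - b - half_nu
            m = min(m, lam_stat)
            if lam_stat - m >= params.lam:
                level[k] = 1
                armed = False
                lam_stat = 0.0
                m = 0.0
        else:
            level[k] = 1
    return AlarmTrace.from_level(series.beat_time, level)


def run_all(series: RRSeries, config: DetectorConfig) -> dict[str, AlarmTrace]:
    """Run the three detectors of one alarm tier on a common beat grid."""
    return {
        "fixed": detect_fixed(series, config.fixed),
        "adaptive": detect_adaptive(series, config.adaptive),
        "page_hinkley": detect_page_hinkley(series, config.page_hinkley),
    }
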