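"""Beat and RR-interval series: the canonical containers of the package.

Every downstream component (detectors, event annotation, the synthetic
cohort, evaluation) consumes the same two containers:

* :class:`BeatSeries` — the instants ``t(k)`` (seconds from record start)
  of detected heartbeats, strictly increasing.
* :class:`RRSeries` — beat-to-beat intervals ``RR = t(k+1) - t(k)`` in
  milliseconds.  Interval ``k`` is stamped at the time of the *later*
  beat: an online detector only learns an interval when the beat that
  closes it arrives, so this stamping is the causal, real-time contract.

Units are fixed throughout the package: time in seconds, RR in
milliseconds, heart rate in beats per minute (``HR = 60000 / RR``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BeatSeries",
    "RRSeries",
    "build_rr_series",
    "beats_from_rr",
    "bpm_to_rr",
    "rr_to_bpm",
    "trailing_mean_rr",
    "trailing_means",
]

MS_PER_MIN = 60000.0


class SeriesError(ValueError):
    """Invalid beat/RR series input."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise SeriesError(f"{name} must be one-dimensional")
    if arr.size and not np.all(np.isfinite(arr)):
        raise SeriesError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class BeatSeries:
    """Strictly increasing heartbeat instants, seconds from record start."""

    times: np.ndarray

    def __post_init__(self) -> None:
        times = _as_float_array(self.times, "times")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise SeriesError("beat times must be strictly increasing")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class RRSeries:
    """Beat-to-beat intervals (ms), each stamped at its closing beat (s)."""

    beat_time: np.ndarray
    rr: np.ndarray

    def __post_init__(self) -> None:
        t = _as_float_array(self.beat_time, "beat_time")
        rr = _as_float_array(self.rr, "rr")
        if t.size != rr.size:
            raise SeriesError("beat_time and rr must have equal length")
        if rr.size and not np.all(rr > 0):
            raise SeriesError("rr intervals must be strictly positive")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise SeriesError("beat_time must be strictly increasing")
        object.__setattr__(self, "beat_time", t)
        object.__setattr__(self, "rr", rr)

    def __len__(self) -> int:
        return self.rr.size

    @property
    def hr(self) -> np.ndarray:
        """Instantaneous heart rate per interval, bpm."""
        return MS_PER_MIN / self.rr


def build_rr_series(beats: BeatSeries) -> RRSeries:
    """Difference successive beat times into an RR series.

    ``RR(k) = t(k+1) - t(k)`` (ms), stamped at ``t(k+1)``.

    Raises
    ------
    SeriesError
        If fewer than two beats are supplied (no interval exists) or the
        beat times are not strictly increasing (caught by BeatSeries).
    """
    if len(beats) < 2:
        raise SeriesError("at least two beats are required to build an RR series")
    dt = np.diff(beats.times)
    return RRSeries(beat_time=beats.times[1:], rr=dt * 1000.0)


def beats_from_rr(series: RRSeries) -> BeatSeries:
    """Inverse of :func:`build_rr_series`: cumulative reconstruction.

    The first beat is placed at ``beat_time[0] - rr[0]/1000``.
    """
    if len(series) == 0:
        raise SeriesError("cannot reconstruct beats from an empty RR series")
    t0 = series.beat_time[0] - series.rr[0] / 1000.0
    times = np.concatenate([[t0], t0 + np.cumsum(series.rr) / 1000.0])
    return BeatSeries(times=times)


def bpm_to_rr(hr: float) -> float:
    """Heart rate (bpm) to cycle length (ms): 100 bpm -> 600 ms."""
    if hr <= 0:
        raise ValueError("heart rate must be positive")
    return MS_PER_MIN / hr


def rr_to_bpm(rr: float) -> float:
    """Cycle length (ms) to heart rate (bpm): 750 ms -> 80 bpm."""
    if rr <= 0:
        raise ValueError("RR interval must be positive")
    return MS_PER_MIN / rr


def trailing_mean_rr(series: RRSeries, at_time: float, window: float) -> float:
    """Mean RR (ms) over intervals stamped in ``[at_time - window, at_time)``.

    The half-open window excludes an interval stamped exactly at
    ``at_time`` — values "preceding" the current beat, never the current
    one.  Returns ``nan`` when no interval falls in the window.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    lo = np.searchsorted(series.beat_time, at_time - window, side="left")
    hi = np.searchsorted(series.beat_time, at_time, side="left")
    if hi <= lo:
        return float("nan")
    return float(np.mean(series.rr[lo:hi]))


def trailing_means(series: RRSeries, window: float) -> np.ndarray:
    """Vectorised :func:`trailing_mean_rr` evaluated at every beat.

    Entry ``k`` is the mean of intervals stamped in
    ``[beat_time[k] - window, beat_time[k])`` — strictly before beat
    ``k``, so interval ``k`` itself never contributes.  ``nan`` where the
    window is empty (always at ``k = 0``).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n = len(series)
    out = np.full(n, np.nan)
    if n == 0:
        return out
    csum = np.concatenate([[0.0], np.cumsum(series.rr)])
    lo = np.searchsorted(series.beat_time, series.beat_time - window, side="left")
    hi = np.arange(n)  # strictly-increasing stamps: side="left" at t_k is k
    count = hi - lo
    mask = count > 0
    out[mask] = (csum[hi[mask]] - csum[lo[mask]]) / count[mask]
    return out
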