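"""Bradycardia event extraction, multiphasic merging and clinical rules.

Three event definitions are used in neonatal monitoring practice:

* ``B100_5``  — HR below 100 bpm for at least 5 s (yellow-alarm tier);
* ``B80_10``  — HR below 80 bpm for at least 10 s (severe, red tier);
* ``Bclin``   — clinically significant: every B80_10, plus any B100_5
  accompanied by apnea and an SpO2 drop of at least 10 points.  Isolated
  sub-100 bpm dips explained by a low basal rate or by periodic-breathing
  HR oscillations are NOT clinically significant.

By construction B80_10 and Bclin events are subsets of B100_5.

A bradycardia whose HR briefly re-crosses the yellow threshold is a
single multiphasic event: successive sub-threshold dips are merged when
the time spent above 100 bpm between them is shorter than ``merge_gap``
(10 s).  The gap clock uses the 100 bpm threshold for every definition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .series import RRSeries, MS_PER_MIN

__all__ = [
    "BradycardiaDefinition",
    "BradycardiaEvent",
    "ClinicalContext",
    "B100_5",
    "B80_10",
    "find_events",
    "annotate_events",
    "classify_clinical",
    "YELLOW_HR_BPM",
]

YELLOW_HR_BPM = 100.0  # gap clock threshold for multiphasic merging


@dataclass(frozen=True)
class BradycardiaDefinition:
    hr_threshold: float  # bpm
    min_duration: float  # s
    label: str

    def __post_init__(self) -> None:
        if self.hr_threshold <= 0 or self.min_duration <= 0:
            raise ValueError("threshold and duration must be positive")


B100_5 = BradycardiaDefinition(hr_threshold=100.0, min_duration=5.0, label="B100_5")
B80_10 = BradycardiaDefinition(hr_threshold=80.0, min_duration=10.0, label="B80_10")

DEFINITIONS = {"B100_5": B100_5, "B80_10": B80_10}


@dataclass(frozen=True)
class ClinicalContext:
    """Per-event context used by the clinical-significance rule."""

    apnea: bool = False
    spo2_drop: float = 0.0  # percentage points
    low_basal_hr: bool = False
    periodic_breathing: bool = False

    def __post_init__(self) -> None:
        if self.spo2_drop < 0:
            raise ValueError("spo2_drop must be non-negative")


@dataclass(frozen=True)
class BradycardiaEvent:
    """An annotated bradycardia with raw and adjusted boundaries.

    ``onset_raw``/``offset_raw`` are threshold-crossing times; the
    adjusted fields are filled by the sigmoid onset/offset procedure
    (None until computed).  ``n_phases`` counts the merged sub-threshold
    dips (1 = monophasic, 2 = biphasic, ...).
    """

    onset_raw: float
    offset_raw: float
    labels: frozenset[str] = frozenset()
    n_phases: int = 1
    min_hr: float = float("nan")
    onset_adj: float | None = None
    offset_adj: float | None = None
    context: ClinicalContext | None = None

    def __post_init__(self) -> None:
        if not self.offset_raw > self.onset_raw:
            raise ValueError("event offset must follow onset")
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")

    @property
    def duration(self) -> float:
        return self.offset_raw - self.onset_raw

    @property
    def onset(self) -> float:
        """Best available onset: adjusted when computed, raw otherwise."""
        return self.onset_raw if self.onset_adj is None else self.onset_adj


def _sub_threshold_runs(series: RRSeries, hr_threshold: float):
    """Maximal runs of consecutive intervals with HR below the threshold.

    Yields ``(i0, i1)`` inclusive interval-index bounds.  HR < threshold
    is equivalent to RR > 60000/threshold (strict).
    """
    below = series.rr > MS_PER_MIN / hr_threshold
    runs = []
    start = None
    for k, b in enumerate(below):
        if b and start is None:
            start = k
        elif not b and start is not None:
            runs.append((start, k - 1))
            start = None
    if start is not None:
        runs.append((start, len(below) - 1))
    return runs


def _run_onset(series: RRSeries, i0: int) -> float:
    # interval i0 spans [beat_time - rr/1000, beat_time]
    return float(series.beat_time[i0] - series.rr[i0] / 1000.0)


def _gap_above_yellow(series: RRSeries, i_end: int, j_start: int) -> float:
    """Seconds spent with HR above 100 bpm between two sub-threshold runs."""
    gap = slice(i_end + 1, j_start)
    rr = series.rr[gap]
    fast = rr < MS_PER_MIN / YELLOW_HR_BPM  # HR > 100 bpm
    return float(np.sum(rr[fast]) / 1000.0)


def find_events(
    series: RRSeries,
    definition: BradycardiaDefinition,
    merge_gap: float = 10.0,
) -> list[BradycardiaEvent]:
    """Extract bradycardia events under one definition, merging phases.

    Maximal runs of intervals with HR below ``definition.hr_threshold``
    are located; consecutive runs are merged into one multiphasic event
    when the time above 100 bpm separating them is strictly less than
    ``merge_gap`` seconds (``merge_gap = 0`` disables merging).  Merged
    events are kept when their onset-to-offset span reaches
    ``definition.min_duration``.

    The onset is the start of the first sub-threshold interval and the
    offset the closing beat of the last one, so a run's duration is the
    elapsed time between its first and last sub-threshold beats plus the
    first interval.
    """
    runs = _sub_threshold_runs(series, definition.hr_threshold)
    if not runs:
        return []
    # group runs by the gap rule
    groups: list[list[tuple[int, int]]] = [[runs[0]]]
    for run in runs[1:]:
        prev = groups[-1][-1]
        if merge_gap > 0 and _gap_above_yellow(series, prev[1], run[0]) < merge_gap:
            groups[-1].append(run)
        else:
            groups.append([run])
    events = []
    for group in groups:
        i0 = group[0][0]
        i1 = group[-1][1]
        onset = _run_onset(series, i0)
        offset = float(series.beat_time[i1])
        if offset - onset < definition.min_duration:
            continue
        run_idx = np.concatenate([np.arange(a, b + 1) for a, b in group])
        min_hr = float(MS_PER_MIN / np.max(series.rr[run_idx]))
        events.append(
            BradycardiaEvent(
                onset_raw=onset,
                offset_raw=offset,
                labels=frozenset({definition.label}),
                n_phases=len(group),
                min_hr=min_hr,
            )
        )
    return events


def annotate_events(series: RRSeries, merge_gap: float = 10.0) -> list[BradycardiaEvent]:
    """Full annotation pass: B100_5 events carrying a B80_10 label where due.

    Events are extracted under the yellow definition (the superset); an
    event additionally receives the ``B80_10`` label when a severe event
    found under the red definition lies within its span — preserving the
    containment property that every B80_10 is also a B100_5.
    """
    base = find_events(series, B100_5, merge_gap=merge_gap)
    severe = find_events(series, B80_10, merge_gap=merge_gap)
    out = []
    for ev in base:
        labels = set(ev.labels)
        for sv in severe:
            if ev.onset_raw <= sv.onset_raw and sv.offset_raw <= ev.offset_raw + 1e-9:
                labels.add("B80_10")
                break
        out.append(replace(ev, labels=frozenset(labels)))
    return out


def classify_clinical(event: BradycardiaEvent, ctx: ClinicalContext) -> bool:
    """Clinical-significance rule for an annotated event.

    True for every severe (B80_10) event; true for a B100_5 event
    accompanied by apnea and an SpO2 drop of at least 10 points, unless
    the dip is explained by a low basal heart rate or periodic-breathing
    oscillations.  The event must carry the B100_5 label (every
    annotated bradycardia does).
    """
    if "B100_5" not in event.labels:
        raise ValueError("clinical classification requires a B100_5-labelled event")
    if "B80_10" in event.labels:
        return True
    if ctx.low_basal_hr or ctx.periodic_breathing:
        return False
    return bool(ctx.apnea and ctx.spo2_drop >= 10.0)
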