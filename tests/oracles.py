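"""Independent brute-force oracles used to cross-check the streaming code.

Every function here recomputes a detector decision, a statistic or a
matching from first principles — full re-scans, exhaustive enumeration —
and deliberately shares no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def brute_trailing_mean(beat_time, rr, at_time, window):
    """Filter-then-average over the whole series (half-open window)."""
    vals = [r for t, r in zip(beat_time, rr) if at_time - window <= t < at_time]
    return float(np.mean(vals)) if vals else float("nan")


def _run_level_at(rr, u0, k, u1, min_duration, min_occurrences):
    """Level at beat k by scanning the run backwards from scratch."""
    if not (np.isfinite(u0[k]) and rr[k] > u0[k]):
        return 0
    j = k
    while j > 0 and np.isfinite(u0[j - 1]) and rr[j - 1] > u0[j - 1]:
        j -= 1
    run = rr[j : k + 1]
    dur = float(np.sum(run)) / 1000.0
    n_above = int(np.sum(run > u1))
    return int(dur > min_duration and n_above >= min_occurrences)


def oracle_fixed_levels(beat_time, rr, u0, u1, min_duration=4.0, min_occurrences=2):
    """Fixed-threshold alarm level, one independent re-scan per beat."""
    u0_arr = np.full(len(rr), u0)
    return np.array(
        [
            _run_level_at(rr, u0_arr, k, u1, min_duration, min_occurrences)
            for k in range(len(rr))
        ],
        dtype=np.uint8,
    )


def oracle_adaptive_levels(
    beat_time,
    rr,
    factor=1.33,
    mean_window=20.0,
    u1=800.0,
    min_duration=4.0,
    min_occurrences=2,
    warmup=20.0,
):
    """Adaptive-threshold alarm level with brute-force trailing means."""
    n = len(rr)
    u0 = np.empty(n)
    for k in range(n):
        if beat_time[k] < beat_time[0] + warmup:
            u0[k] = np.nan
        else:
            u0[k] = factor * brute_trailing_mean(
                beat_time, rr, beat_time[k], mean_window
            )
    return np.array(
        [
            _run_level_at(rr, u0, k, u1, min_duration, min_occurrences)
            for k in range(n)
        ],
        dtype=np.uint8,
    )


def oracle_ph_levels(beat_time, rr, baseline_window=290.0, lam=717.0, nu=415.0):
    """Page-Hinkley alarm level from the direct definition.

    Within each armed segment starting at beat ``a``, the decision
    statistic at beat n is  max over t in [a..n] of
    sum_{k=t..n} (RR(k) - RRbar0(k) - nu/2),  evaluated exhaustively
    over every candidate change point t.  The alarm/release state
    machine mirrors the documented contract (reset after alarm, re-arm
    when RR returns below RRbar0 + nu/2).
    """
    n = len(rr)
    level = np.zeros(n, dtype=np.uint8)
    base = np.array(
        [brute_trailing_mean(beat_time, rr, beat_time[k], baseline_window) for k in range(n)]
    )
    base = np.where(np.isfinite(base), base, rr)
    inc = rr - base - nu / 2.0
    armed = True
    seg_start = 0
    for k in range(n):
        if not armed and rr[k] < base[k] + nu / 2.0:
            armed = True
            seg_start = k
        if armed:
            stat = max(
                float(np.sum(inc[t : k + 1])) for t in range(seg_start, k + 1)
            )
            if stat >= lam:
                level[k] = 1
                armed = False
        else:
            level[k] = 1
    return level


def oracle_match(annotations, detections, pre=5.0, post=30.0):
    """Annotation/detection matching by literal application of the rules.

    Returns (tp_pairs, fp, fn) with tp_pairs a list of
    (annotation, detection).  Implemented annotation-first (the package
    iterates detections), with explicit dedup passes.
    """
    annotations = list(annotations)
    detections = list(detections)
    used_det: set[float] = set()
    used_ann: set[float] = set()
    ignored_ann: set[float] = set()
    ignored_det: set[float] = set()
    tp = []
    # pass 1: each detection claims the earliest candidate annotation
    for d in detections:
        cands = [
            a
            for a in annotations
            if a - pre <= d <= a + post and a not in used_ann and a not in ignored_ann
        ]
        if not cands:
            continue
        a = min(cands)
        tp.append((a, d))
        used_ann.add(a)
        used_det.add(d)
        for extra in cands[1:]:
            ignored_ann.add(extra)
    # pass 2: classify the remaining detections
    fp = []
    for d in detections:
        if d in used_det:
            continue
        if any(a - pre <= d <= a + post for a in annotations):
            ignored_det.add(d)  # later detection in an already-served window
        else:
            fp.append(d)
    fn = [a for a in annotations if a not in used_ann and a not in ignored_ann]
    return tp, fp, fn
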