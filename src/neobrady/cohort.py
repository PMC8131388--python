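"""Seeded synthetic preterm-infant cohort with ground-truth annotations.

Clinical NICU recordings are not redistributable, so this module
generates records that emulate the statistical structure the detectors
assume:

* a preterm baseline heart rate (default 155 +/- 10 bpm across records)
  with AR(1) beat-to-beat RR variability, optionally modulated by
  periodic-breathing HR oscillations (10-15 s period, 5-15 bpm);
* bradycardia events with mono-, bi- and tri-phasic morphologies built
  from logistic (sigmoid) HR dips — multiphasic dips are separated by
  sub-10 s returns above 100 bpm so they annotate as single events;
* SpO2 desaturations that *precede* the bradycardia onset by a few
  seconds, as apnea-triggered events do;
* sensor artifacts: missed beats (two RR intervals fused) and spurious
  beats (one interval split).

Ground truth is computed analytically from the continuous HR profile of
each injected event (threshold crossings on a dense grid), never by
running the package's own annotator, so generator/annotator round-trip
tests are meaningful.  Event windows are rendered noiseless and
artifacts are kept at least 15 s away from events, keeping the analytic
truth unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .events import BradycardiaEvent, ClinicalContext
from .series import BeatSeries, RRSeries, beats_from_rr, build_rr_series, trailing_mean_rr

__all__ = [
    "CohortConfig",
    "SyntheticRecord",
    "PlacementError",
    "simulate_baseline",
    "inject_event",
    "simulate_spo2",
    "simulate_record",
    "simulate_cohort",
    "sample_morphologies",
]

_GRID_DT = 0.02  # s, dense grid for analytic truth


class PlacementError(ValueError):
    """Event cannot be injected at the requested location."""


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the synthetic cohort (defaults = the design)."""

    n_records: int = 50
    record_duration: float = 1800.0     # s per record
    baseline_hr_mean: float = 155.0     # bpm, across records
    baseline_hr_sd: float = 10.0        # bpm, across records
    rr_noise_sd: float = 10.0           # ms, stationary AR(1) sd
    ar_coeff: float = 0.8               # AR(1) coefficient
    event_rate: float = 4.0             # events / hour
    morphology_mix: tuple[float, float, float] = (0.66, 0.24, 0.10)  # mono/bi/tri
    nadir_range: tuple[float, float] = (50.0, 75.0)     # bpm
    duration_range: tuple[float, float] = (12.0, 25.0)  # s below threshold
    desat_prob: float = 0.85            # P(event coupled to a desaturation)
    artifact_rate: float = 1.0          # artifacts / hour
    periodic_breathing_prob: float = 0.3  # per record
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.morphology_mix) - 1.0) > 1e-9:
            raise ValueError("morphology_mix fractions must sum to 1")
        for name in ("event_rate", "artifact_rate", "rr_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.ar_coeff < 1:
            raise ValueError("ar_coeff must lie in [0, 1)")


@dataclass(frozen=True)
class SyntheticRecord:
    record_id: str
    rr: RRSeries
    spo2_time: np.ndarray   # s, 1 Hz grid
    spo2: np.ndarray        # %
    events: list[BradycardiaEvent]  # ground truth, onset_adj = analytic
    periodic_breathing: bool
    seed: int


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_baseline(
    config: CohortConfig,
    seed: int,
    duration: float | None = None,
    baseline_hr: float | None = None,
    periodic_breathing: bool = False,
) -> RRSeries:
    """Event-free baseline RR series.

    ``RR(k) = 60000/HR(t) + e(k)`` with e an AR(1) process
    (coefficient ``ar_coeff``, stationary sd ``rr_noise_sd``), clipped to
    [250, 600] ms; the clip at 600 ms (= 100 bpm) guarantees the baseline
    alone never crosses the yellow threshold.  With periodic breathing,
    HR(t) carries a sinusoidal modulation (period 10-15 s, amplitude
    5-15 bpm drawn once per record).
    """
    rng = np.random.default_rng(seed)
    dur = config.record_duration if duration is None else duration
    if dur <= 0:
        raise ValueError("duration must be positive")
    hr0 = config.baseline_hr_mean if baseline_hr is None else baseline_hr
    if periodic_breathing:
        pb_period = rng.uniform(10.0, 15.0)
        pb_amp = rng.uniform(5.0, 15.0)
        pb_phase = rng.uniform(0.0, 2.0 * np.pi)
    n_max = int(dur / 0.25) + 2
    innov = rng.standard_normal(n_max)
    innov_sd = config.rr_noise_sd * np.sqrt(1.0 - config.ar_coeff**2)
    t = 0.0
    e = 0.0
    times: list[float] = []
    rrs: list[float] = []
    for k in range(n_max):
        hr = hr0
        if periodic_breathing:
            hr = hr + pb_amp * np.sin(2.0 * np.pi * t / pb_period + pb_phase)
        e = config.ar_coeff * e + innov_sd * innov[k]
        rr = float(np.clip(60000.0 / hr + e, 250.0, 600.0))
        t += rr / 1000.0
        times.append(t)
        rrs.append(rr)
        if t >= dur:
            break
    return RRSeries(beat_time=np.array(times), rr=np.array(rrs))


def _event_profile(
    hr_base: float,
    nadir: float,
    duration: float,
    n_phases: int,
    gaps: np.ndarray,
    ramp_s: float = 1.2,
):
    """Continuous HR profile of one event, as (callable, total span).

    Each phase is a logistic dip ``depth * sig((tau-a)/s) * sig((b-tau)/s)``
    below the local baseline.  Phase widths are calibrated so the total
    time below the calibration level (80 bpm for severe events, 100 bpm
    otherwise) is approximately ``duration``; successive dips are spaced
    by the requested ``gaps`` (drawn well under 10 s, so the short
    interludes above 100 bpm make the dips annotate as one multiphasic
    event).
    """
    depth = hr_base - nadir
    if depth <= 0:
        raise PlacementError("event nadir must lie below the local baseline")
    cal_level = 80.0 if nadir < 78.0 else 100.0
    if hr_base <= cal_level:
        raise PlacementError("local baseline too low to calibrate the event")
    q_cal = (hr_base - cal_level) / depth
    q_cal = min(max(q_cal, 1e-6), 1.0 - 1e-6)
    x_cal = np.log(q_cal / (1.0 - q_cal))
    per_phase = duration / n_phases
    width = max(per_phase + 2.0 * ramp_s * x_cal, 2.0 * ramp_s)
    pad = 8.0 * ramp_s
    starts = []
    a = pad
    for p in range(n_phases):
        starts.append(a)
        if p < n_phases - 1:
            a = a + width + float(gaps[p])
    total = starts[-1] + width + pad
    a_arr = np.array(starts)
    b_arr = a_arr + width

    def hr(tau):
        tau = np.asarray(tau, dtype=float)
        bump = np.zeros_like(tau)
        for ap, bp in zip(a_arr, b_arr):
            bump = bump + _logistic((tau - ap) / ramp_s) * _logistic((bp - tau) / ramp_s)
        return hr_base - depth * bump

    return hr, float(total)


def _truth_from_profile(hr_fn, total: float, at: float, n_phases: int) -> BradycardiaEvent:
    """Analytic ground truth: threshold crossings of the continuous profile."""
    tau = np.arange(0.0, total, _GRID_DT)
    hr = hr_fn(tau)
    below100 = hr < 100.0
    if not np.any(below100):
        raise PlacementError("event profile never crosses 100 bpm")
    i100 = np.flatnonzero(below100)
    onset = at + tau[i100[0]]
    offset = at + tau[i100[-1]]
    labels = {"B100_5"} if tau[i100[-1]] - tau[i100[0]] >= 5.0 else set()
    below80 = hr < 80.0
    if np.any(below80):
        i80 = np.flatnonzero(below80)
        if tau[i80[-1]] - tau[i80[0]] >= 10.0:
            labels |= {"B80_10", "B100_5"}
    # analytic sigmoid onset: first instant the RR profile steepens past 1 ms/s
    rr = 60000.0 / hr
    drr = np.gradient(rr, _GRID_DT)
    centre = int(np.argmin(hr))
    steep = np.flatnonzero(drr[:centre] > 1.0)
    onset_adj = at + tau[steep[0]] if steep.size else onset
    return BradycardiaEvent(
        onset_raw=float(onset),
        offset_raw=float(offset),
        labels=frozenset(labels),
        n_phases=n_phases,
        min_hr=float(np.min(hr)),
        onset_adj=float(onset_adj),
    )


def inject_event(
    series: RRSeries,
    at: float,
    nadir: float,
    duration: float,
    n_phases: int = 1,
    gaps: np.ndarray | None = None,
    ramp_s: float = 1.2,
) -> tuple[RRSeries, BradycardiaEvent]:
    """Insert one bradycardia event into a baseline series at time ``at``.

    Beats inside the event window are re-synthesised by walking the
    continuous HR profile (noiseless); beats after the window resume the
    original RR sequence, re-stamped.  Raises :class:`PlacementError`
    when the window overlaps an existing slow segment or falls outside
    the record.
    """
    if n_phases < 1 or n_phases > 3:
        raise ValueError("n_phases must be 1, 2 or 3")
    if gaps is None:
        gaps = np.full(max(n_phases - 1, 1), 6.0)
    base_rr = trailing_mean_rr(series, at, 20.0)
    if not np.isfinite(base_rr):
        raise PlacementError("no baseline history in the 20 s before the event")
    hr_base = 60000.0 / base_rr
    hr_fn, total = _event_profile(hr_base, nadir, duration, n_phases, gaps, ramp_s)
    end = at + total
    if at <= series.beat_time[0] + 20.0 or end >= series.beat_time[-1] - 10.0:
        raise PlacementError("event window falls outside the usable record")
    guard = (series.beat_time > at - 25.0) & (series.beat_time < end + 25.0)
    if np.any(series.rr[guard] > 600.0):
        raise PlacementError("event window overlaps an existing slow segment")
    keep = series.beat_time < at
    times = list(series.beat_time[keep])
    rrs = list(series.rr[keep])
    t = times[-1] if times else at
    while t < end:
        rr = 60000.0 / float(hr_fn(t - at))
        t += rr / 1000.0
        times.append(t)
        rrs.append(rr)
    # Re-join the original tail at its ORIGINAL stamps (later events must
    # not drift), bridging the walk end to the first reusable tail beat
    # with evenly spaced intervals in the 250-600 ms baseline band so the
    # junction can never read as a sub-100 bpm interval.
    tail_idx = np.flatnonzero(series.beat_time >= t + 0.25)
    if tail_idx.size:
        j = int(tail_idx[0])
        x = float(series.beat_time[j] - t)
        n_mid = max(int(np.ceil(x / 0.55)), 1)
        d = x / n_mid
        times.extend(t + d * np.arange(1, n_mid + 1))
        rrs.extend([d * 1000.0] * n_mid)
        times.extend(series.beat_time[j + 1 :])
        rrs.extend(series.rr[j + 1 :])
    new = RRSeries(beat_time=np.array(times), rr=np.array(rrs))
    return new, _truth_from_profile(hr_fn, total, at, n_phases)


def simulate_spo2(
    duration: float,
    events: list[BradycardiaEvent],
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """1 Hz SpO2 series coupled to the events that carry a desaturation.

    Baseline 95-99 % with small noise.  For each event whose context has
    ``apnea`` set, SpO2 starts falling 2-5 s *before* the bradycardia
    onset (apnea precedes the HR response), reaches baseline minus the
    event's ``spo2_drop`` and recovers after the event offset.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 1.0)
    base = rng.uniform(95.0, 99.0)
    spo2 = base + 0.3 * rng.standard_normal(t.size)
    for ev in events:
        if ev.context is None or not ev.context.apnea:
            continue
        depth = max(ev.context.spo2_drop, 10.0)
        lead = rng.uniform(2.0, 5.0)
        fall_start = ev.onset_raw - lead
        fall_end = fall_start + 5.0
        rec_start = ev.offset_raw + rng.uniform(2.0, 5.0)
        rec_end = rec_start + 10.0
        drop = np.zeros_like(t)
        drop[(t >= fall_start) & (t < fall_end)] = (
            (t[(t >= fall_start) & (t < fall_end)] - fall_start) / 5.0
        )
        drop[(t >= fall_end) & (t < rec_start)] = 1.0
        rec = (t >= rec_start) & (t < rec_end)
        drop[rec] = 1.0 - (t[rec] - rec_start) / 10.0
        spo2 = spo2 - depth * drop
    return t, np.clip(spo2, 40.0, 100.0)


def sample_morphologies(n: int, mix: tuple[float, float, float], seed: int) -> np.ndarray:
    """Draw n phase counts (1, 2 or 3) from the morphology mix."""
    rng = np.random.default_rng(seed)
    return rng.choice([1, 2, 3], size=n, p=list(mix))


def _apply_artifacts(
    series: RRSeries,
    events: list[BradycardiaEvent],
    n_artifacts: int,
    rng: np.random.Generator,
) -> RRSeries:
    """Missed beats (two intervals fused) and spurious beats (one split).

    Artifact sites are kept >= 15 s away from every event so the ground
    truth stays unambiguous.  Beat insertions/deletions preserve all
    other beat instants.
    """
    if n_artifacts <= 0:
        return series
    beats = list(beats_from_rr(series).times)
    forbidden = [(ev.onset_raw - 15.0, ev.offset_raw + 15.0) for ev in events]

    def allowed(t: float) -> bool:
        return all(not (lo <= t <= hi) for lo, hi in forbidden)

    t_lo, t_hi = beats[2], beats[-3]
    for _ in range(n_artifacts):
        for _attempt in range(20):
            t = rng.uniform(t_lo, t_hi)
            if allowed(t):
                break
        else:
            continue
        i = int(np.searchsorted(beats, t))
        if i < 2 or i > len(beats) - 3:
            continue
        if rng.uniform() < 0.5:
            del beats[i]  # missed beat: intervals i-1 and i fuse
        else:
            u = rng.uniform(0.4, 0.6)
            beats.insert(i, beats[i - 1] + u * (beats[i] - beats[i - 1]))
    return build_rr_series(BeatSeries(times=np.array(beats)))


def simulate_record(config: CohortConfig, seed: int, record_id: str) -> SyntheticRecord:
    """One record: baseline, Poisson-placed events, SpO2, artifacts."""
    rng = np.random.default_rng(seed)
    hr0 = float(
        np.clip(
            rng.normal(config.baseline_hr_mean, config.baseline_hr_sd), 120.0, 190.0
        )
    )
    periodic = bool(rng.uniform() < config.periodic_breathing_prob)
    series = simulate_baseline(
        config,
        seed=int(rng.integers(2**31 - 1)),
        baseline_hr=hr0,
        periodic_breathing=periodic,
    )
    dur = config.record_duration
    n_events = int(rng.poisson(config.event_rate * dur / 3600.0))
    phases = sample_morphologies(
        max(n_events, 1), config.morphology_mix, int(rng.integers(2**31 - 1))
    )
    events: list[BradycardiaEvent] = []
    for j in range(n_events):
        placed = False
        for _attempt in range(50):
            at = rng.uniform(60.0, dur - 120.0)
            if any(abs(at - ev.onset_raw) < 90.0 for ev in events):
                continue
            nadir = rng.uniform(*config.nadir_range)
            length = rng.uniform(*config.duration_range)
            gaps = rng.uniform(3.0, 7.0, size=max(int(phases[j]) - 1, 1))
            try:
                series, ev = inject_event(
                    series, at, nadir, length, n_phases=int(phases[j]), gaps=gaps
                )
            except PlacementError:
                continue
            desat = bool(rng.uniform() < config.desat_prob) or "B80_10" in ev.labels
            ctx = ClinicalContext(
                apnea=desat,
                spo2_drop=float(rng.uniform(10.0, 25.0)) if desat else 0.0,
                periodic_breathing=False,
            )
            events.append(replace(ev, context=ctx))
            placed = True
            break
        if not placed:
            continue
    events.sort(key=lambda e: e.onset_raw)
    n_artifacts = int(rng.poisson(config.artifact_rate * dur / 3600.0))
    series = _apply_artifacts(series, events, n_artifacts, rng)
    spo2_t, spo2 = simulate_spo2(dur, events, seed=int(rng.integers(2**31 - 1)))
    return SyntheticRecord(
        record_id=record_id,
        rr=series,
        spo2_time=spo2_t,
        spo2=spo2,
        events=events,
        periodic_breathing=periodic,
        seed=seed,
    )


def simulate_cohort(config: CohortConfig) -> list[SyntheticRecord]:
    """The full cohort: ``n_records`` independent seeded records."""
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=config.n_records)
    return [
        simulate_record(config, seed=int(s), record_id=f"rec{i:03d}")
        for i, s in enumerate(seeds)
    ]
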