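# Methods

This note records the modelling assumptions, parameter conventions and
design decisions behind `neobrady`, at the level a maintainer or a
careful user needs.

## Data model and units

The universal input is the RR series: beat-to-beat intervals in
milliseconds, each stamped at the time (seconds) of the beat that
*closes* it.  An online detector only learns `RR(k) = t(k+1) − t(k)`
when beat `k+1` arrives, so stamping the interval at the later beat is
the causal contract; every detector decision at a beat uses only
intervals stamped at or before it, and truncating a series never
changes past alarm levels (tested as a property).  Heart rate is always
the instantaneous `60000 / RR` bpm.  Trailing means ("the mean RR over
the preceding W seconds") use the half-open window `[t − W, t)`: values
strictly preceding the current beat, the current interval excluded.

## Detectors

**Fixed threshold.**  A run is an uninterrupted streak of intervals
with `RR > U0`.  The alarm condition — run longer than 4 s with at
least 2 intervals above `U1` — is evaluated per beat; "longer than 4 s"
is the *cumulative duration* of the run (the sum of its RR intervals in
seconds), so the detector is purely beat-driven and needs no wall
clock.  The 2-occurrence confirmation is counted over the whole current
run, not a sliding sub-window.  The alarm level stays raised while the
run persists and falls at the first interval at or below `U0`
(release-on-recovery, the behaviour of bedside monitors).  Operating
points: yellow U0/U1 = 600/640 ms, red 750/800 ms, both with the
4 s / 2-occurrence rule.

**Adaptive threshold.**  Identical run logic with
`U0'(k) = 1.33 · RR_mean(k)` over a 20 s trailing mean and the fixed
confirmation threshold `U1'` (640/800 ms).  The detector is disarmed
until 20 s of record have elapsed: before that the trailing mean is not
representative (cold start is otherwise unspecified by the rule).

**Page–Hinkley.**  The CUSUM reduction of the generalized likelihood
ratio test for an upward jump of size ν in the RR mean:
`Λ += RR(k) − RR̄0(k) − ν/2`, `m = min(m, Λ)`, alarm when
`Λ − m ≥ λ`, with `RR̄0` the 290 s trailing mean and λ = 717, ν = 415
(ms).  Two behaviours the statistic itself does not define:

* *Baseline freezing.*  `RR̄0` (and `RR_mean`) update causally every
  beat, including beats inside an evolving bradycardia.  The 290 s
  window keeps the contamination small — a worked check: with a long
  400 ms history and a step to 1000 ms, the alarm still fires at the
  second post-step beat (cumulative increment ≈ 779 ≥ 717) despite the
  first step beat entering the window.  Freezing during suspected
  events would need an event-state feedback loop the rule does not
  define.
* *Release and re-arming.*  After an alarm, Λ and m reset to zero and
  the level holds at 1 until the first beat with
  `RR < RR̄0 + ν/2` (back in the baseline regime), when the detector
  re-arms.  Without this, the statistic would re-alarm continuously
  through a single long event.

Both alarm tiers share the single printed Page–Hinkley triple.

The streaming implementations are verified beat-for-beat against
offline brute-force re-scans, and the Λ/m recursion against the direct
`max_t Σ_{k=t..n}` formulation evaluated exhaustively over change
points.

## Fusion

Votes are taken per beat on the *level* signals, not on point
detections with a tolerance window: the voting rule `Σ dᵢ > n/2` is
instantaneous, and level-based voting introduces no extra simultaneity
parameter.  Consequences tested as properties: the fused detection
instant is the second-order statistic of the local rise times; fusion
never fires with ≤ 1 active detector and always fires with 3.  Traces
must share one beat grid (detectors run on the same series do by
construction); fusing traces from different grids is rejected rather
than resampled.  Attribution labels each fused detection with the
subset of detectors active at that instant.

## Event annotation

Definitions: `B100_5` (HR < 100 bpm for ≥ 5 s), `B80_10` (HR < 80 bpm
for ≥ 10 s) and the clinical rule (severe events always; yellow events
only with apnea plus an SpO₂ drop ≥ 10 points, and never when explained
by a low basal rate or periodic-breathing oscillations).  `B80_10` and
clinically significant events are subsets of `B100_5` by construction.

A run's duration is the elapsed time from the start of its first
sub-threshold interval to its last sub-threshold beat — i.e. first/last
crossing, including the first interval.  Multiphasic merging: two
sub-threshold runs belong to one event when the time spent *above
100 bpm* between them is shorter than 10 s.  The gap clock uses the
100 bpm threshold for every definition (severe events' interludes
typically hover between 80 and 100 bpm; only time above the yellow
threshold counts against the merge), and `merge_gap = 0` disables
merging.

**Sigmoid onset adjustment.**  The RR transition in a ±15 s window
around an annotated onset is fitted with
`f(t) = A + B/(1 + exp(−(t − t0)/s))` (scipy `curve_fit`;
initialisation A = first-quarter mean, B = last-minus-first quarter
difference, t0 = steepest finite-difference slope, s = 1 s).  The
adjusted onset is the earliest t with `f'(t) > 1`, with the derivative
threshold read in **ms/s** — the only units in which typical
bradycardia slopes (hundreds of ms over a few seconds, peak slope
`B/4s` ~ 50–150 ms/s) make a threshold of 1 meaningful.  The crossing
has the closed form `t = t0 + s·log(u/(1−u))` with
`u = (1 − √(1 − 4s/B))/2`, verified against a bracketed numerical root;
when the peak slope never reaches the threshold (or the fit fails) the
procedure falls back to the annotated instant with a warning.  Offsets
are adjusted by the same procedure on the time-reversed recovery
transition (only the onset procedure is defined; the reversal is the
natural mirror and is exact on symmetric events).

## Synthetic cohort

The generator emulates what the detectors assume about preterm
recordings; its defaults are the study conditions and are not tuned per
experiment:

* 50 records × 1800 s (25 cohort-hours — enough for ~100 severe events
  while keeping any desk-scale run in seconds);
* baseline HR 155 ± 10 bpm across records; within a record, RR =
  60000/HR plus AR(1) noise (coefficient 0.8, stationary sd 10 ms),
  clipped to [250, 600] ms — the 600 ms cap means baseline variability
  alone can never cross the 100 bpm threshold, so every sub-threshold
  excursion is an injected event;
* events at 4/h (Poisson), morphology mix 0.66/0.24/0.10
  mono/bi/triphasic, nadir uniform in 50–75 bpm, time-below-threshold
  uniform in 12–25 s, inter-phase interludes of 3–7 s;
* event morphology is a product-of-logistics HR dip (ramp scale
  1.2 s), rendered *noiselessly* inside the event window so the
  analytic ground truth (threshold crossings and slope-based onset of
  the continuous profile, on a 20 ms grid) is unambiguous; noise
  robustness of the sigmoid fit is exercised separately by Monte-Carlo
  tests;
* SpO₂ at 1 Hz, baseline 95–99 %, with desaturations ≥ 10 points that
  begin 2–5 s *before* the bradycardia onset (apnea precedes the heart
  rate response) for the 85 % of events flagged as apnea-coupled;
* artifacts at 1/h — a missed beat (two intervals fuse) or a spurious
  beat (one interval splits) — placed at least 15 s from any event.
  A fused interval reads as a sub-100 bpm sample for under 1.5 s, far
  below the 5 s definition floor, so artifacts perturb detectors but
  never the truth;
* periodic breathing in 30 % of records: a sinusoidal HR modulation
  (10–15 s period, 5–15 bpm amplitude).

What the generator deliberately does not model: ECG-level noise and
QRS mis-detection statistics, autonomic coupling between respiration,
SpO₂ and heart rate, drifting baselines beyond AR(1)+sinusoid, or the
heavy-tailed artifact bursts of real electrode trouble.  Passing the
cohort benchmark therefore demonstrates the *relative* behaviour of the
detectors under the assumed signal model, not clinical performance
figures; the sensitivity/FAR/delay magnitudes on synthetic data are not
comparable to bedside numbers.

## Evaluation protocol

Matching is greedy in time order: each detection (after adding the
1512 ms real-time acquisition/QRS latency) claims the earliest
unserved annotation whose −5/+30 s window contains it; later detections
in a served window are ignored (not FPs); further annotations covered
by the same detection are ignored (not FNs); everything else is FP/FN.
Delays are measured from *adjusted* onsets.  Sensitivity and FAR are
pooled over the cohort; delays of events detected by both arms enter a
two-sided Wilcoxon signed-rank test (α = 0.05).

In the cohort benchmark the monitor-like baseline is the fixed-threshold
detector running on the very same RR stream as the fusion arm, so both
arms receive the same latency compensation by default; the
`compensate_monitor=False` switch models an externally captured monitor
alarm whose own latency is already embedded in its timestamps.

## Numerical and degenerate-input conventions

* Trailing means return NaN on an empty window; a NaN adaptive
  threshold disarms the detector at that beat.
* The Page–Hinkley baseline falls back to the current interval where
  undefined (first beat), making the first increment exactly −ν/2.
* Sigmoid fits require ≥ 6 beats in the window and reject |B| < 1 ms as
  "no transition"; fits are canonicalised to s > 0.
* Metrics with empty denominators (no events, no detections) are NaN,
  never exceptions; delay SD is NaN with fewer than two TPs.
* Wilcoxon on identical paired vectors is degenerate: (NaN, NaN).
* All randomness flows from `numpy.random.default_rng` seeds;
  regeneration with the same seed and library versions is bit-exact
  (across versions, agreement to ~1e-9 is the documented expectation).

## Known limitations

* The pair/triple fusion attribution is computed at the fused detection
  instant; computing it over whole events would shift the percentages.
* The onset-adjustment shift on synthetic events (≈ −6 s) is larger in
  magnitude than typical clinical reports, because the generator's
  logistic ramps have long shallow tails; only the shift's sign (and
  the closed-form/numerical agreement) is asserted.
* The benchmark's absolute false alarm rate is dominated by
  re-detections of long multiphasic events outside the +30 s window
  and by borderline events excluded from a definition's truth set —
  mechanisms present in, but not calibrated to, bedside data.
* `n` = 3 detectors is assumed throughout the shipped configurations;
  the voting rule accepts any n ≥ 2 but is untested beyond 3.
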