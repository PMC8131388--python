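"""Sigmoid onset adjustment: reproducible event boundaries from RR data.

Fits the four-parameter logistic A + B/(1 + exp(-(t-t0)/s)) to the RR
transition around an annotated onset and moves the annotation to the
first instant where the fitted slope exceeds 1 ms/s — earlier, and far
less jittery, than a manually placed threshold-crossing mark.
"""

import neobrady as nb

config = nb.CohortConfig()
baseline = nb.simulate_baseline(config, seed=9, duration=400.0, baseline_hr=158.0)
series, truth = nb.inject_event(baseline, at=200.0, nadir=65.0, duration=14.0)

annotated = truth.onset_raw  # the 100 bpm crossing a clinician would mark
fit = nb.fit_sigmoid(series, (annotated - 15.0, annotated + 15.0))
adjusted = nb.adjust_onset(series, annotated)

print(f"annotated onset (100 bpm crossing): {annotated:8.2f} s")
print(
    f"fitted logistic: A={fit.a:6.1f} ms  B={fit.b:6.1f} ms  "
    f"t0={fit.t0:7.2f} s  s={fit.s:5.2f} s  (RMS residual {fit.residual:.2f} ms)"
)
print(f"peak RR slope B/(4s): {fit.max_slope:8.1f} ms/s")
print(f"adjusted onset (first slope > 1 ms/s): {adjusted:8.2f} s")
print(f"shift: {adjusted - annotated:+.2f} s")
print(
    "\nThe adjusted onset precedes the crossing annotation: the cycle\n"
    "length starts lengthening before the heart rate falls through the\n"
    "alarm threshold, and detection delays are measured from this\n"
    "reproducible instant."
)
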