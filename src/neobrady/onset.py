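"""Sigmoid-based adjustment of annotated bradycardia onsets/offsets.

Manual onset annotations carry jitter of a second or two.  To obtain a
reproducible reference instant, the RR series around the annotated onset
is interpolated by a four-parameter logistic

    f(t) = A + B / (1 + exp(-(t - t0) / s))        [RR in ms, t in s]

and the adjusted onset is the FIRST time the fitted derivative exceeds
1 ms/s — the moment the cycle length starts lengthening appreciably,
which precedes the threshold crossing a clinician marks.  The derivative
has the closed form

    f'(t) = (B / s) * u * (1 - u),   u = logistic((t - t0) / s)

whose maximum is B / (4 s) at t0; when that maximum never reaches the
threshold the adjustment falls back to the annotated instant.  Offsets
are adjusted by the same procedure applied to the time-reversed recovery
transition (falling RR becomes a rising sigmoid in reversed time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .series import RRSeries

__all__ = [
    "SigmoidFit",
    "FitError",
    "sigmoid",
    "sigmoid_slope",
    "fit_sigmoid",
    "slope_crossing",
    "adjust_onset",
    "adjust_offset",
]

MIN_BEATS = 6


class FitError(RuntimeError):
    """Sigmoid fit failed or degenerate (no transition in window)."""


def sigmoid(t, a, b, t0, s):
    """Four-parameter logistic A + B / (1 + exp(-(t - t0)/s))."""
    return a + b / (1.0 + np.exp(-(np.asarray(t, dtype=float) - t0) / s))


def sigmoid_slope(t, b, t0, s):
    """Derivative of :func:`sigmoid`: (B/s) u (1-u), ms/s."""
    u = 1.0 / (1.0 + np.exp(-(np.asarray(t, dtype=float) - t0) / s))
    return (b / s) * u * (1.0 - u)


@dataclass(frozen=True)
class SigmoidFit:
    a: float         # lower asymptote, ms
    b: float         # amplitude, ms
    t0: float        # inflection instant, s
    s: float         # time scale, s
    residual: float  # RMS residual, ms

    @property
    def max_slope(self) -> float:
        """Peak derivative |B|/(4|s|), ms/s (attained at t0)."""
        return abs(self.b) / (4.0 * abs(self.s))

    def __call__(self, t):
        return sigmoid(t, self.a, self.b, self.t0, self.s)

    def slope(self, t):
        return sigmoid_slope(t, self.b, self.t0, self.s)


def fit_sigmoid(series: RRSeries, window: tuple[float, float]) -> SigmoidFit:
    """Least-squares logistic fit to the (beat_time, rr) pairs in a window.

    Initialisation: A = mean RR of the window's first quarter, B = last
    quarter's mean minus A, t0 = the instant of steepest finite-difference
    slope, s = 1 s.  Raises :class:`FitError` on non-convergence or a
    degenerate (|B| < 1 ms) transition, and ValueError with fewer than
    6 beats in the window.
    """
    lo, hi = window
    mask = (series.beat_time >= lo) & (series.beat_time <= hi)
    t = series.beat_time[mask]
    rr = series.rr[mask]
    if t.size < MIN_BEATS:
        raise ValueError(
            f"sigmoid fit needs >= {MIN_BEATS} beats in window, got {t.size}"
        )
    q = max(2, t.size // 4)
    a0 = float(np.mean(rr[:q]))
    b0 = float(np.mean(rr[-q:]) - a0)
    if abs(b0) < 1e-9:
        b0 = 1e-9
    slopes = np.diff(rr) / np.maximum(np.diff(t), 1e-9)
    k = int(np.argmax(np.abs(slopes)))
    t0_0 = float(0.5 * (t[k] + t[k + 1]))
    p0 = (a0, b0, t0_0, 1.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # overflow in exp during search
            popt, _ = curve_fit(sigmoid, t, rr, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"sigmoid fit did not converge: {exc}") from exc
    a, b, t0, s = (float(v) for v in popt)
    if not all(np.isfinite([a, b, t0, s])) or s == 0.0:
        raise FitError("sigmoid fit returned non-finite or degenerate parameters")
    if abs(b) < 1.0:
        raise FitError("no transition in window (|B| < 1 ms)")
    # canonical orientation: s > 0 (B carries the direction)
    if s < 0:
        a, b, t0, s = a + b, -b, t0, -s
    resid = float(np.sqrt(np.mean((sigmoid(t, a, b, t0, s) - rr) ** 2)))
    return SigmoidFit(a=a, b=b, t0=t0, s=s, residual=resid)


def slope_crossing(fit: SigmoidFit, threshold: float = 1.0) -> float | None:
    """Earliest t with f'(t) > threshold, in closed form.

    Solving (B/s) u (1-u) = threshold gives u(1-u) = threshold*s/B; the
    smaller root u- maps to t = t0 + s*log(u/(1-u)).  Returns None when
    the peak slope B/(4s) never reaches the threshold (B <= 0 included:
    a falling transition never has positive slope).
    """
    if fit.b <= 0:
        return None
    c = threshold * fit.s / fit.b
    if c >= 0.25:  # max of u(1-u) is 1/4 at u=1/2
        return None
    u = 0.5 * (1.0 - np.sqrt(1.0 - 4.0 * c))
    return float(fit.t0 + fit.s * np.log(u / (1.0 - u)))


def adjust_onset(
    series: RRSeries,
    annotated_onset: float,
    fit_window: float = 15.0,
    slope_threshold: float = 1.0,
) -> float:
    """Adjusted onset: first instant the fitted RR slope exceeds 1 ms/s.

    Fits the logistic on ``annotated_onset +/- fit_window`` and returns
    the closed-form slope crossing.  Falls back (with a warning) to the
    annotated instant when the fit fails or its peak slope stays at or
    below the threshold.
    """
    try:
        fit = fit_sigmoid(
            series, (annotated_onset - fit_window, annotated_onset + fit_window)
        )
    except (FitError, ValueError) as exc:
        warnings.warn(f"onset adjustment fell back to annotation: {exc}")
        return float(annotated_onset)
    t = slope_crossing(fit, slope_threshold)
    if t is None:
        warnings.warn(
            "onset adjustment fell back to annotation: peak sigmoid slope "
            f"{fit.max_slope:.3g} ms/s <= threshold {slope_threshold:g}"
        )
        return float(annotated_onset)
    return t


def adjust_offset(
    series: RRSeries,
    annotated_offset: float,
    fit_window: float = 15.0,
    slope_threshold: float = 1.0,
) -> float:
    """Adjusted offset: the onset procedure on the time-reversed recovery.

    The RR series in ``annotated_offset +/- fit_window`` is reflected
    about the annotated offset (recovery's falling RR becomes a rising
    sigmoid), adjusted as an onset, and the result mapped back.
    """
    lo, hi = annotated_offset - fit_window, annotated_offset + fit_window
    mask = (series.beat_time >= lo) & (series.beat_time <= hi)
    t = series.beat_time[mask]
    rr = series.rr[mask]
    if t.size < MIN_BEATS:
        warnings.warn("offset adjustment fell back to annotation: too few beats")
        return float(annotated_offset)
    rev = RRSeries(beat_time=(2.0 * annotated_offset - t)[::-1], rr=rr[::-1])
    adj_rev = adjust_onset(rev, annotated_offset, fit_window, slope_threshold)
    return float(2.0 * annotated_offset - adj_rev)
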