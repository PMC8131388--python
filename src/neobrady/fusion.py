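"""Decentralized majority-vote fusion of local detector decisions.

With n local detectors emitting binary decisions d_i, the fused decision
fires when sum(d_i) > n/2 — for the three detectors used here, when at
least two alarm levels are simultaneously active.  Votes are taken on
the per-beat LEVEL signals (not on point detections with a tolerance
window): the voting rule is instantaneous and needs no extra parameter.
A consequence tested as a property: the fused detection instant is the
moment the SECOND detector's level rises.

`attribute_detections` labels each fused detection with the subset of
detectors active at that instant, reproducing the pair/triple
contribution breakdown reported for the fusion detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detectors import AlarmTrace

__all__ = ["FusionBreakdown", "fuse_majority", "attribute_detections"]


class FusionError(ValueError):
    """Traces incompatible for fusion (mismatched beat grids)."""


def _common_grid(traces: dict[str, AlarmTrace]) -> np.ndarray:
    items = list(traces.values())
    grid = items[0].beat_time
    for t in items[1:]:
        if t.beat_time.shape != grid.shape or not np.array_equal(t.beat_time, grid):
            raise FusionError("alarm traces are not on a common beat grid")
    return grid


def fuse_majority(traces: dict[str, AlarmTrace]) -> AlarmTrace:
    """Fuse local alarm levels by majority vote (sum d_i > n/2 per beat).

    All traces must share one beat grid (detectors run on the same
    RRSeries do by construction); traces from different grids are
    rejected rather than resampled.
    """
    if len(traces) < 2:
        raise FusionError("fusion requires at least two local detectors")
    grid = _common_grid(traces)
    n = len(traces)
    votes = np.sum([t.level.astype(int) for t in traces.values()], axis=0)
    level = (votes > n / 2).astype(np.uint8)
    return AlarmTrace.from_level(grid, level)


@dataclass(frozen=True)
class FusionBreakdown:
    """Which detector subset produced each fused detection.

    ``per_detection`` maps each fused detection instant to the sorted
    tuple of detector names whose level was active then; ``fractions``
    aggregates these into percentages summing to 100.
    """

    per_detection: list[tuple[float, tuple[str, ...]]]
    fractions: dict[tuple[str, ...], float]

    @property
    def n_detections(self) -> int:
        return len(self.per_detection)


def attribute_detections(
    fused: AlarmTrace, traces: dict[str, AlarmTrace]
) -> FusionBreakdown:
    """Label every fused detection with the locally-active detector subset."""
    grid = _common_grid(traces)
    if fused.beat_time.shape != grid.shape or not np.array_equal(fused.beat_time, grid):
        raise FusionError("fused trace is not on the local traces' beat grid")
    names = sorted(traces)
    per_detection: list[tuple[float, tuple[str, ...]]] = []
    idx = np.searchsorted(grid, fused.detections)
    for i, t_det in zip(idx, fused.detections):
        active = tuple(n for n in names if traces[n].level[i])
        if len(active) < 2:
            raise FusionError(
                f"fused detection at {t_det:.3f}s with fewer than 2 active detectors"
            )
        per_detection.append((float(t_det), active))
    fractions: dict[tuple[str, ...], float] = {}
    if per_detection:
        for _, subset in per_detection:
            fractions[subset] = fractions.get(subset, 0.0) + 1.0
        total = len(per_detection)
        fractions = {k: 100.0 * v / total for k, v in fractions.items()}
    return FusionBreakdown(per_detection=per_detection, fractions=fractions)
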