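import numpy as np
import pytest

from neobrady import RRSeries


def random_rr_series(rng: np.random.Generator, n_beats: int = 150) -> RRSeries:
    """Piecewise-constant RR with random jumps plus noise.

    Built to exercise detector state machines: segments alternate
    between fast baselines and slow (bradycardic) levels, with
    occasional values straddling the printed thresholds.
    """
    levels = []
    remaining = n_beats
    while remaining > 0:
        seg = int(rng.integers(5, 40))
        seg = min(seg, remaining)
        level = float(rng.choice([350.0, 400.0, 450.0, 620.0, 760.0, 810.0, 900.0]))
        levels.extend([level] * seg)
        remaining -= seg
    rr = np.array(levels) + rng.normal(0.0, 15.0, size=n_beats)
    rr = np.clip(rr, 250.0, 1400.0)
    beat_time = np.cumsum(rr) / 1000.0
    return RRSeries(beat_time=beat_time, rr=rr)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
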