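import numpy as np
import pytest

from pentrack.io import TrajectorySet
from pentrack.simulate import SimConfig, simulate_pen


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def clean_scenario():
    """Noise-free 4-animal scenario: detections equal ground truth."""
    cfg = SimConfig(
        seed=7,
        duration=20.0,
        occlusion_rate=0.0,
        baseline_miss_rate=0.0,
        jitter_sd=0.0,
    )
    return simulate_pen(cfg)


@pytest.fixture(scope="session")
def noisy_scenario():
    """Default-noise 1-minute scenario with occlusion episodes."""
    return simulate_pen(SimConfig(seed=11, duration=60.0))


def random_trajectory_set(rng, n_ids=3, n_frames=10, p_present=0.8, size=20.0, span=100.0):
    """Small random TrajectorySet used by metric oracle comparisons."""
    ts = TrajectorySet(fps=25.0)
    for tid in range(1, n_ids + 1):
        for f in range(n_frames):
            if rng.random() < p_present:
                l, t = rng.uniform(0, span, 2)
                w, h = rng.uniform(size / 2, size, 2)
                ts.add(tid, f, (l, t, w, h))
    if ts.n_boxes() == 0:
        ts.add(1, 0, (0, 0, size, size))
    return ts
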