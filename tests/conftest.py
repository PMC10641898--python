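import numpy as np
import pytest

from caimnet.behavior import BoutSegmentation, segment_bouts
from caimnet.synthetic import SimConfig, simulate_speed, simulate_traces


@pytest.fixture(scope="session")
def small_session():
    """One simulated 600-s session with default study conditions."""
    cfg = SimConfig(n_cells=6, seed=11)
    speed, bouts = simulate_speed(cfg)
    seg = segment_bouts(speed)
    traces, truth = simulate_traces(cfg, bouts)
    return cfg, speed, seg, traces, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def alternating_segmentation(n: int, block: int = 300, fs: float = 20.0) -> BoutSegmentation:
    """Rest/run tiling in equal blocks, for tests that need exact state times."""
    labels = ["rest", "run"]
    intervals = [
        (k, min(k + block, n), labels[(k // block) % 2]) for k in range(0, n, block)
    ]
    return BoutSegmentation(intervals, n_samples=n, fs=fs)


def sparse_train(rng, n: int, rate_per_min: float = 2.2, fs: float = 20.0,
                 rise_lo: int = 6, rise_hi: int = 15) -> np.ndarray:
    """Binarized event train with Poisson onsets and variable rising phases."""
    x = np.zeros(n, dtype=np.uint8)
    for o in np.flatnonzero(rng.random(n) < rate_per_min / 60.0 / fs):
        x[o : o + rng.integers(rise_lo, rise_hi)] = 1
    return x
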