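import numpy as np
import pytest

from calcispect import SimulationConfig, simulate_movie, simulate_traces


@pytest.fixture(scope="session")
def small_movie():
    """3 planted oscillatory spots, clean enough for exact recovery."""
    cfg = SimulationConfig(
        image_height_px=64,
        image_width_px=64,
        n_frames=400,
        n_rois=3,
        fraction_oscillatory=1.0,
        noise_sd=0.02,
        rng_seed=42,
    )
    movie, gt = simulate_movie(cfg)
    return cfg, movie, gt


@pytest.fixture(scope="session")
def oscillatory_cohort():
    """100 units, all oscillatory, 60 s at 20 Hz, default amplitudes."""
    cfg = SimulationConfig(
        n_rois=100,
        fraction_oscillatory=1.0,
        n_frames=1200,
        aperiodic_amplitude=0.05,
        rng_seed=7,
    )
    traces, gt = simulate_traces(cfg)
    return cfg, traces, gt


@pytest.fixture
def rng():
    return np.random.default_rng(0)
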