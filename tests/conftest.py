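import numpy as np
import pytest

from ecogsleep import synthdata as sd


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully-featured simulation shared across test modules."""
    cfg = sd.SimConfig(
        n_channels=3,
        fs=512.0,
        duration=120.0,
        spindle_rate=0.1,
        spindle_amp_snr=4.0,
        spike_rate=2.0,
        coupling_pairs=((0, 1, 0.8),),
        seed=42,
    )
    rec, truth = sd.simulate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
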