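import numpy as np
import pytest

from evobci.preprocess import EpochSet
from evobci.synth import SynthConfig, generate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_epochs(rng):
    """White-noise epochs: 6 trials, 4 channels, 1 s at 160 Hz."""
    data = rng.standard_normal((6, 4, 160))
    return EpochSet(data=data, labels=np.array([0, 1, 0, 1, 0, 1]),
                    rate_hz=160.0)


@pytest.fixture(scope="session")
def small_subject():
    """One desk-scale synthetic subject with a strong 9-11 Hz effect."""
    cfg = SynthConfig(
        channels=6, trials_per_class=16, rate_hz=160.0, duration_s=2.0,
        planted_band_hz=(9.0, 11.0), erd_depth=0.9, noise_level=2.5, seed=7,
    )
    return generate_subject(cfg)
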