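import numpy as np
import pytest

from capflow import synth


@pytest.fixture(scope="session")
def long_layout():
    """Abstract long channel so test profiles never hit the channel cap."""
    return synth.default_layout(channel_length_cm=40.0)


@pytest.fixture(scope="session")
def sqrt4_profile(long_layout):
    """Noiseless single-regime profile L(t) = sqrt(4 t) at 30 fps."""
    cfg = synth.SynthConfig(noise_sd_cm=0.0, D_early=4.0, D_late=4.0, layout=long_layout)
    return synth.gen_profile(cfg)[0]


@pytest.fixture(scope="session")
def two_regime(long_layout):
    """Two-regime profile: D_early=12, D_late=3, crossover frame 50, 1000 frames."""
    cfg = synth.SynthConfig(
        noise_sd_cm=0.0, D_early=12.0, D_late=3.0, crossover_frame=50,
        n_frames=1000, layout=long_layout,
    )
    return cfg, synth.gen_profile(cfg)[0]
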