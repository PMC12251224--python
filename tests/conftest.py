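import numpy as np
import pytest

from lamstim import SynthConfig, generate_session


@pytest.fixture(scope="session")
def small_pair():
    """Reduced-duration Flash / Flash+AC pair with deep-layer unimodal
    modulation; shared across modules to keep the suite fast."""
    cfg = SynthConfig(seed=21, duration_s=40.0, ramp_s=5.0,
                      modulation_mode="unimodal", modulation_depth=0.4,
                      preferred_phase_deg=-90.0,
                      modulated_layers=("L4C", "L56"))
    flash, flash_ac, truth = generate_session(cfg)
    return flash, flash_ac, truth


@pytest.fixture(scope="session")
def mua_pair():
    """Short session pair with wideband streams for spike analyses."""
    cfg = SynthConfig(seed=23, duration_s=12.0, ramp_s=2.0,
                      include_wideband=True)
    flash, flash_ac, truth = generate_session(cfg)
    return flash, flash_ac, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
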