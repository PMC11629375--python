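import numpy as np
import pytest

from glycoquant.panels import build_default_panel
from glycoquant.quantitation import SpikeConfig
from glycoquant.simulate import InterferenceConfig, NoiseConfig, SimConfig


@pytest.fixture(scope="session")
def panel():
    return build_default_panel()


@pytest.fixture(scope="session")
def spike():
    return SpikeConfig()


def clean_sim_config(**kwargs) -> SimConfig:
    """Simulation config with all stochastic perturbations switched off
    (exact spectra apart from the default mass miscalibration)."""
    defaults = dict(
        noise=NoiseConfig(0.0, 0.0, 0.0),
        interference=InterferenceConfig(0.0, 0.0),
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


def mult_noise_sim_config(**kwargs) -> SimConfig:
    """Multiplicative 5% intensity noise only (no floor, no contaminants)."""
    defaults = dict(
        noise=NoiseConfig(0.05, 0.0, 0.0),
        interference=InterferenceConfig(0.0, 0.0),
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)
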