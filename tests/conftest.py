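import numpy as np
import pytest

from ddherd.ddpcr_sim import AssayConfig, control_profile


@pytest.fixture(scope="session")
def default_config() -> AssayConfig:
    return AssayConfig()


@pytest.fixture(scope="session")
def clean_config() -> AssayConfig:
    """Noise-free, rain-free assay configuration for exactness oracles."""
    return AssayConfig(amplitude_sd=0.0, rain_fraction=0.0)


@pytest.fixture(scope="session")
def skbr3():
    return control_profile("SKBR3")


@pytest.fixture(scope="session")
def ns12911():
    return control_profile("NS12911")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240219)
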