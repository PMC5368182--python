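import numpy as np
import pytest

from rrnthermo import (
    DEFAULT_PRIMERS,
    RrnFamilyConfig,
    default_model,
    generate_rrn_family,
)


@pytest.fixture(scope="session")
def model():
    """Thermometer calibrated on all three reference paralog rows."""
    return default_model()


@pytest.fixture(scope="session")
def model_two_point():
    """Thermometer through the two extreme-GC reference rows (rrsA, rrsC)."""
    return default_model(("rrsA", "rrsC"))


@pytest.fixture(scope="session")
def family():
    """Default synthetic 3-paralog 16S family (seeded)."""
    return generate_rrn_family(RrnFamilyConfig(seed=42))


@pytest.fixture(scope="session")
def primers():
    return DEFAULT_PRIMERS


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
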