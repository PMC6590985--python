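import numpy as np
import pytest

from otokit.population import ProtocolConfig, class_params, simulate_unit
from otokit.stimulus import generate_noise_stimulus


@pytest.fixture(scope="session")
def regular_params():
    return class_params("regular", seed=0)


@pytest.fixture(scope="session")
def irregular_params():
    return class_params("irregular", seed=0)


@pytest.fixture(scope="session")
def frozen_stimulus():
    return generate_noise_stimulus(10.0, cutoff=20.0, sd=0.1, seed=42)


@pytest.fixture(scope="session")
def naturalistic_pair(regular_params, irregular_params, frozen_stimulus):
    """One regular and one irregular unit, 10 repeats of the frozen stimulus."""
    proto = ProtocolConfig(
        resting_duration=30.0,
        naturalistic_repeats=10,
        include_sinusoids=False,
        include_tilts=False,
    )
    reg = simulate_unit("reg00", "regular", regular_params, proto, 101, frozen_stimulus)
    irr = simulate_unit("irr00", "irregular", irregular_params, proto, 202, frozen_stimulus)
    return reg, irr
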