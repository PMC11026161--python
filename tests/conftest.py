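import numpy as np
import pytest

from neurelec.synth import GeneratorConfig

#: geometric area of a 25-um-diameter disc electrode, cm^2
DISC_25UM_CM2 = float(np.pi * (12.5e-4) ** 2)


@pytest.fixture
def cfg0():
    """Noise-free generator config (deterministic forward models)."""
    return GeneratorConfig(seed=0, noise_level=0.0)


@pytest.fixture
def cfg_noise():
    """Default noisy generator config used across end-to-end tests."""
    return GeneratorConfig(seed=2024, noise_level=0.05)


@pytest.fixture
def disc_area():
    return DISC_25UM_CM2
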