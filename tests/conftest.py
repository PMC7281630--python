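import numpy as np
import pytest

from spherefall import MediumState, PhysicsConstants


@pytest.fixture
def medium():
    """Water-like analysis medium: 1 mPa·s, 1000 fg/µm³."""
    return MediumState(viscosity_mpa_s=1.0, density_fg_um3=1000.0)


@pytest.fixture
def constants():
    return PhysicsConstants()


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)
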