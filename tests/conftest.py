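import numpy as np
import pytest

from confocyl.mc import OpticalSystem
from confocyl.phantom import single_cylinder_phantom


@pytest.fixture
def air_optics():
    """NA 0.6 air objective configuration (f = 2 mm, pinhole 1.68 um)."""
    return OpticalSystem(
        na=0.6, focal_length=2.0, pinhole_radius=1.68, n_surround=1.0
    )


@pytest.fixture
def oil_optics():
    """NA 1.4 oil-immersion configuration (f = 0.3 mm, pinhole 0.72 um)."""
    return OpticalSystem(
        na=1.4, focal_length=0.3, pinhole_radius=0.72, n_surround=1.518
    )


@pytest.fixture
def cylinder_air():
    """Single r = 10 um cylinder (n = 1.6285) in air, centred at the origin."""
    return single_cylinder_phantom(10.0, 1.6285, 1.0)


@pytest.fixture
def cylinder_oil():
    """Single r = 10 um cylinder (n = 1.6285) in immersion oil (dn = 0.1105)."""
    return single_cylinder_phantom(10.0, 1.6285, 1.518)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
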