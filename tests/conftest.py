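import numpy as np
import pytest

import fxisim as fx

PHOTON_ENERGY_EV = 1000.0


@pytest.fixture(scope="session")
def wavelength():
    return fx.wavelength_from_energy(PHOTON_ENERGY_EV)


@pytest.fixture(scope="session")
def water():
    return fx.builtin_materials()["water"]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def detector64():
    # 64x64, wide pixels: q_max R ~ 10 for a 40 nm sphere at 1 keV
    return fx.DetectorGeometry(nx=64, ny=64, pixel_size=300e-6,
                               detector_distance=0.74)


@pytest.fixture(scope="session")
def qmap64(detector64, wavelength):
    return fx.qmap_from_detector(detector64, wavelength)


@pytest.fixture(scope="session")
def detector32():
    return fx.DetectorGeometry(nx=32, ny=32, pixel_size=300e-6,
                               detector_distance=0.74)


@pytest.fixture(scope="session")
def qmap32(detector32, wavelength):
    return fx.qmap_from_detector(detector32, wavelength)
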