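import numpy as np
import pytest

from softjam import FluidEnv, JammingParams, PoreGeometry, VirusParams
from softjam.units import molar_to_per_m3


@pytest.fixture(scope="session")
def geom_200nm() -> PoreGeometry:
    """200 nm diameter, 10 um long track-etched pore."""
    return PoreGeometry(radius=100e-9, length=10e-6)


@pytest.fixture(scope="session")
def water() -> FluidEnv:
    return FluidEnv(viscosity=1.0e-3, temperature=295.0)


@pytest.fixture(scope="session")
def hiv() -> VirusParams:
    # hydrodynamic radius back-derived from the 38 s diffusive timescale
    return VirusParams(hydrodynamic_radius=83e-9, label="HIV")


@pytest.fixture(scope="session")
def hiv_params() -> JammingParams:
    return JammingParams(
        kon_pore=0.625,
        koff_clog=1.2e-4,
        Kd_clog=molar_to_per_m3(1.5e-13),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
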