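import numpy as np
import pytest

from mdrc.encoding import (
    Protocol,
    delta_spectra,
    make_desk_protocol,
    protocol_frequency_band,
)
from mdrc.forward import DiffusionComponent, VoxelDistribution
from mdrc.inversion import InversionLimits
from mdrc.synthetic import default_recipes


@pytest.fixture(scope="session")
def desk_protocol() -> Protocol:
    return make_desk_protocol()


@pytest.fixture(scope="session")
def desk_spectra(desk_protocol):
    return delta_spectra(desk_protocol)


@pytest.fixture(scope="session")
def omega_band(desk_protocol):
    return protocol_frequency_band(desk_protocol)


@pytest.fixture(scope="session")
def limits() -> InversionLimits:
    return InversionLimits()


@pytest.fixture
def iso_component() -> DiffusionComponent:
    """Frequency-flat isotropic component (no dispersion: d_par = d_perp = d0)."""
    return DiffusionComponent(
        d0=1e-9, d_par=1e-9, d_perp=1e-9,
        gamma_par=100.0, gamma_perp=100.0, r1=1.0, r2=20.0, w=1.0,
    )


@pytest.fixture
def dispersive_component() -> DiffusionComponent:
    return DiffusionComponent(
        d0=2e-9, d_par=1e-9, d_perp=4e-10,
        gamma_par=2 * np.pi * 80.0, gamma_perp=2 * np.pi * 150.0,
        theta=0.7, phi=1.1, r1=0.8, r2=30.0, w=1.0,
    )


@pytest.fixture(scope="session")
def recipes():
    return default_recipes()


@pytest.fixture
def wm_component(recipes) -> DiffusionComponent:
    return recipes[1].components[0]


@pytest.fixture
def gm_component(recipes) -> DiffusionComponent:
    return recipes[3].components[0]


@pytest.fixture
def fluid_component(recipes) -> DiffusionComponent:
    return recipes[6].components[0]


def random_components(n, rng, limits=None):
    """Random valid components spanning the inversion limits (test helper)."""
    from mdrc.inversion import sample_components

    dist = sample_components(limits or InversionLimits(), n, rng)
    return dist.with_weights(rng.uniform(0.1, 1.0, n))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
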