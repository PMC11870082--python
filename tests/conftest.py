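import numpy as np
import pytest

from maplink import (
    SimulationConfig,
    build_spatial_basis,
    make_parcellation,
)


@pytest.fixture(scope="session")
def grid16():
    """4x4 unit-spacing lattice parcellation with its spatial basis."""
    parc = make_parcellation(SimulationConfig(n_regions=16, geometry="grid", seed=0))
    return parc, build_spatial_basis(parc)


@pytest.fixture(scope="session")
def grid100():
    """10x10 lattice used for calibration-style checks."""
    parc = make_parcellation(SimulationConfig(n_regions=100, geometry="grid", seed=0))
    return parc, build_spatial_basis(parc)


@pytest.fixture(scope="session")
def rand30():
    """30 random regions in the unit cube."""
    parc = make_parcellation(SimulationConfig(n_regions=30, seed=11))
    return parc, build_spatial_basis(parc)


@pytest.fixture(scope="session")
def rand80():
    """Default benchmark geometry: 80 random regions."""
    parc = make_parcellation(SimulationConfig(n_regions=80, seed=7))
    return parc, build_spatial_basis(parc)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
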