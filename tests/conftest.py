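import numpy as np
import pytest

from mweauc.hydro import RotorProtocol, SolventModel, Species, water20
from mweauc.instrument import InstrumentModel, NoiseOptions
from mweauc.presets import (
    aunc_fit_config,
    aunc_two_species_run,
    gfp_like_run,
)


@pytest.fixture(scope="session")
def water():
    return water20()


@pytest.fixture(scope="session")
def analysis_solvent():
    return SolventModel(density=1.0)


@pytest.fixture(scope="session")
def default_instrument():
    return InstrumentModel()


@pytest.fixture(scope="session")
def gfp_run():
    """Single 4 S species dataset plus its generating objects."""
    return gfp_like_run(seed=1)


@pytest.fixture(scope="session")
def aunc_run():
    """Two-species (3.4/3.9 S) nanocluster dataset plus generators."""
    return aunc_two_species_run(seed=2)


@pytest.fixture(scope="session")
def aunc_c2d(aunc_run):
    """2D s-lambda fit of the two-species run (shared: it is expensive)."""
    from mweauc.mwl import MultiWavelengthModel

    ds, species, solvent, protocol, instrument = aunc_run
    model = MultiWavelengthModel(ds, protocol, solvent, aunc_fit_config())
    return model.fit(wavelength_step_nm=3.0, window_nm=(640.0, 900.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
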