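import numpy as np
import pytest

import decosim as ds


@pytest.fixture(scope="session")
def beam300():
    return ds.BeamParameters(300.0)


@pytest.fixture(scope="session")
def lens_cs27():
    return ds.LensConfig(cs_A=2.7e7, source_fwhm_rad=1e-5)


@pytest.fixture(scope="session")
def thin_spectrum():
    return ds.synthetic_thin_spectrum()


@pytest.fixture(scope="session")
def carbon2000_ensemble(beam300, lens_cs27):
    """Shared Monte Carlo transit: 2000 A carbon, 1e5 electrons."""
    specimen = ds.Specimen.single("carbon", 2000.0)
    return ds.simulate_transit(specimen, beam300, 100_000, seed=11, lens=lens_cs27)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
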