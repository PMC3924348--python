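import logging

import numpy as np
import pytest

import deprimap as dm

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def strong_city():
    """One strong-coupling synthetic city, shared across tests."""
    return dm.generate_city(dm.SimConfig.strong_coupling(seed=7, n_tracts=300))


@pytest.fixture(scope="session")
def strong_model(strong_city):
    """Canonical model fitted on the shared strong-coupling city."""
    from deprimap.calibration import city_variable_tables
    from deprimap.transforms import TransformSpec, standardize

    socio_t, land_t = city_variable_tables(strong_city)
    spec = TransformSpec()
    socio_z = standardize(socio_t, spec)
    land_z = standardize(land_t, spec)
    model = dm.fit_cca(socio_z, land_z, transform_spec=spec)
    return model, socio_z, land_z


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
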