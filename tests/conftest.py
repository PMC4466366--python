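import numpy as np
import pytest

import aquatrack as aq


@pytest.fixture(scope="session")
def config():
    return aq.load_config()


@pytest.fixture(scope="session")
def medium(config):
    return config.medium_spec()


@pytest.fixture(scope="session")
def orbital_1b1(medium):
    return medium.orbital("1b1")


@pytest.fixture(scope="session")
def rit_physics(config):
    return config.chain_physics("ritracks_like")


@pytest.fixture(scope="session")
def g4_physics(config):
    return config.chain_physics("geant4dna_like")


@pytest.fixture(scope="session")
def rit_tables(rit_physics):
    from aquatrack.tables import TransportTables
    return TransportTables(rit_physics)


@pytest.fixture(scope="session")
def g4_tables(g4_physics):
    from aquatrack.tables import TransportTables
    return TransportTables(g4_physics)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
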