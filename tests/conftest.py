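import pytest

from gasferm.compounds import load_registry
from gasferm.fba import toy_core_model
from gasferm.thermo import load_thermo_table


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def thermo_table(registry):
    return load_thermo_table(registry=registry)


@pytest.fixture()
def toy_model():
    return toy_core_model()
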