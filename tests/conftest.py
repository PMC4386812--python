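import pytest

from laminaris import ModelSpec


@pytest.fixture(scope="session")
def one_comp_active():
    return ModelSpec.default("one_comp_active_if")


@pytest.fixture(scope="session")
def two_comp_active():
    return ModelSpec.default("two_comp_active_if")


@pytest.fixture(scope="session")
def one_comp_passive():
    return ModelSpec.default("one_comp_passive_if")


@pytest.fixture(scope="session")
def non_spiking():
    return ModelSpec.default("non_spiking")
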