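import pytest

from dpydcea import DecisionModel, default_parameters, gompertz_lifetable


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def lt():
    return gompertz_lifetable()


@pytest.fixture(scope="session")
def model():
    return DecisionModel()


@pytest.fixture(scope="session")
def base_fit(model):
    """Base-case fit shared across tests (the model is deterministic)."""
    return model.fit()
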