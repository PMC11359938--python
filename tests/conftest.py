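import pytest

from zoster_cea import default_parameters, make_synthetic_parameters
from zoster_cea.params import to_dict


@pytest.fixture(scope="session")
def base_params():
    """Packaged base case; session-scoped and treated as read-only."""
    return default_parameters()


@pytest.fixture()
def params(base_params):
    """A private mutable copy of the base case."""
    return base_params.copy()


@pytest.fixture()
def synth_params():
    return make_synthetic_parameters(seed=7)


@pytest.fixture()
def base_config_dict(base_params):
    """Plain-dict form of the base case, for building broken configs."""
    return to_dict(base_params)
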