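import numpy as np
import pytest

from mirabind.sequence_io import load_config
from mirabind.synthetic_fixtures import default_demo_spec, make_dataset


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """The packaged demo fixture, generated once per session."""
    out = tmp_path_factory.mktemp("demo_fixture")
    return make_dataset(default_demo_spec(), out)


@pytest.fixture(scope="session")
def demo_config(demo_bundle):
    return load_config(demo_bundle.config_path)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
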