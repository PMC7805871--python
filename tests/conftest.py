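import pytest

from wfhankle import default_config


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def posterior(cfg):
    return cfg.params_P


@pytest.fixture(scope="session")
def anterior(cfg):
    return cfg.params_A


@pytest.fixture(scope="session")
def geom(cfg):
    return cfg.geometry


@pytest.fixture(scope="session")
def schedule(cfg):
    return cfg.schedule
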