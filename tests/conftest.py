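import logging

import pytest

from hrmsquant.io import read_targets
from hrmsquant.simulate import default_config

logging.getLogger("hrmsquant").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def targets():
    return read_targets()


@pytest.fixture(scope="session")
def targets_by_name(targets):
    return {t.name: t for t in targets}


@pytest.fixture
def make_config():
    """Factory for the stock 8-analyte simulation config."""

    def _make(seed, **overrides):
        return default_config(seed, **overrides)

    return _make
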