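import pytest
from hypothesis import settings

from biocogs import build_uricase_flowsheets, load_config

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def bundle():
    """Packaged uricase case-study configuration (calibrated)."""
    return load_config()


@pytest.fixture(scope="session")
def flowsheets():
    return build_uricase_flowsheets()
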