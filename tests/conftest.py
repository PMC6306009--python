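import pytest
from hypothesis import settings

from cutinseq.monomers import default_catalog

settings.register_profile("default", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("default")


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def mono(catalog):
    """Shortcut: monomer by id."""
    return catalog.get
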