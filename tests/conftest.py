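import pytest

from irpkit.config import Config
from irpkit import simulate as sim


@pytest.fixture(scope="session")
def config():
    return Config()


@pytest.fixture(scope="session")
def templates():
    return {family: sim.template(family) for family in sim.FAMILIES}


@pytest.fixture(scope="session")
def clean_precursors():
    """One noise-free precursor per family."""
    return {family: sim.make_precursor(family, 1, 0.0) for family in sim.FAMILIES}
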