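import pytest

from tracern2o.config import RunConfig
from tracern2o.isotope import IsotopeConstants


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def constants() -> IsotopeConstants:
    return IsotopeConstants()
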