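import pytest

from compas_bc import BandRegistry, ModelConstants


@pytest.fixture(scope="session")
def constants() -> ModelConstants:
    return ModelConstants()


@pytest.fixture(scope="session")
def registry() -> BandRegistry:
    return BandRegistry.default()
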