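import pytest

from bricklab import fixtures


@pytest.fixture(scope="session")
def collection():
    """The packaged registry with synthetic placeholder payloads."""
    return fixtures.load_collection(seed=1)


@pytest.fixture(scope="session")
def demo():
    """(final ClonedPart, AssemblyTree, collection) of the 8-part
    bicistronic MCS construct, built through the full simulator."""
    return fixtures.make_bicistronic_demo(seed=1)


@pytest.fixture(scope="session")
def rmdi_pair():
    return fixtures.make_rmdi_pair(seed=1)


@pytest.fixture(scope="session")
def sespin_template():
    return fixtures.make_sespin_template(seed=1)
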