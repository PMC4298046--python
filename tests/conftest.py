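import pytest

from mutannot import fixtures


@pytest.fixture(scope="session")
def helix12():
    return fixtures.make_helix(12)


@pytest.fixture(scope="session")
def hairpin12():
    return fixtures.make_hairpin(12)


@pytest.fixture(scope="session")
def curated():
    return fixtures.load_curated()


@pytest.fixture(scope="session")
def curated_bundles(curated):
    return fixtures.curated_bundles(curated)
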