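import pytest

from awnloci import synthio, temap


@pytest.fixture(scope="session")
def spec():
    return synthio.default_spec(seed=1)


@pytest.fixture(scope="session")
def reference(spec):
    return synthio.build_reference(spec)


@pytest.fixture(scope="session")
def index(reference):
    return temap.KmerIndex(reference.sequences, k=31)


@pytest.fixture(scope="session")
def windows(spec):
    return temap.boundary_windows(spec.rae1_chrom, spec.te_site, spec.te_length)


@pytest.fixture(scope="session")
def rae2():
    return synthio.rae2_fixture()
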