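import pytest

from cdftkit.reference import PAIRING_MAP, load_reference, species_records


@pytest.fixture(scope="session")
def ref():
    return load_reference()


@pytest.fixture(scope="session")
def ref_records(ref):
    return {r.id: r for r in species_records(ref)}


@pytest.fixture(scope="session")
def pairing_map():
    return PAIRING_MAP
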