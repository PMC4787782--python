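import pytest
from hypothesis import settings

from hairpinfs import datasets as ds

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def dna10_params():
    return ds.reference_two_state_params("DNA10")


@pytest.fixture(scope="session")
def rna10_params():
    return ds.reference_two_state_params("RNA10")


@pytest.fixture(scope="session")
def dna10_construct():
    return ds.reference_construct("DNA10")


@pytest.fixture(scope="session")
def rna10_construct():
    return ds.reference_construct("RNA10")


@pytest.fixture(scope="session")
def all_reference_sets():
    """(name, params, construct, record) for the four benchmark hairpins."""
    out = []
    for name in ("DNA10", "DNA18", "RNA10", "RNA18"):
        out.append((name, ds.reference_two_state_params(name),
                    ds.reference_construct(name), ds.PUBLISHED[name]))
    return out
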