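import pytest

from baitjoint import SeedIndex, build_toy_genome


@pytest.fixture(scope="session")
def reference_spec():
    return build_toy_genome(seed=0)


@pytest.fixture(scope="session")
def reference(reference_spec):
    return reference_spec[0]


@pytest.fixture(scope="session")
def spec(reference_spec):
    return reference_spec[1]


@pytest.fixture(scope="session")
def seed_index(reference):
    return SeedIndex(reference)
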