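import pytest

from localspace import fixtures
from localspace.corpus import Vocabulary


@pytest.fixture(scope="session")
def vocab() -> Vocabulary:
    return Vocabulary()


@pytest.fixture(scope="session")
def fixture_corpus():
    """100 distinct synthetic drug-like molecules (standardized records)."""
    return fixtures.generate_fixture_corpus(
        fixtures.FixtureSpec(n_molecules=100, seed=11)
    ).records


@pytest.fixture(scope="session")
def tiny_pretrained():
    """Benchmark-scale generator pretrained once per session.

    Several tests fine-tune or sample from it; each takes a .clone() so the
    shared pretrained weights stay untouched.
    """
    return fixtures.pretrain_tiny_generator(seed=0)


@pytest.fixture(scope="session")
def campaign_setup():
    """(active seed, 6 inactive seeds, hidden reference) mock benchmark."""
    return fixtures.campaign_seed_set(seed=0)
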