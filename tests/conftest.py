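import numpy as np
import pytest

import ionbind as ib


@pytest.fixture(scope="session")
def worked_fixture():
    """Tiny hand-checkable chain set plus its reference count table."""
    return ib.make_worked_fixture()


@pytest.fixture(scope="session")
def worked_fragments(worked_fixture):
    """L=9 fragments of the worked fixture (one per residue)."""
    chains, _ = worked_fixture
    discretized = [ib.discretize_chain(c) for c in chains]
    return ib.fragments_from_chains(discretized, 9)


@pytest.fixture(scope="session")
def small_chains():
    """A small seeded synthetic chain set with planted signal."""
    spec = ib.GeneratorSpec(n_chains=6, length_mean=80.0, length_sd=15.0,
                            binding_fraction=0.05, seed=11)
    return ib.generate(spec)


@pytest.fixture(scope="session")
def small_fragments(small_chains):
    discretized = [ib.discretize_chain(c) for c in small_chains]
    return ib.fragments_from_chains(discretized, 13)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
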