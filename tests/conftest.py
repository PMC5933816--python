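import pytest

from ltrforest import DomainHierarchy, RunConfig
from ltrforest.io import DomainHit


@pytest.fixture(scope="session")
def hierarchy():
    return DomainHierarchy.default()


@pytest.fixture(scope="session")
def cfg():
    return RunConfig()


@pytest.fixture
def small_cfg():
    """Fewer trees for fast training in unit tests."""
    return RunConfig(n_trees=10, rng_seed=7)


def mk_hit(subject, start, end, strand="+", evalue=1e-20, src="c1"):
    """Hit in internal 0-based half-open coordinates."""
    return DomainHit(subject, start, end, strand, evalue, src)


def hit1(subject, start, end, strand="+", evalue=1e-20, src="c1"):
    """Hit given in 1-based inclusive coordinates (as the paper writes them)."""
    return DomainHit(subject, start - 1, end, strand, evalue, src)


@pytest.fixture
def mk_hit_f():
    return mk_hit


@pytest.fixture
def hit1_f():
    return hit1
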