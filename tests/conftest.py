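import pytest

from entityfuse.synthetic import (
    FixtureSpec,
    make_protocol_triplet_fixture,
    make_unification_example_fixture,
    random_registry,
)


@pytest.fixture
def protocol_triplet():
    """(registry, protocols dict, label->entity_id map)."""
    return make_protocol_triplet_fixture()


@pytest.fixture
def erf1():
    """(registry, recommended protocol, label->entity_id map)."""
    return make_unification_example_fixture()


@pytest.fixture
def small_random():
    """A mid-size random registry with planted classes and promiscuity."""
    return random_registry(FixtureSpec(rng_seed=7, n_classes=15))
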