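import numpy as np
import pytest

from trophoscale import FoodWeb, SyntheticConfig


@pytest.fixture
def w1():
    """Worked four-taxon web: A basal; B eats A; C eats B; D eats A and B."""
    return FoodWeb(
        web_id="W1",
        taxa=frozenset("ABCD"),
        links=frozenset([("B", "A"), ("C", "B"), ("D", "A"), ("D", "B")]),
    )


@pytest.fixture
def chain3():
    """Three-taxon chain: C eats B eats A."""
    return FoodWeb(
        web_id="chain",
        taxa=frozenset("ABC"),
        links=frozenset([("B", "A"), ("C", "B")]),
    )


@pytest.fixture
def small_config():
    """A scaled-down synthetic archipelago for fast end-to-end tests."""
    return SyntheticConfig(
        metaweb_S=45,
        metaweb_C=0.08,
        n_ubiquitous=4,
        n_quadrats=24,
        n_transects=6,
        n_sites=2,
        n_locales=2,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)
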