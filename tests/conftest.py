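import pytest

from dfu_cea.config import ConfigDeck, ResolvedDeck, resolve
from dfu_cea.synthetic_data import generate_reference_deck


@pytest.fixture(scope="session")
def reference_deck() -> ConfigDeck:
    return generate_reference_deck(seed=1)


@pytest.fixture(scope="session")
def rd(reference_deck) -> ResolvedDeck:
    return resolve(reference_deck)
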