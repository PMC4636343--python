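import random

import pytest

from coevolang.semantics import SemanticSpace


@pytest.fixture
def space() -> SemanticSpace:
    """The default 64-meaning space (4 entities, 4+4 predicates)."""
    return SemanticSpace(4, 4, 4)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(12345)
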