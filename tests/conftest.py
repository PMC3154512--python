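import random

import pytest

from catsys import FinMap, FinSet


@pytest.fixture
def map_factory():
    """Deterministic factory for random total maps."""
    rng = random.Random(97)

    def make(dom: FinSet, cod: FinSet, name: str = "f") -> FinMap:
        return FinMap(name, dom, cod,
                      {x: rng.choice(cod.elements) for x in dom})

    return make


@pytest.fixture
def abc():
    return FinSet("abc", ("a", "b", "c"))


@pytest.fixture
def xy():
    return FinSet("xy", ("x", "y"))
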