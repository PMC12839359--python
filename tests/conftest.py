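import numpy as np
import pytest

from mimicnet.graph_core import Network


@pytest.fixture
def path3() -> Network:
    return Network([("A", "B"), ("B", "C")])


@pytest.fixture
def star4() -> Network:
    """Center X with three leaves."""
    return Network([("X", "L1"), ("X", "L2"), ("X", "L3")])


@pytest.fixture
def barbell7() -> Network:
    """Two triangles joined through a single bridge node X."""
    return Network(
        [
            ("a", "b"), ("b", "c"), ("a", "c"),
            ("c", "X"), ("X", "d"),
            ("d", "e"), ("e", "f"), ("d", "f"),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
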