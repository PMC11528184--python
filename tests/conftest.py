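import pytest

from modclust.network import Network


@pytest.fixture
def triangle() -> Network:
    return Network([("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture
def barbell() -> Network:
    """Two triangles {A,B,C} and {D,E,F} joined by the bridge C-D."""
    return Network(
        [("A", "B"), ("B", "C"), ("C", "A"), ("D", "E"), ("E", "F"), ("F", "D"), ("C", "D")]
    )


@pytest.fixture
def two_triangles() -> Network:
    """Two disjoint triangles (no bridge)."""
    return Network(
        [("A", "B"), ("B", "C"), ("C", "A"), ("D", "E"), ("E", "F"), ("F", "D")]
    )


@pytest.fixture
def path3() -> Network:
    return Network([("A", "B"), ("B", "C")])
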