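import numpy as np
import pytest

from nhmc import ClassHierarchy, Network


@pytest.fixture
def tiny_hierarchy() -> ClassHierarchy:
    """Three classes: A, B and B's child B1, with the default decay 0.75."""
    return ClassHierarchy.from_paths(["A", "B", "B/B1"], w0=0.75)


@pytest.fixture
def two_group_instance():
    """Two 4-example groups with distinct closed label vectors, linked only
    within groups — maximal guilt-by-association structure."""
    h = ClassHierarchy.from_paths(["A", "B"], w0=0.75)
    Y = np.array([[1, 0]] * 4 + [[0, 1]] * 4, dtype=np.uint8)
    ids = [f"e{i}" for i in range(8)]
    net = Network()
    for grp in (ids[:4], ids[4:]):
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                net.add_edge(grp[i], grp[j])
    return h, Y, ids, net


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
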