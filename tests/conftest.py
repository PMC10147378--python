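import numpy as np
import pytest

from phenokit.swc import NeuronNode, NeuronTree


@pytest.fixture
def straight_neurite() -> NeuronTree:
    """Soma at origin, two collinear 10 μm edges along +x (total 20 μm)."""
    return NeuronTree(
        [
            NeuronNode(1, 1, 0.0, 0.0, 0.0, 1.0, -1),
            NeuronNode(2, 3, 10.0, 0.0, 0.0, 0.5, 1),
            NeuronNode(3, 3, 20.0, 0.0, 0.0, 0.5, 2),
        ]
    )


@pytest.fixture
def y_tree() -> NeuronTree:
    """Stem of 10 μm then two 5 μm daughters (total 20 μm, 1 branch point)."""
    return NeuronTree(
        [
            NeuronNode(1, 1, 0.0, 0.0, 0.0, 1.0, -1),
            NeuronNode(2, 3, 10.0, 0.0, 0.0, 0.5, 1),
            NeuronNode(3, 3, 13.0, 4.0, 0.0, 0.5, 2),
            NeuronNode(4, 3, 13.0, -4.0, 0.0, 0.5, 2),
        ]
    )


@pytest.fixture
def radial_y_tree() -> NeuronTree:
    """Radial Y: branch node at distance exactly 10, tips at distance exactly
    20 from the soma ((20,0) and the 12-16-20 Pythagorean point)."""
    return NeuronTree(
        [
            NeuronNode(1, 1, 0.0, 0.0, 0.0, 1.0, -1),
            NeuronNode(2, 3, 10.0, 0.0, 0.0, 0.5, 1),
            NeuronNode(3, 3, 20.0, 0.0, 0.0, 0.5, 2),
            NeuronNode(4, 3, 12.0, 16.0, 0.0, 0.5, 2),
        ]
    )


def assert_trees_equal(t1: NeuronTree, t2: NeuronTree, coord_tol: float = 5e-5):
    assert len(t1) == len(t2)
    for a, b in zip(t1.nodes, t2.nodes):
        assert a.id == b.id
        assert a.type_code == b.type_code
        assert a.parent_id == b.parent_id
        assert np.allclose(
            [a.x, a.y, a.z, a.radius], [b.x, b.y, b.z, b.radius], atol=coord_tol
        )
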