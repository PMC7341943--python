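import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from rhizomorph.swc import APOPHYSIS, RHIZOID, THALLUS, Node, TracedTree


@pytest.fixture
def toy_y() -> TracedTree:
    """Small Y-shaped reference tree with hand-computable metrics.

    Thallus root and coincident apophysis at the origin, a 10 µm trunk and
    two 10 µm daughters: total length 30 µm, 2 tips, 1 bifurcation,
    ratio-RGU 15 µm, bifurcation angle arccos(0.28) ~ 73.74 deg, hull 108 µm².
    """
    return TracedTree(
        [
            Node(1, THALLUS, 0.0, 0.0, 0.0, 2.0, -1),
            Node(2, APOPHYSIS, 0.0, 0.0, 0.0, 0.5, 1),
            Node(3, RHIZOID, 0.0, 10.0, 0.0, 0.5, 2),
            Node(4, RHIZOID, 6.0, 18.0, 0.0, 0.5, 3),
            Node(5, RHIZOID, -6.0, 18.0, 0.0, 0.5, 3),
        ],
        cell_id="toy_y",
    )


def make_random_tree(rng: np.random.Generator, n_nodes: int) -> TracedTree:
    """Random geometric tree: each node attaches to a random earlier node."""
    nodes = [Node(1, THALLUS, 0.0, 0.0, 0.0, float(rng.uniform(1, 3)), -1)]
    coords = {1: np.zeros(3)}
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        step = float(rng.uniform(0.2, 5.0))
        pos = coords[parent] + step * direction
        coords[i] = pos
        label = RHIZOID if rng.random() > 0.05 else APOPHYSIS
        nodes.append(
            Node(i, label, float(pos[0]), float(pos[1]), float(pos[2]),
                 float(rng.uniform(0.1, 2.0)), parent)
        )
    return TracedTree(nodes, cell_id=f"rand{n_nodes}")


@pytest.fixture
def random_tree_factory():
    return make_random_tree
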