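"""Shared fixtures: small hand-built networks and random-graph factories."""

from __future__ import annotations

import numpy as np
import pytest

from connectomorph import BinaryNetwork, RegionGeometry


def make_network(edges: list[tuple[int, int]], n: int) -> BinaryNetwork:
    a = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryNetwork(a)


def random_network(rng: np.random.Generator, n: int, p: float) -> BinaryNetwork:
    genome = (rng.random(n * (n - 1) // 2) < p).astype(np.uint8)
    return BinaryNetwork.from_genome(genome, n)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def k4() -> BinaryNetwork:
    return make_network([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)], 4)


@pytest.fixture
def path3() -> BinaryNetwork:
    return make_network([(0, 1), (1, 2)], 3)


@pytest.fixture
def two_cliques() -> BinaryNetwork:
    """Two disjoint K4 cliques on 8 nodes."""
    edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    edges += [(i + 4, j + 4) for i, j in edges]
    return make_network(edges, 8)


@pytest.fixture
def triangle_geometry() -> RegionGeometry:
    return RegionGeometry(np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]))
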