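"""Shared graph fixtures, all built programmatically."""

import networkx as nx
import pytest

from gravityrank import Network
from gravityrank.generators import GeneratorSpec, generate


def net_from_nx(g) -> Network:
    return Network.from_edges(g.edges(), nodes=g.nodes())


def random_graphs(count: int, max_n: int, seed: int, min_n: int = 2):
    """Reproducible stream of small G(n,p) graphs with varied density."""
    rng = __import__("random").Random(seed)
    out = []
    for k in range(count):
        n = rng.randint(min_n, max_n)
        p = rng.uniform(0.1, 0.9)
        out.append(generate(GeneratorSpec("erdos_renyi", n, p=p, rng_seed=seed + k)))
    return out


@pytest.fixture
def path3():
    return generate(GeneratorSpec("path", 3))


@pytest.fixture
def path4():
    return generate(GeneratorSpec("path", 4))


@pytest.fixture
def star4():
    """Hub node 0 with 4 leaves (N = 5)."""
    return generate(GeneratorSpec("star", 4))


@pytest.fixture
def cycle4():
    return generate(GeneratorSpec("cycle", 4))


@pytest.fixture
def k4():
    return generate(GeneratorSpec("complete", 4))


@pytest.fixture
def k5():
    return generate(GeneratorSpec("complete", 5))


@pytest.fixture
def single_edge():
    return Network.from_edges([("a", "b")])


@pytest.fixture
def triangle_pendant():
    """Triangle a-b-c with pendant d attached to a."""
    return Network.from_edges([("a", "b"), ("b", "c"), ("c", "a"), ("a", "d")])


@pytest.fixture
def k4_pendant():
    """K4 on 0..3 plus pendant node 4 attached to 0."""
    g = nx.complete_graph(4)
    g.add_edge(0, 4)
    return net_from_nx(g)


@pytest.fixture
def two_components():
    """A triangle and a disjoint edge."""
    return Network.from_edges([("a", "b"), ("b", "c"), ("c", "a"), ("x", "y")])
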