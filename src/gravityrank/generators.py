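"""Deterministic synthetic-network generators for testing and benchmarking.

Families cover the deterministic fixtures (path, star, cycle, complete) and
the standard random models (random labeled tree, Erdos-Renyi G(n,p),
Barabasi-Albert preferential attachment, Watts-Strogatz small world) that
stand in for real spreading-study networks.  Generation is fully
reproducible: the same :class:`GeneratorSpec` always yields the same edge
set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .graph import Network

__all__ = ["GeneratorSpec", "generate", "FAMILIES"]

FAMILIES = ("path", "star", "cycle", "complete", "tree",
            "erdos_renyi", "barabasi_albert", "watts_strogatz")


@dataclass
class GeneratorSpec:
    """Recipe for one synthetic network.

    family: one of FAMILIES.
    n: node count (for ``star``: the number of leaves, so N = n + 1).
    m: attachment count (barabasi_albert only).
    k: ring-neighbor count (watts_strogatz only, even).
    p: edge / rewiring probability (erdos_renyi, watts_strogatz).
    rng_seed: seed for the random families; ignored by deterministic ones.
    """

    family: str
    n: int
    m: Optional[int] = None
    k: Optional[int] = None
    p: Optional[float] = None
    rng_seed: int = 0


def _from_nx(g: nx.Graph) -> Network:
    return Network.from_edges(g.edges(), nodes=g.nodes())


def generate(spec: GeneratorSpec) -> Network:
    """Build the network described by *spec*; simple, undirected, reproducible."""
    fam, n = spec.family, spec.n
    if fam not in FAMILIES:
        raise ValueError(f"unknown family {fam!r}; choose from {FAMILIES}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if fam == "path":
        return _from_nx(nx.path_graph(n))
    if fam == "star":
        return _from_nx(nx.star_graph(n))  # node 0 is the hub, N = n + 1
    if fam == "cycle":
        return _from_nx(nx.cycle_graph(n))
    if fam == "complete":
        return _from_nx(nx.complete_graph(n))
    if fam == "tree":
        return _from_nx(nx.random_labeled_tree(n, seed=spec.rng_seed))
    if fam == "erdos_renyi":
        if spec.p is None or not 0.0 <= spec.p <= 1.0:
            raise ValueError("erdos_renyi needs edge probability p in [0, 1]")
        return _from_nx(nx.gnp_random_graph(n, spec.p, seed=spec.rng_seed))
    if fam == "barabasi_albert":
        if spec.m is None or spec.m < 1:
            raise ValueError("barabasi_albert needs attachment count m >= 1")
        if n < spec.m + 1:
            raise ValueError(f"barabasi_albert needs n >= m + 1 = {spec.m + 1}")
        # seed growth from a complete graph on m+1 nodes so that every node
        # ends with degree >= m and E = m(m-1)/2 + m(n-m) is predictable
        init = nx.complete_graph(spec.m + 1)
        g = nx.barabasi_albert_graph(n, spec.m, seed=spec.rng_seed,
                                     initial_graph=init)
        return _from_nx(g)
    # watts_strogatz
    if spec.k is None or spec.k < 2 or spec.k % 2:
        raise ValueError("watts_strogatz needs an even ring degree k >= 2")
    if spec.p is None or not 0.0 <= spec.p <= 1.0:
        raise ValueError("watts_strogatz needs rewiring probability p in [0, 1]")
    g = nx.watts_strogatz_graph(n, spec.k, spec.p, seed=spec.rng_seed)
    return _from_nx(g)
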