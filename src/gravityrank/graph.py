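"""Undirected simple graphs, edge-list I/O and topological summary statistics.

The central object is :class:`Network`, a lightweight undirected simple graph
keyed by external node labels (strings or any hashable), with internal integer
indices fixed by first-appearance order so that every downstream computation is
bit-stable across runs.  Summary statistics are the usual suite reported for
spreading-dynamics studies: size, mean degree, mean shortest-path distance,
clustering, degree assortativity, degree heterogeneity H = <k^2>/<k>^2 and the
heterogeneous-mean-field epidemic threshold beta_c ~ <k>/(<k^2> - <k>).
"""

from __future__ import annotations

import io
from collections import deque
from dataclasses import dataclass
from typing import Hashable, Iterable, Iterator, Optional, TextIO

import networkx as nx

__all__ = [
    "Network",
    "SummaryStats",
    "EdgeListParseError",
    "UndefinedStatisticError",
    "load_edge_list",
    "write_edge_list",
    "shortest_paths_from",
    "diameter",
    "average_distance",
    "clustering_coefficient",
    "assortativity",
    "degree_heterogeneity",
    "epidemic_threshold",
    "summarize",
]


class EdgeListParseError(ValueError):
    """Raised for a malformed edge-list line; message names the line number."""


class UndefinedStatisticError(ValueError):
    """Raised when a summary statistic is mathematically undefined for a graph."""


class Network:
    """A simple undirected graph with stable external node labels.

    Invariants: no self-loops, no parallel edges, symmetric adjacency.
    Internal indices 0..N-1 follow first-appearance order of labels.
    """

    __slots__ = ("labels", "index", "adj", "_nx_cache")

    def __init__(self) -> None:
        self.labels: list[Hashable] = []
        self.index: dict[Hashable, int] = {}
        self.adj: list[set[int]] = []
        self._nx_cache: Optional[nx.Graph] = None

    # -- construction -----------------------------------------------------

    def add_node(self, label: Hashable) -> int:
        """Return the internal index of *label*, creating the node if new."""
        i = self.index.get(label)
        if i is None:
            i = len(self.labels)
            self.index[label] = i
            self.labels.append(label)
            self.adj.append(set())
            self._nx_cache = None
        return i

    def add_edge(self, u: Hashable, v: Hashable) -> None:
        """Add the undirected edge u–v; self-loops and duplicates are ignored."""
        iu, iv = self.add_node(u), self.add_node(v)
        if iu == iv:
            return
        if iv not in self.adj[iu]:
            self.adj[iu].add(iv)
            self.adj[iv].add(iu)
            self._nx_cache = None

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[Hashable, Hashable]], nodes: Iterable[Hashable] = ()
    ) -> "Network":
        net = cls()
        for lab in nodes:
            net.add_node(lab)
        for u, v in edges:
            net.add_edge(u, v)
        return net

    # -- basic queries -----------------------------------------------------

    @property
    def N(self) -> int:
        return len(self.labels)

    @property
    def E(self) -> int:
        return sum(len(s) for s in self.adj) // 2

    def __contains__(self, label: Hashable) -> bool:
        return label in self.index

    def __len__(self) -> int:
        return len(self.labels)

    def degree(self, label: Hashable) -> int:
        return len(self.adj[self.index[label]])

    def degrees(self) -> list[int]:
        """Degree sequence in internal index order."""
        return [len(s) for s in self.adj]

    def edges(self) -> Iterator[tuple[Hashable, Hashable]]:
        """Each undirected edge once, in deterministic index order."""
        for i, nbrs in enumerate(self.adj):
            for j in sorted(nbrs):
                if i < j:
                    yield self.labels[i], self.labels[j]

    def neighbors(self, label: Hashable) -> list[Hashable]:
        return [self.labels[j] for j in sorted(self.adj[self.index[label]])]

    def to_networkx(self) -> nx.Graph:
        """networkx view (cached); node identities are the external labels."""
        if self._nx_cache is None:
            g = nx.Graph()
            g.add_nodes_from(self.labels)
            g.add_edges_from(self.edges())
            self._nx_cache = g
        return self._nx_cache

    # -- internal helpers --------------------------------------------------

    def _require(self, label: Hashable) -> int:
        try:
            return self.index[label]
        except KeyError:
            raise KeyError(f"unknown node label: {label!r}") from None

    def bfs_from(self, src: int, max_radius: Optional[int] = None) -> dict[int, int]:
        """Hop counts from internal index *src*, expansion stopped at max_radius."""
        dist = {src: 0}
        frontier = deque([src])
        while frontier:
            i = frontier.popleft()
            d = dist[i]
            if max_radius is not None and d >= max_radius:
                continue
            for j in self.adj[i]:
                if j not in dist:
                    dist[j] = d + 1
                    frontier.append(j)
        return dist

    def connected_components(self) -> list[list[int]]:
        """Components as lists of internal indices, deterministic order."""
        seen: set[int] = set()
        comps: list[list[int]] = []
        for s in range(self.N):
            if s in seen:
                continue
            comp = sorted(self.bfs_from(s))
            seen.update(comp)
            comps.append(comp)
        return comps

    def largest_component(self) -> list[int]:
        comps = self.connected_components()
        if not comps:
            return []
        return max(comps, key=len)

    def is_connected(self) -> bool:
        return self.N <= 1 or len(self.bfs_from(0)) == self.N


@dataclass
class SummaryStats:
    """One row of topological summary statistics; undefined entries are None."""

    N: int
    E: int
    mean_degree: float
    mean_distance: Optional[float]
    clustering: Optional[float]
    assortativity: Optional[float]
    heterogeneity: Optional[float]
    threshold: Optional[float]

    COLUMNS = ("N", "E", "mean_degree", "mean_distance", "clustering",
               "assortativity", "heterogeneity", "threshold")

    def as_row(self) -> list:
        return [getattr(self, c) for c in self.COLUMNS]


# -- edge-list I/O ---------------------------------------------------------


def load_edge_list(source: TextIO | str) -> Network:
    """Parse a plain-text edge list into a :class:`Network`.

    One edge per line as two whitespace-separated labels; ``#`` starts a
    comment; blank lines are skipped.  Input is symmetrized and deduplicated,
    self-loops are dropped, labels are kept verbatim, and first appearance
    fixes the internal index order.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    net = Network()
    for lineno, raw in enumerate(source, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise EdgeListParseError(
                f"line {lineno}: expected two node labels, got {line!r}"
            )
        net.add_edge(tokens[0], tokens[1])
    return net


def write_edge_list(net: Network, sink: TextIO) -> None:
    """Write each undirected edge once, deterministically ordered."""
    for u, v in net.edges():
        sink.write(f"{u} {v}\n")


# -- distances -------------------------------------------------------------


def shortest_paths_from(
    net: Network, source: Hashable, max_radius: Optional[int] = None
) -> dict[Hashable, int]:
    """BFS hop counts from *source*, keyed by label; unreachable nodes absent.

    With *max_radius* only nodes within that many hops appear — this is the
    truncation primitive of the local gravity model.
    """
    if max_radius is not None and max_radius < 1:
        raise ValueError(f"max_radius must be >= 1, got {max_radius}")
    src = net._require(source)
    dist = net.bfs_from(src, max_radius)
    return {net.labels[i]: d for i, d in sorted(dist.items())}


def diameter(net: Network) -> int:
    """Largest hop distance within the largest connected component."""
    comp = net.largest_component()
    if len(comp) < 2:
        raise UndefinedStatisticError(
            "diameter needs >= 2 nodes in the largest component"
        )
    return max(max(net.bfs_from(s).values()) for s in comp)


def average_distance(net: Network) -> float:
    """Mean shortest-path distance over unordered pairs in the largest component."""
    comp = net.largest_component()
    if len(comp) < 2:
        raise UndefinedStatisticError(
            "average distance needs >= 2 nodes in the largest component"
        )
    total = 0
    for s in comp:
        total += sum(net.bfs_from(s).values())
    n = len(comp)
    return total / (n * (n - 1))  # each unordered pair counted twice


# -- degree-sequence statistics --------------------------------------------


def _moments(net: Network) -> tuple[float, float]:
    degs = net.degrees()
    if not degs:
        raise UndefinedStatisticError("empty graph")
    k1 = sum(degs) / len(degs)
    k2 = sum(d * d for d in degs) / len(degs)
    return k1, k2


def clustering_coefficient(net: Network) -> float:
    """Mean local clustering coefficient (Watts–Strogatz average)."""
    if net.N == 0:
        raise UndefinedStatisticError("clustering undefined on the empty graph")
    return nx.average_clustering(net.to_networkx())


def assortativity(net: Network) -> float:
    """Degree assortativity: Pearson correlation of degrees over edge ends."""
    if net.E < 1:
        raise UndefinedStatisticError("assortativity needs at least one edge")
    degs = net.degrees()
    end_degs = {degs[i] for i, nbrs in enumerate(net.adj) if nbrs}
    if len(end_degs) < 2:
        raise UndefinedStatisticError(
            "assortativity undefined: zero degree variance over edge ends"
        )
    return float(nx.degree_pearson_correlation_coefficient(net.to_networkx()))


def degree_heterogeneity(net: Network) -> float:
    """H = <k^2> / <k>^2; equals 1 exactly for regular graphs."""
    k1, k2 = _moments(net)
    if k1 == 0:
        raise UndefinedStatisticError("heterogeneity undefined: all nodes isolated")
    return k2 / (k1 * k1)


def epidemic_threshold(net: Network) -> float:
    """Heterogeneous-mean-field SIR threshold beta_c = <k> / (<k^2> - <k>)."""
    k1, k2 = _moments(net)
    if k2 <= k1:
        raise UndefinedStatisticError(
            f"epidemic threshold undefined: <k^2>={k2} <= <k>={k1}"
        )
    return k1 / (k2 - k1)


def summarize(net: Network) -> SummaryStats:
    """All eight summary statistics; undefined ones become None, not errors."""
    if net.N < 2:
        raise UndefinedStatisticError("summary needs at least 2 nodes")

    def _maybe(fn):
        try:
            return fn(net)
        except UndefinedStatisticError:
            return None

    return SummaryStats(
        N=net.N,
        E=net.E,
        mean_degree=2 * net.E / net.N,
        mean_distance=_maybe(average_distance),
        clustering=_maybe(clustering_coefficient),
        assortativity=_maybe(assortativity),
        heterogeneity=_maybe(degree_heterogeneity),
        threshold=_maybe(epidemic_threshold),
    )
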