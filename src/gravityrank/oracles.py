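"""Brute-force reference implementations for validating the fast paths.

Everything here trades asymptotic cost for being obviously correct: a
triple-loop all-pairs shortest-path relaxation, explicit enumeration of
every shortest path for betweenness, O(N^2) pair counting for Kendall tau,
and an exact SIR outbreak expectation that sums over all 2^E bond-percolation
edge configurations (valid because the one-shot process with recovery
probability 1 is bond percolation from the seed).  Size guards fail loudly
rather than letting an exponential enumeration run away.
"""

from __future__ import annotations

from itertools import combinations
from typing import Hashable, Sequence

from .centrality import ScoreVector
from .graph import Network

__all__ = [
    "brute_force_distances",
    "brute_force_betweenness",
    "brute_force_kendall_tau",
    "exhaustive_sir_expectation",
]

_INF = float("inf")


def brute_force_distances(net: Network) -> dict[Hashable, dict[Hashable, int]]:
    """All-pairs hop distances by Floyd-Warshall; unreachable pairs absent."""
    n = net.N
    if n > 200:
        raise ValueError(f"brute-force distances guarded at N <= 200, got {n}")
    d = [[0 if i == j else _INF for j in range(n)] for i in range(n)]
    for i in range(n):
        for j in net.adj[i]:
            d[i][j] = 1
    for k in range(n):
        dk = d[k]
        for i in range(n):
            dik = d[i][k]
            if dik == _INF:
                continue
            row = d[i]
            for j in range(n):
                alt = dik + dk[j]
                if alt < row[j]:
                    row[j] = alt
    labels = net.labels
    return {
        labels[i]: {labels[j]: int(d[i][j]) for j in range(n) if d[i][j] < _INF}
        for i in range(n)
    }


def _all_shortest_paths(net: Network, s: int, t: int) -> list[tuple[int, ...]]:
    """Every geodesic from s to t as a node tuple (empty if unreachable)."""
    dist = net.bfs_from(s)
    if t not in dist:
        return []
    paths: list[tuple[int, ...]] = []

    def extend(path: tuple[int, ...]) -> None:
        last = path[-1]
        if last == t:
            paths.append(path)
            return
        for j in net.adj[last]:
            if dist.get(j) == dist[last] + 1 and dist[j] <= dist[t]:
                extend(path + (j,))

    extend((s,))
    return paths


def brute_force_betweenness(net: Network) -> ScoreVector:
    """Unnormalized betweenness by explicit enumeration of all geodesics."""
    if net.N > 10:
        raise ValueError(f"brute-force betweenness guarded at N <= 10, got {net.N}")
    acc = [0.0] * net.N
    for s, t in combinations(range(net.N), 2):
        paths = _all_shortest_paths(net, s, t)
        if not paths:
            continue
        w = 1.0 / len(paths)
        for p in paths:
            for i in p[1:-1]:
                acc[i] += w
    return ScoreVector("bc_oracle", dict(zip(net.labels, acc)))


def brute_force_kendall_tau(X: Sequence[float], Y: Sequence[float]) -> float:
    """Kendall tau by O(N^2) pair enumeration with the strict tie rule."""
    n = len(X)
    if len(Y) != n or n < 2:
        raise ValueError("need two aligned sequences of length >= 2")
    num = 0
    for i, j in combinations(range(n), 2):
        dx = (X[i] > X[j]) - (X[i] < X[j])
        dy = (Y[i] > Y[j]) - (Y[i] < Y[j])
        num += dx * dy  # +1 concordant, -1 discordant, 0 if tied in either
    return 2.0 * num / (n * (n - 1))


def exhaustive_sir_expectation(net: Network, seed_node: Hashable,
                               beta: float) -> float:
    """Exact E[F] of the one-shot SIR process by bond-percolation enumeration.

    Each edge is independently open with probability beta; the outbreak is
    the seed's reachable set through open edges.  Sums over all 2^E edge
    configurations, so it is guarded at E <= 20.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    src = net._require(seed_node)
    edges = [(net.index[u], net.index[v]) for u, v in net.edges()]
    m = len(edges)
    if m > 20:
        raise ValueError(f"exhaustive SIR expectation guarded at E <= 20, got {m}")
    n = net.N
    expect = 0.0
    for mask in range(1 << m):
        open_adj: dict[int, list[int]] = {}
        nopen = 0
        for e in range(m):
            if mask >> e & 1:
                u, v = edges[e]
                open_adj.setdefault(u, []).append(v)
                open_adj.setdefault(v, []).append(u)
                nopen += 1
        prob = beta ** nopen * (1.0 - beta) ** (m - nopen)
        if prob == 0.0:
            continue
        seen = {src}
        stack = [src]
        while stack:
            i = stack.pop()
            for j in open_adj.get(i, ()):
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        expect += prob * len(seen) / n
    return expect
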