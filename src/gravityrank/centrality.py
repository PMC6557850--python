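"""Node-influence centralities: the gravity model family and benchmarks.

The gravity model (GM) scores a node by summing, over all other reachable
nodes, the product of the two endpoint degrees divided by the squared
shortest-path distance:

    S(i) = sum_{j != i} k_i * k_j / d_ij^2

in analogy with Newtonian gravity (degree = mass, hop distance = distance).
The local gravity model (LGM) truncates the sum to pairs within a radius R,
which both cuts the cost (a radius-limited BFS per node instead of all-pairs
distances) and suppresses noisy long-range contributions.

Benchmarks provided for comparison: degree centrality, H-index, k-shell
(coreness), closeness, betweenness, and the k-shell-mass gravity centralities
G (fixed interaction radius 3) and G+ (neighbor-sum of G).

All functions return a :class:`ScoreVector`; scores are raw (no
normalization), since evaluation is by rank correlation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

import networkx as nx

from .graph import Network

__all__ = [
    "ScoreVector",
    "degree_centrality",
    "h_index",
    "k_shell",
    "closeness_centrality",
    "betweenness_centrality",
    "gravity_model",
    "local_gravity_model",
    "gravity_centrality_G",
    "extended_gravity_Gplus",
    "all_methods",
    "METHODS",
]

#: radius of the neighborhood psi_i in the k-shell gravity centrality G
G_RADIUS = 3


@dataclass
class ScoreVector:
    """Centrality scores for every node of a network.

    Attributes
    ----------
    method : str
        Identifier of the ranking method (e.g. ``"gm"``, ``"lgm"``).
    params : dict
        Method parameters, e.g. ``{"R": 2}`` for the local gravity model.
    scores : dict
        Map node label -> finite real score, one entry per network node.
    """

    method: str
    scores: dict[Hashable, float]
    params: dict = field(default_factory=dict)

    def ranked(self) -> list[tuple[Hashable, float]]:
        """(label, score) pairs, best first; ties ordered by label repr."""
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], str(kv[0])))

    def aligned(self, order) -> list[float]:
        """Scores as a sequence following the given label order."""
        return [self.scores[lab] for lab in order]


# -- neighborhood-based benchmarks ----------------------------------------


def degree_centrality(net: Network) -> ScoreVector:
    """DC(i) = degree of node i."""
    scores = {net.labels[i]: float(len(net.adj[i])) for i in range(net.N)}
    return ScoreVector("dc", scores)


def h_index(net: Network) -> ScoreVector:
    """Largest h such that node i has >= h neighbors each of degree >= h."""
    degs = net.degrees()
    scores = {}
    for i in range(net.N):
        nd = sorted((degs[j] for j in net.adj[i]), reverse=True)
        h = 0
        while h < len(nd) and nd[h] >= h + 1:
            h += 1
        scores[net.labels[i]] = float(h)
    return ScoreVector("hindex", scores)


def k_shell(net: Network) -> ScoreVector:
    """k-shell (coreness) index by iterative degree pruning; isolates get 0."""
    core = nx.core_number(net.to_networkx()) if net.N else {}
    return ScoreVector("ks", {lab: float(c) for lab, c in core.items()})


# -- path-based benchmarks -------------------------------------------------


def closeness_centrality(net: Network) -> ScoreVector:
    """CC(i) = (n_i - 1) / sum_j d_ij with n_i the size of i's component.

    Evaluated per connected component (component size substitutes for N on
    disconnected graphs); isolated nodes score 0.
    """
    cc = nx.closeness_centrality(net.to_networkx(), wf_improved=False)
    return ScoreVector("cc", {lab: float(v) for lab, v in cc.items()})


def betweenness_centrality(net: Network) -> ScoreVector:
    """Unnormalized shortest-path betweenness over unordered pairs.

    BC(i) = sum over pairs {s,t}, both != i, of the fraction of s–t geodesics
    passing through i.
    """
    bc = nx.betweenness_centrality(net.to_networkx(), normalized=False)
    return ScoreVector("bc", {lab: float(v) for lab, v in bc.items()})


# -- gravity family --------------------------------------------------------


def _gravity_sum(net: Network, masses: list[float], radius: int | None) -> list[float]:
    """Per-node sum of masses[i]*masses[j]/d_ij^2 within the given radius."""
    out = []
    for i in range(net.N):
        dist = net.bfs_from(i, radius)
        s = sum(masses[j] / (d * d) for j, d in dist.items() if d > 0)
        out.append(masses[i] * s)
    return out


def gravity_model(net: Network) -> ScoreVector:
    """GM: S(i) = sum over reachable j != i of k_i*k_j/d_ij^2."""
    degs = [float(d) for d in net.degrees()]
    vals = _gravity_sum(net, degs, None)
    return ScoreVector("gm", dict(zip(net.labels, vals)))


def local_gravity_model(net: Network, R: int) -> ScoreVector:
    """LGM: the gravity sum truncated to pairs with d_ij <= R.

    Computed with a radius-limited BFS per node; for R at or above the
    component diameter it coincides exactly with the gravity model.
    """
    if R < 1:
        raise ValueError(f"truncation radius R must be >= 1, got {R}")
    degs = [float(d) for d in net.degrees()]
    vals = _gravity_sum(net, degs, R)
    return ScoreVector("lgm", dict(zip(net.labels, vals)), {"R": R})


def gravity_centrality_G(net: Network) -> ScoreVector:
    """G: gravity sum with k-shell indices as masses, fixed radius 3."""
    ks = k_shell(net).scores
    masses = [ks[lab] for lab in net.labels]
    vals = _gravity_sum(net, masses, G_RADIUS)
    return ScoreVector("g", dict(zip(net.labels, vals)))


def extended_gravity_Gplus(net: Network) -> ScoreVector:
    """G+: sum of G over each node's direct neighbors."""
    g = gravity_centrality_G(net).scores
    scores = {
        net.labels[i]: sum(g[net.labels[j]] for j in net.adj[i])
        for i in range(net.N)
    }
    return ScoreVector("gplus", scores)


#: method identifier -> callable(net, **params) for all nine ranking methods
METHODS = {
    "bc": betweenness_centrality,
    "cc": closeness_centrality,
    "dc": degree_centrality,
    "hindex": h_index,
    "ks": k_shell,
    "g": gravity_centrality_G,
    "gplus": extended_gravity_Gplus,
    "gm": gravity_model,
    "lgm": local_gravity_model,
}


def all_methods(net: Network, R: int = 1) -> dict[str, ScoreVector]:
    """Score every node by all nine methods (R is the LGM truncation radius)."""
    out = {}
    for name, fn in METHODS.items():
        out[name] = fn(net, R) if name == "lgm" else fn(net)
    return out
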