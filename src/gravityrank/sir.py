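"""Discrete-time SIR spreading and the Monte-Carlo standard influence ranking.

The simulator implements the synchronous susceptible-infected-recovered
process used as ground truth for spreader rankings: one seed starts infected;
each step every infected node independently tries to infect each susceptible
neighbor with probability beta, then every node infected at the start of the
step recovers with probability lam (newly infected nodes cannot recover in
the step they were infected).  The process stops when no infected remain and
returns the final outbreak fraction F = N_r / N.

With lam = 1 every infected node attempts each of its contacts exactly once,
so the process is equivalent to bond percolation with bond probability beta —
a fact the exhaustive test oracle exploits.

The standard ranking repeats this for every node as seed over many
independent runs; randomness is drawn from a per-(node, run) substream so the
result is reproducible and independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

import numpy as np

from .graph import Network, epidemic_threshold

__all__ = ["SIRConfig", "InfluenceVector", "simulate_once",
           "estimate_influence", "standard_ranking"]


@dataclass
class SIRConfig:
    """Parameters of the SIR spreading protocol.

    beta: per-contact infection probability in [0, 1]; defaults are usually
        set to the network's epidemic threshold beta_c.
    lam: per-step recovery probability in (0, 1]; 1 gives the one-shot
        (percolation-equivalent) process.
    runs: independent Monte-Carlo realizations per seed node.
    rng_seed: master seed for the per-(node, run) substreams.
    """

    beta: float
    lam: float = 1.0
    runs: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if not 0.0 < self.lam <= 1.0:
            raise ValueError(f"lam must be in (0, 1], got {self.lam}")
        if self.runs < 1:
            raise ValueError(f"runs must be >= 1, got {self.runs}")

    @classmethod
    def at_threshold(cls, net: Network, **kwargs) -> "SIRConfig":
        """Config with beta set to the network's epidemic threshold."""
        return cls(beta=epidemic_threshold(net), **kwargs)


@dataclass
class InfluenceVector:
    """Mean simulated outbreak fraction F(i) per seed node, with its spread.

    scores maps node label -> mean F over runs (each F in [1/N, 1]);
    stderr maps node label -> standard error of that mean.
    """

    scores: dict[Hashable, float]
    stderr: dict[Hashable, float]
    config: SIRConfig = field(repr=False)

    def aligned(self, order) -> list[float]:
        return [self.scores[lab] for lab in order]


def _run_sir(adj: list[list[int]], src: int, beta: float, lam: float,
             rng: np.random.Generator) -> int:
    """One synchronous SIR realization; returns the recovered count N_r.

    status: 0 susceptible, 1 infected, 2 recovered.  Contact draws for a step
    are batched into one uniform vector; iteration order is deterministic.
    """
    n = len(adj)
    status = bytearray(n)
    status[src] = 1
    infected = [src]
    n_rec = 0
    while infected:
        contacts = [j for i in infected for j in adj[i] if status[j] == 0]
        if contacts:
            draws = rng.random(len(contacts))
            newly: list[int] = []
            for j, u in zip(contacts, draws):
                # a node contacted by several infectors this step is infected
                # if any independent attempt succeeds
                if status[j] == 0 and u < beta:
                    status[j] = 1
                    newly.append(j)
        else:
            newly = []
        if lam >= 1.0:
            for i in infected:
                status[i] = 2
            n_rec += len(infected)
            infected = newly
        else:
            rec = rng.random(len(infected)) < lam
            still = []
            for i, r in zip(infected, rec):
                if r:
                    status[i] = 2
                    n_rec += 1
                else:
                    still.append(i)
            infected = still + newly
    return n_rec


def _sorted_adj(net: Network) -> list[list[int]]:
    return [sorted(s) for s in net.adj]


def simulate_once(net: Network, seed_node: Hashable, beta: float, lam: float,
                  rng: np.random.Generator) -> float:
    """Run one SIR realization seeded at *seed_node*; return F = N_r / N."""
    src = net._require(seed_node)
    return _run_sir(_sorted_adj(net), src, beta, lam, rng) / net.N


def _substream(rng_seed: int, node_idx: int, run: int) -> np.random.Generator:
    """Deterministic, order-independent stream for one (seed node, run) cell."""
    return np.random.default_rng(
        np.random.SeedSequence([abs(int(rng_seed)), node_idx, run])
    )


def estimate_influence(net: Network, seed_node: Hashable,
                       cfg: SIRConfig) -> tuple[float, float]:
    """Mean and standard error of F over cfg.runs independent realizations."""
    src = net._require(seed_node)
    adj = _sorted_adj(net)
    vals = np.empty(cfg.runs)
    for run in range(cfg.runs):
        rng = _substream(cfg.rng_seed, src, run)
        vals[run] = _run_sir(adj, src, cfg.beta, cfg.lam, rng) / net.N
    se = vals.std(ddof=1) / np.sqrt(cfg.runs) if cfg.runs > 1 else 0.0
    return float(vals.mean()), float(se)


def standard_ranking(net: Network, cfg: SIRConfig) -> InfluenceVector:
    """Ground-truth influence: estimate F(i) with every node once as seed."""
    adj = _sorted_adj(net)
    scores: dict[Hashable, float] = {}
    stderr: dict[Hashable, float] = {}
    vals = np.empty(cfg.runs)
    for src, lab in enumerate(net.labels):
        for run in range(cfg.runs):
            rng = _substream(cfg.rng_seed, src, run)
            vals[run] = _run_sir(adj, src, cfg.beta, cfg.lam, rng) / net.N
        scores[lab] = float(vals.mean())
        stderr[lab] = float(vals.std(ddof=1) / np.sqrt(cfg.runs)) if cfg.runs > 1 else 0.0
    return InfluenceVector(scores, stderr, cfg)
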