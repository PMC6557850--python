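# gravityrank

Identify influential spreaders in complex networks with gravity-law
centralities, and validate any node ranking against simulated epidemic
outbreaks.

## The problem

In a spreading process (disease, rumor, innovation) some nodes seed far
larger outbreaks than others. Classic structural centralities capture either
a node's neighborhood (degree, H-index, k-shell) or its position on paths
(closeness, betweenness), but not both. The **gravity model** (GM) combines
them by treating a node's degree as its mass and the shortest-path hop count
as distance:

```
S(i) = Σ_{j≠i}  k_i · k_j / d_ij²
```

A node is influential when it has many neighbors *and* sits close to the
rest of the network. The **local gravity model** (LGM) truncates the sum to
nodes within a radius R:

```
S_R(i) = Σ_{d_ij ≤ R, j≠i}  k_i · k_j / d_ij²
```

which cuts the cost from all-pairs shortest paths to one radius-limited BFS
per node and suppresses noisy long-range interactions. Empirically the best
radius tracks half the average distance, **R\* ≈ ⟨d⟩/2**, so a good LGM needs
no global information at all.

Ground truth comes from the discrete-time SIR model: seed one infected node,
infect each susceptible neighbor of an infected node with probability β per
step, recover with probability λ (here λ = 1, making the process equivalent
to bond percolation), and record the final outbreak fraction F(i) = N_r/N
averaged over many runs, with β at the epidemic threshold
β_c ≈ ⟨k⟩/(⟨k²⟩−⟨k⟩). Agreement between a centrality and this standard
ranking is measured by Kendall's tau over all node pairs,

```
τ = 2(n₊ − n₋) / (N(N−1))
```

with tied pairs counting in neither n₊ nor n₋ (the full pair count stays in
the denominator — deliberately not the tie-corrected tau-b).

Alongside GM/LGM the package implements seven benchmark rankings: degree,
H-index, k-shell, closeness, betweenness, and the k-shell-mass gravity
centralities G (fixed radius 3) and G+ (neighbor-sum of G).

## Worked example

```python
from gravityrank import (SIRConfig, all_methods, evaluate_method,
                         standard_ranking, summarize, sweep_radius)
from gravityrank.generators import GeneratorSpec, generate

net = generate(GeneratorSpec("barabasi_albert", 100, m=2, rng_seed=7))
s = summarize(net)
print(f"N={s.N} E={s.E} <k>={s.mean_degree:.3f} <d>={s.mean_distance:.3f} "
      f"H={s.heterogeneity:.3f} beta_c={s.threshold:.4f}")

cfg = SIRConfig.at_threshold(net, runs=1000, rng_seed=7)   # beta = beta_c, lam = 1
standard = standard_ranking(net, cfg)                      # ground-truth F(i)
prof = sweep_radius(net, standard)
print(f"optimal R* = {prof.optimal_R}, predicted <d>/2 -> R = {prof.predicted_R}")
for name, sv in all_methods(net, R=prof.optimal_R).items():
    print(f"  tau[{name:6s}] = {evaluate_method(net, sv, standard).tau:.4f}")
```

prints

```
N=100 E=197 <k>=3.940 <d>=2.930 H=2.078 beta_c=0.1391
optimal R* = 1, predicted <d>/2 -> R = 1
  tau[bc    ] = 0.4897
  tau[cc    ] = 0.7933
  tau[dc    ] = 0.4921
  tau[hindex] = 0.3685
  tau[ks    ] = 0.0000
  tau[g     ] = 0.8349
  tau[gplus ] = 0.8558
  tau[gm    ] = 0.7570
  tau[lgm   ] = 0.8071
```

The gravity-family methods (g, gplus, gm, lgm) clearly beat the classic
centralities on this scale-free graph, and the heuristic radius prediction
matches the swept optimum. The k-shell tau is 0 because a Barabási–Albert
graph with fixed attachment m has every node in the same core, so that
ranking is one big tie — under the strict tie rule a fully tied ranking
carries no ordering information.

The same workflow is available from the shell for any whitespace-delimited
edge list (`#` comments allowed):

```sh
gravityrank stats network.edges
gravityrank rank network.edges --method lgm          # radius defaults to <d>/2
gravityrank evaluate network.edges --runs 1000 --seed 1
gravityrank sweep-radius network.edges --runs 1000 --seed 1
```

β defaults to the network's epidemic threshold and all effective parameters
are echoed for provenance.

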