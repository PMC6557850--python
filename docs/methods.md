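# Methods

## Graphs and statistics

Networks are simple and undirected. Edge-list input is symmetrized and
deduplicated, self-loops are dropped, and node labels are kept verbatim with
internal indices fixed by first appearance, so every deterministic output is
bit-stable across runs. Disconnected input is supported everywhere: distance
sums run over reachable pairs only (the natural d→∞ limit of an inverse-square
law), the average distance is taken over the largest connected component, and
closeness is evaluated per component with the component size substituted for
N. The CLI warns when a graph is disconnected.

Summary statistics follow the standard definitions: mean degree 2E/N; mean
distance over unordered reachable pairs in the largest component; clustering
as the *average local* (Watts–Strogatz) coefficient, with nodes of degree < 2
contributing 0 — not global transitivity; degree assortativity as the Pearson
correlation of degrees over edge ends (undefined on regular graphs, where the
variance is zero); degree heterogeneity H = ⟨k²⟩/⟨k⟩² (≥ 1, with equality iff
regular); and the heterogeneous-mean-field SIR epidemic threshold
β_c = ⟨k⟩/(⟨k²⟩−⟨k⟩), algebraically identical to 1/(H⟨k⟩−1). Statistics that
are undefined for a particular graph surface as absent fields in the summary
row rather than as failures.

## Gravity centralities

GM treats degree as mass and hop distance as distance:
S(i) = Σ_{j≠i} k_i k_j / d_ij², summed over nodes reachable from i. LGM
truncates the sum at radius R and is computed by a radius-limited BFS per
node — never via a full distance matrix — so its cost is local. For R at or
above the component diameter, LGM equals GM exactly (same summation order,
bit-identical floats). The benchmark gravity variants use k-shell indices as
masses: G fixes the interaction radius at 3 (a literal constant, not a
parameter), and G+ sums G over direct neighbors. Scores are reported raw; no
normalization is applied anywhere, since evaluation is by rank correlation
only.

Benchmark centralities delegate to networkx where the definition is textbook:
betweenness uses unnormalized Brandes counting (unordered pairs, endpoints
excluded, fractional over tied geodesics), closeness uses the per-component
formula without the Wasserman–Faust rescaling, and k-shell is the core
number from iterative degree pruning (isolates get 0). The H-index (largest h
with ≥ h neighbors of degree ≥ h) is computed directly.

## SIR simulator

Synchronous discrete time. Per step: (1) every infected node independently
attempts to infect each currently susceptible neighbor with probability β —
a node receiving several attempts in one step is infected if any succeeds;
(2) every node infected *at the start of the step* recovers with probability
λ. Newly infected nodes cannot recover in the step they were infected, so
with λ = 1 each node performs exactly one round of infection attempts and
the process is bond percolation with bond probability β — the basis of the
exhaustive test oracle, which sums the seed's reachable-set size over all
2^E open/closed edge configurations (guarded at E ≤ 20).

Influence is the final outbreak fraction F = N_r/N ∈ {1/N, …, 1}. The
standard ranking estimates E[F] for every node as seed. Each (seed node,
run) cell draws from its own `numpy` SeedSequence substream keyed by
(master seed, node index, run index), so results are reproducible,
independent of execution order, and a single-node estimate reproduces the
corresponding entry of the full ranking bit for bit. Contact draws within a
step are batched into one uniform vector for speed.

Defaults follow the standard protocol: λ = 1, β = β_c of the input network,
1000 runs per seed node. λ < 1 is fully supported by the simulator but not
exercised by the acceptance checks.

## Kendall's tau and the tie rule

τ = 2(n₊−n₋)/(N(N−1)) over all node pairs, where a pair tied in either
sequence counts in neither n₊ nor n₋ but stays in the denominator. This is
implemented literally (Knight's O(N log N) merge-count; the discordant count
is the number of Y-inversions after sorting by (X, Y), corrected for tie
groups) rather than delegating to a library tau-b, whose variance-style tie
correction would change the values on tied data. One consequence worth
stating: two *identical* score vectors have τ = 1 only when untied; a fully
tied vector (e.g. any centrality on a vertex-transitive graph) has τ = 0
against anything, including itself, because no pair carries ordering
information. Heavily tied rankings such as k-shell on a fixed-m
Barabási–Albert graph are therefore honestly penalized. τ on raw scores
equals τ on ranks, so scores are never pre-ranked.

## Truncation-radius analysis

`sweep_radius` computes LGM tau against the standard ranking for
R = 1..R_max (default: the diameter of the largest component, beyond which
the profile is constant); the optimal R* is the argmax with ties broken
toward the smallest radius (the cheaper model). The heuristic prediction is
the nearest integer to ⟨d⟩/2 with half-integers rounded down and a floor of
1 — consistent with ⟨d⟩ ≈ 4.03 predicting R = 2.
`consecutive_radius_similarity` reports τ between the LGM score vectors at
radius R and R+1; it is purely deterministic and saturates to its
tie-limited maximum once R reaches the diameter.

## Synthetic benchmark and what it shows

The test suite and the acceptance script run entirely on generated graphs:
canonical fixtures (path, star, cycle, complete) with hand-derived expected
values, small random G(n,p) graphs checked against brute-force oracles
(Floyd–Warshall distances, exhaustive geodesic enumeration for betweenness,
O(N²) pair counting for tau, 2^E percolation enumeration for SIR), and a
Barabási–Albert benchmark (N = 500, m = 3, growth seeded from a complete
graph on m+1 nodes so E = m(m−1)/2 + m(n−m)) for the end-to-end protocol.
BA was chosen because its heavy-tailed degrees and small diameter resemble
the collaboration/communication networks this kind of study targets. It does
not reproduce real networks' community structure, degree correlations or
clustering, and its k-core structure is degenerate (coreness ≡ m), so
passing results demonstrate correctness of the machinery and the qualitative
superiority of the gravity family at β = β_c — not quantitative tau values
for any particular real network. Real edge lists can be analyzed directly
through the CLI.

Problem sizes were chosen to keep the full pipeline comfortably interactive:
1000 SIR runs per seed node on the 500-node benchmark (the protocol's run
count), 20000 runs for the Monte-Carlo-vs-exact comparisons (3-standard-error
acceptance bands), 100 random graphs per oracle-equivalence sweep and 1000
random sequence pairs for the tau oracle.

## Numerical notes and limitations

- Gravity sums accumulate in BFS discovery order; LGM↔GM equality at
  R ≥ diameter is exact because the orders coincide.
- The tau merge-count is exact integer arithmetic until the final division.
- Monte-Carlo standard errors use the sample standard deviation (ddof = 1);
  a single run reports stderr 0.
- Degenerate inputs: empty graphs and sub-2-node components raise
  undefined-statistic errors; `summarize` converts these to absent fields;
  β_c is undefined when ⟨k²⟩ ≤ ⟨k⟩ (e.g. perfect matchings).
- Weighted, directed and temporal networks are out of scope, as are
  tunable-exponent or asymmetric gravity variants.
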