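# Methods

## Weight model and renormalisation

Retrograde tracer data give, per injected target area *t*, the fraction of
labelled extrinsic neurons FLNe(s, t) per source area *s*; the in-weights of
every injected area sum to 1, so the absolute in-strength is factored out.
When the per-experiment counts (LNi, LNe, LNtot) are available, the absolute
weights are recovered as LNe(s, t) = FLNe(s, t) · T(t), where T(t) pools the
extrinsic totals of all experiments at *t*. The pooling rule is
configurable (`mean`, `sum`, `max`); the default is the arithmetic mean,
which is stable against unequal numbers of repeat injections — summing would
weight a twice-injected area double. After conversion
Σ_s LNe(s, t) = T(t) within 1e-9, and the inverse conversion
(column normalisation) restores FLNe exactly; zero columns (unmeasured or
unconnected targets) stay zero rather than becoming NaN.

Conventions fixed throughout: `W[s, t]` has sources in rows and targets in
columns; self-links are forbidden; an area is *measured* iff it was an
injection site; inter-area distances are Euclidean between centroids in mm
(the alternative, geodesics along the cortical sheet, needs a surface mesh
and is out of scope).

## Random-walk flow and the map equation

Module detection models network traffic as a teleporting random walk: with
probability 1 − τ the walker follows out-links proportionally to weight,
with probability τ (probability 1 from a node with no out-links) it jumps
uniformly over all nodes. τ defaults to 0.15, the standard PageRank value.
The stationary visit rates p solve p = Mᵀp; both a power iteration
(residual < 1e-12) and a direct linear solve are implemented, and they agree
to better than 1e-10 — the pair serves as a built-in cross-check. Link flow
is f(s, t) = (1 − τ)·p_s·W[s, t]/s_out(s).

The two-level map equation scores a partition M by the description length
of the walk under a two-level Huffman-style code,

L(M) = q·H(Q) + Σ_m p_m^⊙·H(P_m),   q_m = exit flow of module m,

in bits (log₂). Teleportation is *recorded* and uniform over nodes, so a
module's exit flow is its cross-module link flow plus the teleport mass
landing outside it, q_m = (Σ_{i∈m} τ_i p_i)(n − n_m)/n + link exits. This
scheme was chosen because it makes the one-module limit exact: with all
nodes in one module both terms of q vanish and L reduces to the entropy of
the visit rates. Only the flat (two-level) code is implemented; hierarchical
variants are out of scope.

Optimisation is greedy: starting from singletons, nodes move to the
neighbouring module with the best codelength decrease (deltas maintained
incrementally in O(degree) per candidate), followed by greedy module merges,
iterated to convergence; the whole search is repeated from `n_trials`
shuffled node orders (default 100) and the lowest-L partition kept, never
worse than the one-module partition. Both node moves and merges use an
improvement threshold of 1e-10 bits to avoid cycling on float noise, and
the final L is recomputed from scratch to guard against incremental drift.
On graphs small enough to enumerate every set partition the search attains
the exhaustive minimum in ≥95% of random instances (tested). Nodes with no
links at all are *orphans*: excluded from the walk, reported with zero flow
and module id −1. Modules are numbered by descending total flow.

Louvain modularity maximisation (networkx implementation, default
resolution) on the symmetrised matrix provides an independent decomposition
for comparison, with undirected Q = Σ_m (e_m/m − (a_m/m)²); a directed
variant Q = (1/m)Σ_ij[W_ij − s_i^out s_j^in/m]δ(c_i,c_j) is also available.
Both are invariant under global weight rescaling. A run that produces a
single module is flagged degenerate — binarised dense cortical matrices
behave this way, which is itself informative: the weights carry the modular
structure.

## Hub cartography

Per link direction, P_i = 1 − Σ_m (s_im/s_i)² with weighted degrees by
default (the analysis is weight-driven; unweighted mode is retained for
comparison with binary-matrix studies), and z_i standardises the
within-module degree with the *population* standard deviation, following
the original role-cartography convention; σ = 0 modules give z = 0 rather
than an error. Role boundaries (non-hubs split at P = 0.05/0.62/0.80, hubs
at 0.30/0.75, hub cutoff z > 2.5, marginal band 2 < z ≤ 2.5) are
configuration values with the classic metabolic-network defaults — they
were not derived for cortex and may need revisiting, hence configurable.
A node's module is its partition assignment regardless of direction.

## Temporal tracing

Conduction velocity defaults to 1 mm/ms (1 m/s, typical of unmyelinated
local circuits) and each relay adds a 2 ms synaptic delay (equivalent to
2 mm of path). Arrival of a link traversed as the k-th hop is
(cumulative path length)/velocity + (k−1)·delay. Qualifying links must have
weight strictly greater than `min_weight` (default 1 — counts below one
labelled neuron are of unclear meaning) and length strictly less than
`max_length_mm` (default 5 mm, the usual display radius; raise it to follow
pathways further). When a link or node is reachable along several paths the
earliest arrival is kept — the physically meaningful choice for signal
propagation. Filtered-out link counts are reported. In-traces follow links
backwards but events keep the true link orientation.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes:

| parameter | default | rationale |
|---|---|---|
| n_nodes / n_measured | 116 / 55 | areas and injection sites of the marmoset-scale setting |
| box | 25 × 15 × 10 mm | cortical hemisphere extent |
| lambda_decay | 4.57 mm | exponential weight–distance decay length |
| n_modules | 8 | planted module count |
| p_within / p_between | 0.85 / 0.48 | gives ≈ 3300–3500 links after censoring (density ≈ 0.55 of the 115×55 possible), with modules carried mainly by the weight/distance structure |
| log_sigma | 0.5 | log-normal weight noise (natural-log scale) at which the decay length remains recoverable within 10% |
| weight_scale | 100 | sets the absolute count scale (weights are dimensionless cell counts) |
| module_scatter_mm | 2.0 | Gaussian scatter of areas around their module centre, so modules are spatially compact |

Module centres are uniform in the box; membership is balanced round-robin;
a directed link exists with probability p_within/p_between by planted
membership; weights are weight_scale·e^(−d/λ)·e^(N(0, σ²)), strictly
positive. Censoring zeroes the in-link columns of all but the measured
subset, reproducing the in/out degree asymmetry of partially sampled tracer
data. One RNG stream per call; fixed seed ⇒ identical output.

What the generator does *not* emulate: laminar structure, hemispheric
mirroring, neuronal-density gradients, heavy-tailed weight spreads beyond
what distance decay plus log-normal noise produce (real counts span ~6
decades), or expert-guided selection of injection sites (the measured
subset is uniform at random). Passing tests therefore demonstrate
correctness of the algorithms under these statistical assumptions, not
fidelity to any particular real cortex. Under the dense default contrast
the map-equation decomposition may merge spatially adjacent planted modules
— only the strong-separation regime (e.g. p 0.6 vs 0.05) guarantees exact
recovery, and that is the regime the recovery experiments use.

## Numerical choices and degenerate inputs

- Family fits compare bare maximum log likelihoods; all families have two
  parameters, so no AIC/BIC penalty is applied. Zero samples are excluded
  (and counted) for positive-support families; zero-variance samples raise
  a degeneracy error.
- Decay fits are unbinned per-link OLS on log-transformed data; R² is
  reported in that transformed space, matching a straight-line fit on a log
  plot. Links with zero weight or zero distance are excluded and counted.
  λ and γ are invariant under global weight rescaling.
- Flow/codelength tolerances: stationarity residual 1e-12; codelength move
  threshold 1e-10 bits; FLNe column sums validated at 1e-9.
- Ties in link ranking break by (source, target) label order; ties in trace
  events by (order, source, target).
- Duplicate link rows are rejected by default (tracer link lists are unique
  per source–target pair); pooling by sum is explicit opt-in.
- Partition agreement uses sklearn's NMI/ARI with orphans excluded; NMI of
  a one-module vs an all-singletons partition is 0 by that convention.

## Problem sizes used in the checks

The test suite and the acceptance script run entirely on generated data:
the full 116/55 condition for the pipeline-scale quantities, n = 60 with
four planted modules for recovery experiments (20 replicates), n ≤ 8 for
exhaustive-enumeration comparisons (100 instances; Bell(8) = 4140
partitions), and 14–30-node graphs for oracle cross-checks of flow, roles
and tracing.

## Known limitations

- The map-equation teleportation scheme affects module flows at the second
  decimal; results with other InfoMap variants (unrecorded teleportation,
  link teleportation) will differ slightly.
- Greedy search carries no optimality guarantee beyond the small-n
  enumeration evidence; pathological near-tie landscapes may require more
  trials.
- Euclidean centroid distances underestimate true fibre lengths; traced
  arrival times are correspondingly optimistic.
- The FLNe→LNe conversion assumes labelled-neuron counts are comparable
  across experiments; no correction for injection-volume or neuronal-density
  variation is applied.
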