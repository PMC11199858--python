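# cortexflow

Network analysis of mesoscale cortical connectomes measured by retrograde
tracer injections. Tracer studies of primate cortex report, for each injected
(target) area *t*, the fraction of labelled neurons found in every source
area *s* — the **FLNe** weight, which by construction sums to 1 over the
in-links of each injected area. That normalisation throws away the *absolute*
in-link strength. Given the per-experiment labelled-neuron counts, the column
sums can be restored: **LNe(s, t) = FLNe(s, t) · LNe(t)**, where
LNe(t) = Σₛ LNe(s, t) is the target's total extrinsic count. `cortexflow`
performs that renormalisation and the downstream network analysis that it
enables:

- **Weight recovery** — FLNe ↔ LNe conversion with pooling of repeated
  injections, plus readers/writers for link lists, labelled adjacency
  matrices, node metadata and injection records.
- **Descriptive statistics** — degree/strength distributions, maximum-
  likelihood comparison of exponential / normal / log-normal families, and
  OLS fits of the weight–distance relation, `w ∼ e^(−d/λ)` versus
  `w ∼ d^(−γ)`, in log space.
- **Module detection** — a two-level map-equation (InfoMap-style)
  decomposition of the directed weighted network. A PageRank-style random
  walk (teleport rate τ = 0.15) gives node visit rates `p_i` and link flows
  `f(s,t) = (1−τ)·p_s·W[s,t]/s_out(s)`; the description length
  `L(M) = q·H(Q) + Σ_m p_m^⊙·H(P_m)` is minimised by greedy node moves and
  module agglomeration over shuffled restarts. Weighted Louvain modularity
  (Q) is provided for comparison.
- **Hub cartography** — per-direction participation coefficients
  `P_i = 1 − Σ_m (s_im/s_i)²` and within-module z-scores, mapped to the
  Guimerà–Amaral roles R1–R7 (hubs require z > 2.5; marginal hubs
  2 < z ≤ 2.5).
- **High-traffic links** — ranking of links by probability flow (e.g. the
  top 15%).
- **Temporal tracing** — time-evolving link shells around seed areas at a
  conduction velocity of 1 m/s with a 2 ms per-synapse delay, with
  weight/length display filters and CSV/JSON export for external 3-D
  viewers.
- **Synthetic connectomes** — a spatially embedded generator (116 areas in
  a 25×15×10 mm box, exponential weight–distance decay with λ = 4.57 mm,
  log-normal weight noise, planted modules, censoring of in-links to 55
  injection sites) with full ground truth, so every stage is testable
  without external data.

The clustering and classification cores are scikit-learn-style estimators
(`MapEquation`, `LouvainCommunities`, `CartographyClassifier`) and compose
with sklearn tooling; the module-level functions are thin wrappers.

## Worked example

```python
import numpy as np
from collections import Counter
from cortexflow import (SynthConfig, generate, weight_distance_fit,
                        optimize_partition, modularity, compare_partitions,
                        Partition, assign_roles, trace, TraceConfig)

cfg = SynthConfig(n_nodes=60, n_measured=60, n_modules=4,
                  p_within=0.6, p_between=0.05, seed=7)
net, truth = generate(cfg)
print(f"{net.n_nodes} areas, {net.n_links} links")

fit = weight_distance_fit(net, "exponential")
print(f"decay length {fit.decay_length_mm:.2f} mm  (R^2 = {fit.r_squared:.2f})")

part = optimize_partition(net, n_trials=10, seed=7)
q = modularity(net, part)
print(f"{part.n_modules} modules, codelength {part.codelength:.3f} bits, Q = {q:.2f}")
print("module flows:", np.round(part.module_flow, 3))

planted = Partition(labels=net.labels,
                    modules=np.array([truth.partition[l] for l in net.labels]))
print("agreement with planted modules:", compare_partitions(part, planted))

r_out = assign_roles(net, part, "out")
print("out-link roles:", dict(Counter(r.role for r in r_out)))

seed_area = part.members(0)[0]
tr = trace(net, TraceConfig(seeds=(seed_area,)))
print(f"trace from {seed_area}: {len(tr.events)} link activations within "
      f"2 synapses; {tr.n_excluded_weight} weak links omitted")
```

prints

```
60 areas, 611 links
decay length 4.55 mm  (R^2 = 0.75)
4 modules, codelength 4.816 bits, Q = 0.70
module flows: [0.265 0.259 0.259 0.217]
agreement with planted modules: {'nmi': 1.0, 'ari': 1.0}
out-link roles: {'R2': 36, 'R1': 22, 'R5': 2}
trace from a001: 49 link activations within 2 synapses; 0 weak links omitted
```

The generator planted four spatially compact modules with a 4.57 mm
weight–distance decay; the fit recovers the decay length to within a few
percent, the map-equation decomposition recovers the planted modules exactly
(NMI = ARI = 1) and ranks them by random-walk flow, the cartography finds
two provincial hubs (R5), and the trace lists each activated link with its
arrival time (path length / velocity plus 2 ms per intermediate synapse).

## Command line

```bash
cortexflow synth --seed 1                    # write a synthetic link list
cortexflow stats synthetic_links.tsv --node-meta synthetic_nodes.tsv
cortexflow modules synthetic_links.tsv --trials 100 --seed 1
cortexflow roles synthetic_links.tsv --top-n 10
cortexflow flow synthetic_links.tsv --fraction 0.15
cortexflow trace synthetic_links.tsv --node-meta synthetic_nodes.tsv --seeds a000
cortexflow run --config run.yaml             # full pipeline + manifest
```

Real tracer data is read the same way: a `source target weight` link list or
a labelled adjacency matrix (rows = sources, columns = targets; a
rectangular 116×55 matrix is unioned into one node set with the 55 column
areas flagged as measured), with optional
`label region x_mm y_mm z_mm measured` metadata and
`target injection_volume LNi LNe LNtot` injection records for the FLNe→LNe
renormalisation.

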