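# trnhier

Hierarchical decomposition of directed transcriptional regulatory
networks by exact mixed-integer programming.

## The problem

Transcription factors (TFs) regulate one another, forming a directed
network G = (N, E) of regulator → target edges. Such networks are widely
believed to be organised in layers: master regulators on top, downstream
effectors at the bottom. `trnhier` makes that idea quantitative. It
assigns every node n_i an integer level t_i with 0 ≤ t_i < M (M = the
allowed number of levels) so as to minimise the number of *conflicting*
pairs — penalisable ordered pairs (i, j) with t_i ≤ t_j, i.e. regulators
that fail to sit strictly above what they regulate:

    minimise   γ = Σ p_ij          over pairs with ϕ(n_i, n_j) = 1
    subject to p_ij ∈ {0, 1},  0 ≤ t_i < M  integer,
               t_j − t_i − M·p_ij ≥ −M,
               t_j − t_i − M·p_ij ≤ −1,

where ϕ marks the penalisable pairs: the **adjacency** scheme penalises
direct edges, the **reachability** scheme every ordered pair joined by a
directed path. The two inequalities force p_ij = 1 exactly when
t_i ≤ t_j, so the program counts conflicts exactly, and a branch-and-bound
solver (HiGHS) returns a provably optimal hierarchy even for cyclic
networks. The toolkit around the optimiser provides:

* a **divide-and-conquer** mode (random partition growth, frozen levels,
  best of many restarts) for networks too large for one MILP;
* **permutation Z-scores** z = (μ − γ)/σ against random level
  assignments with the identical level histogram;
* **robustness/stability experiments** under degree-preserving edge
  shuffling;
* per-level **hypergeometric enrichment** of node annotations (e.g.
  essential genes);
* a **planted-hierarchy generator** for ground-truth benchmarking.

It is aimed at computational/systems biologists analysing regulatory or
other directed networks where an ordering hypothesis is meaningful.

## Worked example

The bundled seven-node demonstration network has 8 edges, a master
regulator `n1`, and a directed cycle `n3 → n6 → n7 → n3`, so no perfect
layering exists:

```python
from trnhier import HierarchyModel, example_network

res = HierarchyModel(example_network(), scheme="adjacency",
                     max_levels=4).fit()
print(res.summary(seed=0))
```

```
Hierarchical decomposition
==================================================
Nodes / edges:      7 / 8
Scheme:             adjacency (8 pairs)
Max levels (M):     4
Method / backend:   exact / highs
Penalty (gamma):    1 conflicting pairs
Proven optimal:     True
Z-score:            2.78  (null mu=4.78, sigma=1.36, n=1000)
Level occupancy:    L1:3, L2:1, L3:2, L4:1
```

A penalty of 1 means the best 4-level hierarchy leaves exactly one edge
pointing sideways or upward — the unavoidable cost of the 3-cycle (any
cycle must break somewhere). `res.levels` gives the 1-based assignment,
e.g. `n1` at level 4 (top). The Z-score says this hierarchy beats random
placements of the same level multiset by ~2.8 null standard deviations
(μ = 4.78 conflicts expected at random versus 1 observed); small networks
cap how extreme z can get, while curated TRNs typically score far higher.

The same run from the shell:

```sh
trnhier solve --edges example.tsv --phi adjacency --max-levels 4 --out levels.tsv
```

Other subcommands: `dnc` (partitioned solving), `zscore`, `shuffle`,
`sweep` (penalty vs. M), `enrich`, `compare`, `subnet` (local vs. global
hierarchy), `simulate` (planted benchmarks). All seeded subcommands are
bit-reproducible.

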