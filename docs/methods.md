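# Methods

## The model

A transcriptional regulatory network is a directed graph G = (N, E) whose
nodes are transcription factors and whose edges point from a regulator to
its target. A hierarchical decomposition assigns each node n_i an integer
level t_i with 0 ≤ t_i < M, where M is a user-chosen cap on the number of
levels. The working hypothesis is that regulation flows downward: a
regulator should sit strictly above everything it regulates. An ordered
pair (i, j) is *conflicting* when the pair is penalisable and t_i ≤ t_j,
and the quality of a decomposition is its penalty γ — the number of
conflicting pairs. Two pair schemes are supported:

* **adjacency** — (i, j) is penalisable iff the edge i→j exists; γ counts
  conflicting direct interactions;
* **reachability** — (i, j) is penalisable iff a directed path i ⇝ j
  exists; γ counts conflicting ancestor/descendant relations.

Levels are 0-based internally; every file and report is 1-based, with
larger numbers higher in the hierarchy. Self-loops are dropped at ingest
and self-pairs are excluded from the reachability closure: a node on a
cycle reaches itself and t_i ≤ t_i always holds, so such pairs would add
the same constant to every assignment and carry no information. Whether
curated penalty figures elsewhere count such pairs is not always stated;
this package's convention is fixed and documented here.

## Exact solving

The minimum-penalty assignment is found as a mixed-integer program. Each
node contributes a bounded integer variable t_i; each penalisable pair a
binary variable p_ij and the two inequalities

    t_j − t_i − M·p_ij ≥ −M
    t_j − t_i − M·p_ij ≤ −1

For integer levels in [0, M) these admit p_ij = 0 exactly when t_i > t_j
and p_ij = 1 exactly when t_i ≤ t_j (an enumeration test verifies this for
all level pairs up to M = 8), so minimising Σ p_ij minimises γ. Pairs that
are not penalisable contribute nothing. The model is always feasible —
putting every node on one level with all p_ij = 1 satisfies every
constraint — so an infeasible status from a backend is treated as a
construction bug, never as a legitimate outcome.

The default backend is HiGHS branch-and-bound (via `scipy.optimize.milp`)
with relative MIP gap 0, i.e. a proven optimum. A time limit, if given,
degrades the result to non-optimal rather than erroring. Backends are
pluggable behind a minimal array-level contract. The reported penalty is
always recomputed from the returned assignment with the pure penalty
function, never read off the backend objective. Ties among optima are left
to the backend; tests assert only the optimal value. The independent
brute-force oracle enumerates all M^m assignments (vectorised, capped at
10^7 by default, lexicographically smallest optimum on sorted node order)
and agrees with the MILP on every instance small enough to enumerate.

Useful identities, all property-tested: γ is non-increasing in M and
constant for M ≥ m; γ = 0 for some M iff the network is acyclic; and at
M ≥ m the adjacency optimum equals the minimum feedback arc set size.

## Divide and conquer

Networks beyond roughly a hundred nodes make the single MILP impractical,
so a randomised partition scheme is used: grow a partition from a random
seed node by repeatedly adding a random unassigned neighbour (either edge
direction) until a size cap (default 100) is reached, solve that partition
as its own MILP, freeze its levels, and repeat until every node is
assigned. When the frontier empties before the cap (disconnected
remainder) a fresh random seed is drawn — the connected case is the one
the growth rule is designed for, and this is the natural extension. The
whole pass is restarted many times (default 1000) from fresh random seeds
and the best restart — judged by the global penalty on the full pair set,
earliest restart winning ties — is kept. For the reachability scheme the
closure is computed once on the full network and only filtered per
partition; reachability is a property of G, not of subgraphs.

A restart can miss a level of the underlying hierarchy entirely: the
probability that k sampled nodes all miss a level holding n of N nodes is
C(N−n, k)/C(N, k), and independent restarts shrink the overall failure
probability geometrically (0.9^1000 ≈ 1.7×10⁻⁴⁶; the computation is done
in log space to avoid underflow).

By default each partition's MILP sees only the pairs internal to the
partition. An optional `boundary_terms` mode also scores pairs that link
the partition to already-frozen nodes, whose levels enter the model as
constants. **Known limitation:** because each partition's subproblem has
many optimal solutions and the backend's pick is arbitrary, the frozen
levels of different partitions need not align, and cross-partition edges
can stay in conflict no matter how many restarts are run. On planted
150-node instances with exact optimum 10 the heuristic typically plateaus
around 3× the optimum even with hundreds of restarts; the boundary-terms
mode helps only marginally. The heuristic is therefore an upper bound on
the optimum — exact when a partition covers the whole network — not an
approximation scheme with a guarantee.

## Significance: permutation Z-scores

Raw penalties are incomparable across networks of different size and
density, so a decomposition T with penalty γ is scored against a null that
redistributes the *same* levels: each null draw permutes the observed
multiset of levels uniformly across nodes, preserving the per-level node
counts exactly, and is scored on the same pair set. With null mean μ and
sample (ddof = 1) standard deviation σ,

    z = (μ − γ) / σ

Higher is better; z ≥ 4 is conventionally taken as very significant. The
defaults — 1000 null draws, sample rather than population σ — are package
choices; at that sample size the two σ flavours differ by under 0.1%. A
zero-variance null (e.g. an empty pair set) raises a degenerate-null error
rather than returning an arbitrary number.

## Robustness and stability under network mutation

Curated networks are imprecise, so decompositions are stress-tested with
the degree-preserving edge shuffle: pick two distinct edges (u, v) and
(s, t), and replace them with (u, t) and (s, v) provided u ≠ t, s ≠ v and
neither replacement edge already exists — the extra inequalities keep the
no-self-loop invariant that a bare double swap would violate. η accepted
swaps on a network with |E| edges define a mutation percentage of
η/|E|×100 (rounded); every node keeps its exact (in, out) degree pair and
|E| is unchanged. A configurable attempt budget per swap turns pathological
inputs (e.g. a two-edge fan out of one regulator, which admits no valid
swap) into an explicit shuffle-stuck error.

Two experiment designs, each averaging over a configurable number of
mutants per percentage (default 10):

* **robustness** — solve T once on the original network, then re-score
  that same T (penalty and Z) on each mutant's pair set: how much does the
  answer degrade if the input network was wrong?
* **stability** — re-solve each mutant from scratch for its own T′: does
  the method keep finding significant hierarchies on perturbed topologies?

On planted networks the original decomposition's mean Z stays clearly
positive through 20% mutation, mirroring the behaviour expected of a real
hierarchy-bearing network; stability penalties are asserted only within
their trivial bounds, as no monotone trend in mutation percentage exists.

## Per-level enrichment

For annotation terms (opaque labels; no ontology traversal) the package
asks whether a term concentrates at a level. With N nodes total, K
carrying the term, n at the level and k carrying the term at the level,
the p-value is the upper tail P[X ≥ k] of Hypergeometric(N, K, n) —
over-representation, matching how essential-gene concentration is usually
read. p-values are raw by default; a multiple-testing flag (Bonferroni,
Benjamini–Hochberg via statsmodels) exists but is off, since single-table
inspection is the intended use. The k/n ratio column serves binary
annotations such as essentiality directly.

## Comparing decompositions

Assignments with different M are compared on a common [0, 1] scale,
t/(M−1) (a single-level assignment maps to 0.5 — the only choice that
treats "no information" symmetrically). The per-node absolute shift sorts
unstable nodes first; nodes that move far between, say, a 5- and a 6-level
decomposition are the ones whose predicted position should not be trusted.

## Local versus global hierarchies

For a functional subnetwork G′ of G, the levels induced on G′ by the full
network's optimum are compared against a fresh local solve of G′ alone,
both scored on G′'s own pair set; the local penalty can never exceed the
induced one, since the induced assignment is feasible for the local
problem. Boundary incoming/outgoing edge counts (edges crossing into and
out of G′) are reported per subnetwork and per node, as the degree of
outside influence explains how far the two hierarchies drift apart.

## Synthetic benchmarks

Real regulatory networks carry no ground truth, so quantitative claims are
validated on generated instances. `planted_hierarchy(n, L, e, V)` spreads
n nodes near-uniformly over L levels (remainder to the top levels), lays a
backbone chain spanning all levels, adds random strictly-downward edges to
a density of e edges per node, and plants exactly V violating edges. In
the default mode violations are random non-descending pairs, so the
planted assignment witnesses γ = V and the optimum is ≤ V. In **tight**
mode each violation is the reverse of an existing downward edge: the V
resulting 2-cycles are edge-disjoint, any assignment must conflict on at
least one edge of each, and the optimum is therefore exactly V — which
turns the ≤ into a testable equality. The generator is reproducible from
its seed and refuses infeasible edge budgets.

What the generator does *not* emulate: scale-free degree distributions,
dense regulator hubs, autoregulation, or the correlated noise of curated
interaction databases. Passing tests show that the optimiser recovers
planted structure and that the statistics behave as designed; they do not
certify biological conclusions on any particular organism's network.

## Problem sizes and numerical choices

The test suite works at sizes where exact cross-checking is possible:
oracle equivalence on 200 random digraphs of ≤ 6 nodes across M ∈ {2,3,4};
feedback-arc-set identity on 100 digraphs of ≤ 5 nodes; parameter recovery
on 60-node, 5-level tight instances with V ∈ {0, 2, 4, 8} over 20 seeds
each; null-model and robustness checks on 200-node planted networks.
Penalty evaluation is vectorised (pairs as index arrays); MILP level
variables are read back with rounding and clipped into [0, M−1] before
the penalty is recomputed exactly in integer arithmetic, so float noise in
the backend solution cannot corrupt a reported γ. All randomness flows
through `numpy.random.Generator` seeds; CLI runs and experiment tables are
bit-reproducible given the same seed.
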