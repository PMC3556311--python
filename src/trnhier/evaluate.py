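"""Statistical and biological evaluation of hierarchical decompositions.

Covers the permutation Z-score of a decomposition against a level-histogram
preserving null, degree-preserving edge shuffling (the null model for
robustness and stability experiments), per-level hypergeometric enrichment
of node annotations, cross-decomposition comparison, and local-versus-global
hierarchy analysis of subnetworks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .network import (LevelAssignment, Network, PairSet, build_pair_set,
                      induce_subnetwork, penalty, penalty_vector)
from .solver import SolveResult, solve

__all__ = [
    "ZScoreResult",
    "MutationSpec",
    "DegenerateNullError",
    "ShuffleStuckError",
    "zscore",
    "degree_preserving_shuffle",
    "robustness_experiment",
    "stability_experiment",
    "level_enrichment",
    "compare_assignments",
    "local_vs_global",
    "LocalVsGlobal",
]


class DegenerateNullError(ValueError):
    """The permutation null has zero variance; the Z-score is undefined."""


class ShuffleStuckError(RuntimeError):
    """No admissible edge swap found within the attempt budget."""

    def __init__(self, completed: int, requested: int, attempts: int):
        self.completed = completed
        self.requested = requested
        super().__init__(
            f"no admissible swap after {attempts} draws; completed "
            f"{completed} of {requested} requested swaps")


@dataclass
class ZScoreResult:
    """Observed penalty against a level-permutation null.

    z = (mu - gamma) / sigma: the number of standard deviations by which
    the observed decomposition beats random assignments drawn with the
    identical per-level node counts.  Higher is better; >= 4 is typically
    considered very significant.
    """

    gamma: int
    mu: float
    sigma: float
    z: float
    n_samples: int


@dataclass(frozen=True)
class MutationSpec:
    """How many degree-preserving swaps to apply to a network.

    ``eta`` is the accepted-swap count; the mutation percentage of a network
    with |E| edges is eta / |E| * 100, rounded to the nearest integer.
    """

    percent: int
    eta: int

    @classmethod
    def from_percent(cls, percent: float, n_edges: int) -> "MutationSpec":
        if percent < 0:
            raise ValueError(f"percent must be >= 0, got {percent}")
        eta = int(round(percent / 100.0 * n_edges))
        return cls(int(round(eta / n_edges * 100)) if n_edges else 0, eta)


def sample_null_levels(assign: LevelAssignment, n_samples: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Null level draws: each row permutes the observed levels uniformly
    at random across nodes (in ``assign.nodes`` order), so the per-level
    node counts of every draw equal the observed ones exactly."""
    base = np.array([assign.levels[n] for n in assign.nodes], dtype=np.int64)
    perms = np.empty((n_samples, base.size), dtype=np.int64)
    for s in range(n_samples):
        perms[s] = base[rng.permutation(base.size)]
    return perms


def zscore(assign: LevelAssignment, ps: PairSet, n_samples: int = 1000,
           rng: np.random.Generator | int | None = None) -> ZScoreResult:
    """Permutation Z-score of ``assign`` on ``ps``.

    Each null draw permutes the observed levels across nodes uniformly at
    random, so every draw has exactly the observed per-level node counts.
    mu and sigma are the sample mean and sample (ddof=1) standard deviation
    of the null penalties.

    Raises :class:`DegenerateNullError` when sigma is zero (e.g. an empty
    pair set, where every penalty is 0).
    """
    if n_samples < 2:
        raise ValueError(f"n_samples must be >= 2, got {n_samples}")
    rng = np.random.default_rng(rng)
    nodes = assign.nodes
    order = {n: k for k, n in enumerate(nodes)}
    src, dst = ps.index_arrays(order)
    gamma = penalty(assign, ps)

    perms = sample_null_levels(assign, n_samples, rng)
    null = penalty_vector(perms, src, dst)
    mu = float(null.mean())
    sigma = float(null.std(ddof=1))
    if sigma == 0.0:
        raise DegenerateNullError(
            "null penalty distribution has zero variance; z is undefined")
    return ZScoreResult(gamma, mu, sigma, (mu - gamma) / sigma, n_samples)


def degree_preserving_shuffle(net: Network, spec: MutationSpec,
                              rng: np.random.Generator | int | None = None,
                              max_attempts_per_swap: int = 10_000) -> Network:
    """Mutate a network by ``spec.eta`` accepted double edge swaps.

    A candidate swap removes two randomly drawn distinct edges (u, v) and
    (s, t) and adds (u, t) and (s, v).  It is accepted only if u != t and
    s != v (no self-loop creation) and neither (u, t) nor (s, v) already
    exists.  Accepted swaps leave every node's in- and out-degree and the
    edge count unchanged.

    Raises :class:`ShuffleStuckError` if ``max_attempts_per_swap``
    consecutive draws yield no admissible swap.
    """
    if spec.eta > 0 and net.n_edges < 2:
        raise ValueError("need at least 2 edges to swap")
    rng = np.random.default_rng(rng)
    mutant = net.copy()
    if spec.eta == 0:
        return mutant
    edges = list(mutant.edges)
    edge_set = set(edges)
    for done in range(spec.eta):
        for _ in range(max_attempts_per_swap):
            a, b = rng.choice(len(edges), size=2, replace=False)
            u, v = edges[a]
            s, t = edges[b]
            if u == t or s == v:
                continue
            if (u, t) in edge_set or (s, v) in edge_set:
                continue
            edge_set.discard((u, v))
            edge_set.discard((s, t))
            edge_set.add((u, t))
            edge_set.add((s, v))
            edges[a] = (u, t)
            edges[b] = (s, v)
            break
        else:
            raise ShuffleStuckError(done, spec.eta, max_attempts_per_swap)
    return Network(edges, nodes=net.nodes)


def _mean_z(assign: LevelAssignment, ps: PairSet, n_zsamples: int,
            rng: np.random.Generator) -> float:
    try:
        return zscore(assign, ps, n_samples=n_zsamples, rng=rng).z
    except DegenerateNullError:
        return float("nan")


def robustness_experiment(net: Network, scheme: str, M: int,
                          percents: Sequence[float], n_mutants: int = 10,
                          n_zsamples: int = 1000,
                          rng: np.random.Generator | int | None = None,
                          backend=None) -> pd.DataFrame:
    """How well the original decomposition survives network mutation.

    The decomposition T is solved ONCE on the original network.  For each
    mutation percentage, ``n_mutants`` degree-preserving mutants are drawn
    and T's penalty and Z-score are recomputed on each mutant's pair set;
    the table reports their means per percentage.
    """
    rng = np.random.default_rng(rng)
    ps0 = build_pair_set(net, scheme)
    base = solve(ps0, net.nodes, M, backend=backend)
    rows = []
    for percent in percents:
        spec = MutationSpec.from_percent(percent, net.n_edges)
        gammas, zs = [], []
        for _ in range(n_mutants):
            mutant = degree_preserving_shuffle(net, spec, rng)
            psm = build_pair_set(mutant, scheme)
            gammas.append(penalty(base.assignment, psm))
            zs.append(_mean_z(base.assignment, psm, n_zsamples, rng))
        rows.append({"percent": percent, "mean_penalty": float(np.mean(gammas)),
                     "mean_z": float(np.mean(zs)), "n_mutants": n_mutants})
    return pd.DataFrame(rows)


def stability_experiment(net: Network, scheme: str, M: int,
                         percents: Sequence[float], n_mutants: int = 10,
                         n_zsamples: int = 1000,
                         rng: np.random.Generator | int | None = None,
                         backend=None) -> pd.DataFrame:
    """How well fresh decompositions of mutants perform.

    Unlike :func:`robustness_experiment`, each mutant is RE-SOLVED for its
    own optimal decomposition T'; the table reports mean penalty and mean
    Z-score of those per-mutant optima.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for percent in percents:
        spec = MutationSpec.from_percent(percent, net.n_edges)
        gammas, zs = [], []
        for _ in range(n_mutants):
            mutant = degree_preserving_shuffle(net, spec, rng)
            psm = build_pair_set(mutant, scheme)
            res = solve(psm, mutant.nodes, M, backend=backend)
            gammas.append(res.penalty)
            zs.append(_mean_z(res.assignment, psm, n_zsamples, rng))
        rows.append({"percent": percent, "mean_penalty": float(np.mean(gammas)),
                     "mean_z": float(np.mean(zs)), "n_mutants": n_mutants})
    return pd.DataFrame(rows)


def level_enrichment(assign: LevelAssignment,
                     annotation: Mapping[str, set[str] | frozenset[str]],
                     correction: str | None = None) -> pd.DataFrame:
    """Per-(level, term) hypergeometric over-representation.

    For each term and level: N = total nodes in the assignment, K = nodes
    carrying the term, n = nodes at the level, k = term-carrying nodes at
    the level; the p-value is the upper tail P[X >= k] of
    hypergeometric(N, K, n).  Nodes absent from ``annotation`` are simply
    unannotated.  Levels are reported 1-based.  The ``ratio`` column (k/n)
    supports binary annotations such as gene essentiality.

    p-values are raw by default; ``correction`` may name a method of
    ``statsmodels.stats.multitest.multipletests`` (e.g. "bonferroni",
    "fdr_bh") to add an adjusted column.
    """
    if not assign.levels:
        raise ValueError("empty assignment")
    unknown = set(annotation) - set(assign.levels)
    if unknown:
        raise KeyError(f"annotated node(s) not in assignment: "
                       f"{sorted(unknown)[:5]}")
    N = len(assign)
    terms: dict[str, set[str]] = {}
    for node, node_terms in annotation.items():
        for term in node_terms:
            terms.setdefault(term, set()).add(node)
    by_level: dict[int, set[str]] = {}
    for node, t in assign.levels.items():
        by_level.setdefault(t, set()).add(node)

    rows = []
    for term in sorted(terms):
        carriers = terms[term]
        K = len(carriers)
        for t in sorted(by_level):
            members = by_level[t]
            n = len(members)
            k = len(members & carriers)
            p = float(hypergeom.sf(k - 1, N, K, n))
            rows.append({"level": t + 1, "term": term, "k": k, "n": n,
                         "K": K, "N": N, "ratio": k / n, "p_value": p})
    table = pd.DataFrame(rows)
    if correction is not None and len(table):
        from statsmodels.stats.multitest import multipletests
        table["p_adjusted"] = multipletests(table["p_value"],
                                            method=correction)[1]
    return table


def compare_assignments(a: LevelAssignment, b: LevelAssignment) -> pd.DataFrame:
    """Per-node normalised level shift between two decompositions.

    Each assignment's levels are rescaled to [0, 1] via t / (M - 1)
    (a single-level decomposition maps everything to 0.5), so hierarchies
    with different level counts are comparable.  The table is sorted by
    descending |shift|: nodes whose position is least reliable across
    decompositions surface first.
    """
    if set(a.levels) != set(b.levels):
        raise KeyError("assignments cover different node sets")

    def scale(t: int, M: int) -> float:
        return 0.5 if M == 1 else t / (M - 1)

    rows = [{"node": n,
             "scaled_a": scale(a.levels[n], a.M),
             "scaled_b": scale(b.levels[n], b.M)}
            for n in a.levels]
    table = pd.DataFrame(rows)
    table["shift"] = (table["scaled_a"] - table["scaled_b"]).abs()
    return (table.sort_values(["shift", "node"], ascending=[False, True])
            .reset_index(drop=True))


@dataclass
class LocalVsGlobal:
    """Induced-global versus locally re-solved hierarchy of a subnetwork."""

    global_penalty: int
    global_z: float
    local_penalty: int
    local_z: float
    incoming: int
    outgoing: int
    incoming_per_node: float
    outgoing_per_node: float
    subnetwork: Network = field(repr=False)
    induced: LevelAssignment = field(repr=False)
    local: LevelAssignment = field(repr=False)


def local_vs_global(net: Network, sub_nodes, scheme: str, M: int,
                    backend=None, n_zsamples: int = 1000,
                    rng: np.random.Generator | int | None = None
                    ) -> LocalVsGlobal:
    """Compare a subnetwork's own hierarchy with the one the full network
    induces on it.

    The full network is solved for T; restricting T to the subnetwork gives
    the induced global hierarchy; re-solving the subnetwork in isolation
    gives the local one.  Both are scored (penalty, Z) on the subnetwork's
    own pair set, alongside the boundary incoming/outgoing edge counts.
    The local penalty can never exceed the induced one.
    """
    rng = np.random.default_rng(rng)
    sub, incoming, outgoing = induce_subnetwork(net, sub_nodes)
    full_ps = build_pair_set(net, scheme)
    global_res = solve(full_ps, net.nodes, M, backend=backend)
    induced = LevelAssignment(
        {n: global_res.assignment.levels[n] for n in sub.nodes}, M)
    sub_ps = build_pair_set(sub, scheme)
    local_res = solve(sub_ps, sub.nodes, M, backend=backend)
    n_sub = max(sub.n_nodes, 1)
    return LocalVsGlobal(
        global_penalty=penalty(induced, sub_ps),
        global_z=_mean_z(induced, sub_ps, n_zsamples, rng),
        local_penalty=local_res.penalty,
        local_z=_mean_z(local_res.assignment, sub_ps, n_zsamples, rng),
        incoming=incoming, outgoing=outgoing,
        incoming_per_node=incoming / n_sub,
        outgoing_per_node=outgoing / n_sub,
        subnetwork=sub, induced=induced, local=local_res.assignment)
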