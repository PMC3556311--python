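"""Divide-and-conquer decomposition for networks too large for one MILP.

Exact solving scales comfortably to roughly a hundred nodes; beyond that
the integer program grows too large.  The strategy here randomly grows
fixed-size partitions one node at a time, solves each partition as an
independent MILP (its levels are then frozen), repeats until every node is
assigned, scores the resulting global assignment on the FULL pair set, and
keeps the best of many random restarts.

A restart can miss the true layering if its partitions never intersect some
level; the chance that k randomly chosen nodes all miss a level holding n
of N nodes is C(N-n, k)/C(N, k), and independent restarts drive the overall
failure probability down geometrically (0.9**1000 is of order 1e-46).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import LevelAssignment, Network, build_pair_set, penalty
from .solver import SolveResult, get_backend, solve

__all__ = [
    "DncConfig",
    "grow_partition",
    "dnc_solve",
    "partition_miss_probability",
    "restart_failure_probability",
]


@dataclass
class DncConfig:
    """Divide-and-conquer run configuration.

    Defaults: 100-node partitions and 1000 restarts.  ``boundary_terms``
    additionally scores pairs linking a partition to already-frozen nodes
    inside each partition MILP (their levels enter as constants); off by
    default, where each partition is the stand-alone subproblem defined by
    its internal pairs.
    """

    scheme: str
    M: int
    partition_size: int = 100
    restarts: int = 1000
    rng_seed: int = 0
    boundary_terms: bool = False

    def __post_init__(self) -> None:
        if self.partition_size < 1:
            raise ValueError("partition_size must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.M < 1:
            raise ValueError("M must be >= 1")


def grow_partition(net: Network, unassigned: set[str], size_limit: int,
                   rng: np.random.Generator) -> set[str]:
    """Randomly grow one partition inside ``unassigned``.

    Starts from a uniformly random seed node, then repeatedly adds a
    uniformly random unassigned node adjacent (either edge direction) to
    the partition, until ``size_limit`` is reached or ``unassigned`` is
    exhausted.  If the frontier empties first (disconnected remainder), a
    fresh random seed is drawn and growth continues.
    """
    if not unassigned:
        raise ValueError("unassigned node set is empty")
    if size_limit < 1:
        raise ValueError("size_limit must be >= 1")
    pool = sorted(unassigned)
    g = net.to_digraph()
    part: set[str] = set()
    frontier: set[str] = set()

    def add(node: str) -> None:
        part.add(node)
        frontier.discard(node)
        for nb in set(g.successors(node)) | set(g.predecessors(node)):
            if nb in unassigned and nb not in part:
                frontier.add(nb)

    add(pool[int(rng.integers(len(pool)))])
    while len(part) < min(size_limit, len(unassigned)):
        if frontier:
            cands = sorted(frontier)
        else:
            cands = sorted(set(pool) - part)  # fresh seed for a new component
        add(cands[int(rng.integers(len(cands)))])
    return part


def dnc_solve(net: Network, cfg: DncConfig, backend=None) -> SolveResult:
    """Best-of-restarts partitioned decomposition.

    Per restart, partitions are grown and solved until all nodes carry a
    frozen level; the restart's global penalty is evaluated on the full
    pair set (reachability pairs always come from the full network, never
    from subgraphs).  The best restart wins; ties keep the earliest.  Fully
    reproducible from ``cfg.rng_seed``.
    """
    backend = get_backend(backend)
    rng = np.random.default_rng(cfg.rng_seed)
    full_ps = build_pair_set(net, cfg.scheme)
    all_nodes = list(net.nodes)

    best: SolveResult | None = None
    best_restart = -1
    trace = []
    for restart in range(cfg.restarts):
        unassigned = set(all_nodes)
        frozen: dict[str, int] = {}
        all_optimal = True
        while unassigned:
            part = sorted(grow_partition(net, unassigned,
                                         cfg.partition_size, rng))
            internal = full_ps.restrict(part)
            part_set = set(part)
            if cfg.boundary_terms and frozen:
                touching = frozenset(
                    p for p in full_ps.pairs
                    if (p[0] in part_set and p[1] in frozen)
                    or (p[1] in part_set and p[0] in frozen))
                ps_part = type(internal)(internal.scheme,
                                         internal.pairs | touching,
                                         internal.nodes)
                res = solve(ps_part, part, cfg.M, backend=backend,
                            fixed_levels=frozen)
                levels = {n: res.assignment.levels[n] for n in part}
            else:
                res = solve(internal, part, cfg.M, backend=backend)
                levels = res.assignment.levels
            all_optimal = all_optimal and res.optimal
            frozen.update(levels)
            unassigned -= part_set
        assign = LevelAssignment(dict(frozen), cfg.M)
        gamma = penalty(assign, full_ps)
        trace.append(gamma)
        if best is None or gamma < best.penalty:
            # provably optimal only when the whole network fit in one
            # partition and the backend certified that single solve
            proven = cfg.partition_size >= net.n_nodes and all_optimal
            best = SolveResult(assign, gamma, proven,
                               getattr(backend, "name",
                                       type(backend).__name__), {})
            best_restart = restart
    assert best is not None
    best.wall_info = {"best_restart": best_restart,
                      "restarts": cfg.restarts,
                      "partition_size": cfg.partition_size,
                      "restart_trace": trace}
    return best


def restart_trace_frame(result: SolveResult) -> pd.DataFrame:
    """The per-restart global penalties of a :func:`dnc_solve` result."""
    trace = result.wall_info.get("restart_trace", [])
    return pd.DataFrame({"restart": range(len(trace)),
                         "global_penalty": trace})


def partition_miss_probability(N: int, n: int, k: int) -> float:
    """P[a uniform k-subset of N nodes misses all n nodes of one level].

    Equals C(N-n, k) / C(N, k), with C(a, b) = 0 for b > a.
    """
    if N < 0 or n < 0 or k < 0:
        raise ValueError("arguments must be non-negative")
    if n > N or k > N:
        raise ValueError("need n <= N and k <= N")
    if k > N - n:
        return 0.0
    return math.comb(N - n, k) / math.comb(N, k)


def restart_failure_probability(p_single: float, restarts: int) -> float:
    """P[every one of ``restarts`` independent restarts fails].

    Computed in log space: 0.9**1000 is of order 1e-46 and must not
    underflow through naive repeated multiplication of rounded partials.
    """
    if not 0.0 <= p_single <= 1.0:
        raise ValueError("p_single must be a probability")
    if restarts < 0:
        raise ValueError("restarts must be >= 0")
    if restarts == 0:
        return 1.0
    if p_single == 0.0:
        return 0.0
    return math.exp(restarts * math.log(p_single))
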