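"""Synthetic networks with a known (planted) hierarchy.

Real regulatory networks come with no ground-truth layering, so every
quantitative claim about the solver is validated here on networks whose
hierarchy is planted by construction: nodes are spread over L levels,
"downward" edges run from strictly higher to strictly lower levels, and a
chosen number of violating edges run level-upward (or sideways).  The
planted assignment then incurs exactly ``n_violations`` adjacency
conflicts, which upper-bounds the solver's optimum; in *tight* mode the
bound is provably exact (see :func:`planted_hierarchy`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import LevelAssignment, Network

__all__ = [
    "PlantedInstance",
    "CapacityError",
    "example_network",
    "planted_hierarchy",
    "random_digraph",
]


class CapacityError(ValueError):
    """The requested edge budget exceeds the available node pairs."""


@dataclass
class PlantedInstance:
    """A generated network with its ground-truth level assignment.

    ``penalty(truth, adjacency pairs) == n_violations`` by construction;
    every non-violating edge descends strictly in the truth.
    """

    network: Network
    truth: LevelAssignment
    n_violations: int


#: the seven-node, eight-edge demonstration network: a master regulator n1,
#: a chain through n2/n4, and the directed cycle n3 -> n6 -> n7 -> n3
_EXAMPLE_EDGES = [
    ("n1", "n2"), ("n1", "n3"), ("n1", "n5"), ("n2", "n4"),
    ("n3", "n5"), ("n3", "n6"), ("n6", "n7"), ("n7", "n3"),
]


def example_network() -> Network:
    """The seven-node worked example (8 edges, one directed 3-cycle)."""
    return Network(_EXAMPLE_EDGES)


def planted_hierarchy(n_nodes: int, L: int, edges_per_node: float,
                      n_violations: int,
                      rng: np.random.Generator | int | None = None,
                      tight: bool = False) -> PlantedInstance:
    """Generate a network with a planted L-level hierarchy.

    Nodes are spread near-uniformly over L levels (remainder nodes go to
    the top levels).  A backbone chain with one node per level guarantees
    downward edges span all levels, then random downward edges are added
    until ``round(edges_per_node * n_nodes)`` is reached.  Violations:

    * default — ``n_violations`` extra edges drawn uniformly among
      non-descending node pairs (source level <= target level), so the
      solver optimum is <= n_violations;
    * ``tight`` — each violation reverses an existing downward edge,
      creating edge-disjoint 2-cycles.  Any assignment must conflict on at
      least one edge of each 2-cycle, so the optimum EQUALS n_violations
      at M >= L.

    Reproducible from ``rng``; raises :class:`CapacityError` when the edge
    budget does not fit the cross-level pair capacity.
    """
    if L < 2:
        raise ValueError(f"L must be >= 2, got {L}")
    if n_nodes < L:
        raise ValueError(f"need n_nodes >= L, got {n_nodes} < {L}")
    if n_violations < 0:
        raise ValueError("n_violations must be >= 0")
    rng = np.random.default_rng(rng)

    nodes = [f"g{i}" for i in range(n_nodes)]
    base, rem = divmod(n_nodes, L)
    # remainder nodes to the top levels; assign bottom level 0 first
    counts = [base + (1 if lvl >= L - rem else 0) for lvl in range(L)]
    levels: dict[str, int] = {}
    i = 0
    for lvl, c in enumerate(counts):
        for _ in range(c):
            levels[nodes[i]] = lvl
            i += 1
    by_level = [[n for n in nodes if levels[n] == lvl] for lvl in range(L)]

    n_edges = int(round(edges_per_node * n_nodes))
    down_capacity = sum(counts[a] * counts[b]
                        for a in range(L) for b in range(a))
    if n_edges > down_capacity:
        raise CapacityError(
            f"{n_edges} downward edges requested but only {down_capacity} "
            f"cross-level pairs exist")

    edge_set: set[tuple[str, str]] = set()
    # backbone: one random node per level, chained top -> bottom
    chain = [by_level[lvl][int(rng.integers(len(by_level[lvl])))]
             for lvl in range(L - 1, -1, -1)]
    for u, v in zip(chain, chain[1:]):
        edge_set.add((u, v))
    while len(edge_set) < n_edges:
        a = int(rng.integers(1, L))
        b = int(rng.integers(a))
        u = by_level[a][int(rng.integers(len(by_level[a])))]
        v = by_level[b][int(rng.integers(len(by_level[b])))]
        edge_set.add((u, v))

    down_edges = sorted(edge_set)
    if tight:
        if n_violations > len(down_edges):
            raise CapacityError(
                f"tight mode needs n_violations <= {len(down_edges)} "
                f"downward edges, got {n_violations}")
        picks = rng.choice(len(down_edges), size=n_violations, replace=False)
        for k in sorted(int(p) for p in picks):
            u, v = down_edges[k]
            edge_set.add((v, u))
    else:
        up_capacity = sum(counts[a] * counts[b]
                          for a in range(L) for b in range(a, L)) - n_nodes
        if n_violations > up_capacity:
            raise CapacityError(
                f"{n_violations} violations requested but only "
                f"{up_capacity} non-descending pairs exist")
        added = 0
        while added < n_violations:
            a = int(rng.integers(L))
            b = int(rng.integers(a, L))
            u = by_level[a][int(rng.integers(len(by_level[a])))]
            v = by_level[b][int(rng.integers(len(by_level[b])))]
            if u == v or (u, v) in edge_set:
                continue
            edge_set.add((u, v))
            added += 1

    net = Network(sorted(edge_set), nodes=nodes)
    truth = LevelAssignment(levels, L)
    return PlantedInstance(net, truth, n_violations)


def random_digraph(n_nodes: int, edge_prob: float,
                   rng: np.random.Generator | int | None = None) -> Network:
    """Erdős–Rényi style digraph: every ordered non-self pair independently
    with probability ``edge_prob``."""
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must be in [0, 1]")
    rng = np.random.default_rng(rng)
    nodes = [f"v{i}" for i in range(n_nodes)]
    draws = rng.random((n_nodes, n_nodes))
    edges = [(nodes[i], nodes[j])
             for i in range(n_nodes) for j in range(n_nodes)
             if i != j and draws[i, j] < edge_prob]
    return Network(edges, nodes=nodes)
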