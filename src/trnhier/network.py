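"""Directed regulatory networks, level assignments and conflict penalties.

A transcriptional regulatory network (TRN) is a directed graph whose nodes
are transcription factors and whose edges point from a regulator to its
target.  A hierarchical decomposition assigns an integer level ``t`` to each
node; a regulator should sit strictly above everything it regulates.  The
penalty of an assignment counts the ordered pairs for which this fails.

Two pair schemes are supported:

* ``adjacency`` — a pair (i, j) counts iff the edge i->j exists;
* ``reachability`` — a pair (i, j) counts iff a directed path i ~> j exists.

Levels are 0-based internally (``0 <= t < M``); all file and report output
is 1-based, with larger values higher in the hierarchy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

SCHEMES = ("adjacency", "reachability")

__all__ = [
    "Network",
    "PairSet",
    "LevelAssignment",
    "EdgeListParseError",
    "read_edge_list",
    "write_edge_list",
    "build_pair_set",
    "penalty",
    "induce_subnetwork",
    "read_levels",
    "write_levels",
    "SCHEMES",
]


class EdgeListParseError(ValueError):
    """A malformed line in an edge-list file."""


class Network:
    """A directed network of regulator -> target interactions.

    Node identifiers are opaque, case-sensitive strings.  Self-loops are
    never stored (they are dropped at ingest) and the edge set holds no
    duplicates.  Node and edge iteration order is insertion order, which
    makes every downstream seeded computation reproducible.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = (),
                 nodes: Iterable[str] = ()) -> None:
        self._g = nx.DiGraph()
        self.n_self_loops_dropped = 0
        for n in nodes:
            self._g.add_node(str(n))
        for u, v in edges:
            self.add_edge(str(u), str(v))

    # -- construction -----------------------------------------------------
    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            self.n_self_loops_dropped += 1
            self._g.add_node(u)
            return
        self._g.add_edge(u, v)

    # -- views ------------------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self._g.nodes)

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(self._g.edges)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def has_node(self, n: str) -> bool:
        return self._g.has_node(n)

    def in_degree(self, n: str) -> int:
        return self._g.in_degree(n)

    def out_degree(self, n: str) -> int:
        return self._g.out_degree(n)

    def degree_pairs(self) -> dict[str, tuple[int, int]]:
        """Per-node (in-degree, out-degree)."""
        return {n: (self._g.in_degree(n), self._g.out_degree(n))
                for n in self._g.nodes}

    def to_digraph(self) -> nx.DiGraph:
        """A copy as a plain :class:`networkx.DiGraph`."""
        return self._g.copy()

    def copy(self) -> "Network":
        return Network(self.edges, self.nodes)

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self._g)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return (set(self.nodes) == set(other.nodes)
                and set(self.edges) == set(other.edges))

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class PairSet:
    """The ordered node pairs that can incur a conflict penalty.

    ``pairs`` holds every ordered pair (i, j), i != j, for which the chosen
    scheme's indicator is 1.  Under ``adjacency`` this is exactly the edge
    set; under ``reachability`` it is the transitive closure (self-pairs
    excluded: a node on a cycle reaches itself, but t_i <= t_i always holds,
    so such pairs would only add a constant offset to every assignment).
    """

    scheme: str
    pairs: frozenset[tuple[str, str]]
    nodes: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.pairs)

    def restrict(self, keep: Iterable[str]) -> "PairSet":
        """Pairs with both endpoints inside ``keep`` (scheme unchanged).

        The indicator stays the one computed on the *full* network; this
        only filters pairs, it never recomputes reachability on a subgraph.
        """
        ks = set(keep)
        return PairSet(self.scheme,
                       frozenset(p for p in self.pairs
                                 if p[0] in ks and p[1] in ks),
                       tuple(n for n in self.nodes if n in ks))

    def index_arrays(self, order: Mapping[str, int]) -> tuple[np.ndarray, np.ndarray]:
        """Source/target index arrays for vectorised penalty evaluation."""
        if not self.pairs:
            e = np.empty(0, dtype=np.intp)
            return e, e.copy()
        src, dst = zip(*sorted(self.pairs))
        return (np.fromiter((order[u] for u in src), dtype=np.intp),
                np.fromiter((order[v] for v in dst), dtype=np.intp))


@dataclass
class LevelAssignment:
    """Map node -> hierarchy level, 0-based, with level cap ``M``.

    Larger level means higher in the hierarchy (master regulators on top).
    Reports and files use 1-based levels.
    """

    levels: dict[str, int]
    M: int

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError(f"M must be >= 1, got {self.M}")
        for n, t in self.levels.items():
            if not 0 <= t < self.M:
                raise ValueError(
                    f"level {t} of node {n!r} outside [0, {self.M})")

    def __getitem__(self, node: str) -> int:
        return self.levels[node]

    def __len__(self) -> int:
        return len(self.levels)

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.levels)

    def as_one_based(self) -> dict[str, int]:
        return {n: t + 1 for n, t in self.levels.items()}

    @classmethod
    def from_one_based(cls, levels: Mapping[str, int], M: int) -> "LevelAssignment":
        return cls({n: t - 1 for n, t in levels.items()}, M)

    def level_histogram(self) -> dict[int, int]:
        """Number of nodes per (0-based) level."""
        h: dict[int, int] = {}
        for t in self.levels.values():
            h[t] = h.get(t, 0) + 1
        return h


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _open_lines(source: str | Path | IO[str]):
    if hasattr(source, "read"):
        return source, False
    return open(source, "r", encoding="utf-8"), True


def read_edge_list(source: str | Path | IO[str]) -> Network:
    """Read a two-column (regulator, target) edge list.

    Columns are tab- or whitespace-separated; ``#`` starts a comment line;
    blank lines are skipped.  Duplicate edges collapse; self-loops are
    dropped with a logged warning (the count is kept on the returned
    network).  An empty input yields an empty network.

    Raises
    ------
    EdgeListParseError
        If a non-comment line has fewer than two fields (the message names
        the offending line number).
    """
    fh, should_close = _open_lines(source)
    net = Network()
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise EdgeListParseError(
                    f"line {lineno}: expected >= 2 fields "
                    f"(regulator, target), got {len(fields)}: {line!r}")
            net.add_edge(fields[0], fields[1])
    finally:
        if should_close:
            fh.close()
    if net.n_self_loops_dropped:
        logger.warning("dropped %d self-loop(s) at ingest",
                       net.n_self_loops_dropped)
    return net


def write_edge_list(net: Network, dest: str | Path | IO[str]) -> None:
    """Write a network as a two-column tab-separated edge list."""
    lines = [f"{u}\t{v}\n" for u, v in net.edges]
    # isolated nodes survive a round-trip via a comment directive
    isolated = [n for n in net.nodes
                if net.in_degree(n) == 0 and net.out_degree(n) == 0]
    header = [f"#node\t{n}\n" for n in isolated]
    if hasattr(dest, "write"):
        dest.writelines(header + lines)
    else:
        with open(dest, "w", encoding="utf-8") as fh:
            fh.writelines(header + lines)


def read_edge_list_with_isolates(source: str | Path | IO[str]) -> Network:
    """Read an edge list honouring ``#node <id>`` isolated-node directives."""
    fh, should_close = _open_lines(source)
    try:
        text = fh.read()
    finally:
        if should_close:
            fh.close()
    import io
    net = read_edge_list(io.StringIO(text))
    for line in text.splitlines():
        if line.startswith("#node\t") or line.startswith("#node "):
            net._g.add_node(line.split(None, 1)[1].strip())
    return net


def write_levels(assign: LevelAssignment, dest: str | Path | IO[str]) -> None:
    """Write (node, 1-based level), tab-separated, sorted by descending
    level then node id."""
    rows = sorted(assign.as_one_based().items(), key=lambda kv: (-kv[1], kv[0]))
    lines = [f"{n}\t{t}\n" for n, t in rows]
    if hasattr(dest, "write"):
        dest.writelines(lines)
    else:
        with open(dest, "w", encoding="utf-8") as fh:
            fh.writelines(lines)


def read_levels(source: str | Path | IO[str], M: int | None = None) -> LevelAssignment:
    """Read a (node, 1-based level) file back into a :class:`LevelAssignment`.

    ``M`` defaults to the maximum level seen.
    """
    fh, should_close = _open_lines(source)
    levels: dict[str, int] = {}
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise EdgeListParseError(
                    f"line {lineno}: expected (node, level), got {line!r}")
            levels[fields[0]] = int(fields[1])
    finally:
        if should_close:
            fh.close()
    if M is None:
        M = max(levels.values(), default=1)
    return LevelAssignment.from_one_based(levels, M)


# ---------------------------------------------------------------------------
# Pair sets and penalties
# ---------------------------------------------------------------------------

def build_pair_set(net: Network, scheme: str) -> PairSet:
    """All ordered pairs with indicator 1 under ``scheme``.

    ``adjacency``: the edge set.  ``reachability``: every ordered pair
    (i, j), i != j, with a directed path from i to j, computed by graph
    search from each node (transitive closure).
    """
    if scheme == "adjacency":
        pairs = frozenset(net.edges)
    elif scheme == "reachability":
        g = net._g
        pairs = frozenset((u, v) for u in g.nodes
                          for v in nx.descendants(g, u) if v != u)
    else:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    return PairSet(scheme, pairs, net.nodes)


def penalty(assign: LevelAssignment | Mapping[str, int], ps: PairSet) -> int:
    """Number of conflicting pairs: |{(i, j) in ps : t_i <= t_j}|.

    Pure function; raises ``KeyError`` naming the first node of ``ps`` that
    the assignment does not cover.
    """
    levels = assign.levels if isinstance(assign, LevelAssignment) else assign
    gamma = 0
    for u, v in ps.pairs:
        if u not in levels:
            raise KeyError(f"node {u!r} in pair set but not in assignment")
        if v not in levels:
            raise KeyError(f"node {v!r} in pair set but not in assignment")
        if levels[u] <= levels[v]:
            gamma += 1
    return gamma


def penalty_vector(level_matrix: np.ndarray, src: np.ndarray,
                   dst: np.ndarray) -> np.ndarray:
    """Penalties for many assignments at once.

    ``level_matrix`` is (n_assignments, n_nodes); ``src``/``dst`` index the
    pair endpoints into its columns.  Returns one penalty per row.
    """
    if src.size == 0:
        return np.zeros(level_matrix.shape[0], dtype=np.int64)
    return (level_matrix[:, src] <= level_matrix[:, dst]).sum(axis=1)


def induce_subnetwork(net: Network, keep: Iterable[str]
                      ) -> tuple[Network, int, int]:
    """Subnetwork on ``keep`` plus boundary-edge counts.

    Returns ``(subnet, incoming, outgoing)`` where *incoming* counts edges
    from a node outside ``keep`` to a node inside, and *outgoing* the
    reverse — the boundary interactions a local analysis ignores.
    """
    ks = set(keep)
    for n in ks:
        if not net.has_node(n):
            raise KeyError(f"node {n!r} not in network")
    sub = Network(nodes=[n for n in net.nodes if n in ks])
    incoming = outgoing = 0
    for u, v in net.edges:
        u_in, v_in = u in ks, v in ks
        if u_in and v_in:
            sub.add_edge(u, v)
        elif v_in:
            incoming += 1
        elif u_in:
            outgoing += 1
    return sub, incoming, outgoing
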