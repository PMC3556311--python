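"""Model/Results front-end for hierarchical network decomposition.

:class:`HierarchyModel` is built from a network plus the two modelling
choices — the pair scheme (adjacency or reachability) and the level cap M —
and ``fit()`` returns a :class:`HierarchyResults` carrying the optimal
level assignment, its penalty, the optimality certificate and diagnostics,
in the spirit of the statsmodels Model/Results split::

    >>> from trnhier import HierarchyModel, example_network
    >>> res = HierarchyModel(example_network(), scheme="adjacency",
    ...                      max_levels=4).fit()
    >>> res.penalty
    1
"""

from __future__ import annotations

from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd

from . import evaluate, network, partition, solver

__all__ = ["HierarchyModel", "HierarchyResults"]


class HierarchyModel:
    """A minimum-conflict hierarchical decomposition problem.

    Parameters
    ----------
    net
        The directed regulator -> target network.
    scheme
        ``"adjacency"`` penalises conflicting direct edges;
        ``"reachability"`` penalises every conflicting ordered pair joined
        by a directed path.
    max_levels
        Level cap M.  Four is a practical default: on curated regulatory
        networks the penalty drops steeply up to four levels and only
        marginally beyond.
    """

    def __init__(self, net: network.Network, scheme: str,
                 max_levels: int = 4) -> None:
        if scheme not in network.SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}")
        if max_levels < 1:
            raise ValueError("max_levels must be >= 1")
        self.network = net
        self.scheme = scheme
        self.max_levels = max_levels
        self.pair_set = network.build_pair_set(net, scheme)

    @classmethod
    def from_edgelist(cls, source: str | Path | IO[str], scheme: str,
                      max_levels: int = 4) -> "HierarchyModel":
        """Build the model from a two-column regulator/target file."""
        return cls(network.read_edge_list(source), scheme, max_levels)

    # -- fitting ----------------------------------------------------------
    def fit(self, backend=None, time_limit: float | None = None
            ) -> "HierarchyResults":
        """Solve the MILP exactly (proven optimum unless time-limited)."""
        res = solver.solve(self.pair_set, self.network.nodes,
                           self.max_levels, backend=backend,
                           time_limit=time_limit)
        return HierarchyResults(self, res, method="exact")

    def fit_partitioned(self, partition_size: int = 100,
                        restarts: int = 1000, seed: int = 0,
                        backend=None, boundary_terms: bool = False
                        ) -> "HierarchyResults":
        """Divide-and-conquer fit for networks too large for one MILP."""
        cfg = partition.DncConfig(scheme=self.scheme, M=self.max_levels,
                                  partition_size=partition_size,
                                  restarts=restarts, rng_seed=seed,
                                  boundary_terms=boundary_terms)
        res = partition.dnc_solve(self.network, cfg, backend=backend)
        return HierarchyResults(self, res, method="divide-and-conquer")

    def fit_brute_force(self, cap: int = 10**7) -> "HierarchyResults":
        """Exhaustive-enumeration fit (small instances only)."""
        res = solver.brute_force_solve(self.pair_set, self.network.nodes,
                                       self.max_levels, cap=cap)
        return HierarchyResults(self, res, method="brute-force")

    def sweep(self, M_values: Sequence[int], backend=None,
              n_zsamples: int = 1000, seed: int = 0) -> pd.DataFrame:
        """Optimal penalty and Z-score per level cap."""
        return solver.sweep_levels(self.network, self.scheme, M_values,
                                   backend=backend, n_zsamples=n_zsamples,
                                   seed=seed)


class HierarchyResults:
    """A fitted hierarchical decomposition.

    Exposes the level assignment (1-based via :attr:`levels`), the conflict
    penalty, the optimality certificate, permutation-test significance and
    the robustness/stability simulation experiments.
    """

    def __init__(self, model: HierarchyModel, res: solver.SolveResult,
                 method: str) -> None:
        self.model = model
        self.assignment = res.assignment
        self.penalty = res.penalty
        self.optimal = res.optimal
        self.backend_name = res.backend_name
        self.method = method
        self.diagnostics = res.wall_info

    # -- views ------------------------------------------------------------
    @property
    def levels(self) -> dict[str, int]:
        """Node -> level, 1-based, larger = higher in the hierarchy."""
        return self.assignment.as_one_based()

    def zscore(self, n_samples: int = 1000,
               seed: int | np.random.Generator | None = 0
               ) -> evaluate.ZScoreResult:
        """Permutation Z-score of the fitted assignment."""
        return evaluate.zscore(self.assignment, self.model.pair_set,
                               n_samples=n_samples, rng=seed)

    def compare(self, other: "HierarchyResults") -> pd.DataFrame:
        """Per-node normalised level shift against another fit."""
        return evaluate.compare_assignments(self.assignment,
                                            other.assignment)

    # -- simulation experiments -------------------------------------------
    def robustness(self, percents: Sequence[float], n_mutants: int = 10,
                   n_zsamples: int = 1000, seed=0, backend=None
                   ) -> pd.DataFrame:
        """Score THIS assignment on degree-preserving mutants."""
        return evaluate.robustness_experiment(
            self.model.network, self.model.scheme, self.model.max_levels,
            percents, n_mutants=n_mutants, n_zsamples=n_zsamples, rng=seed,
            backend=backend)

    def stability(self, percents: Sequence[float], n_mutants: int = 10,
                  n_zsamples: int = 1000, seed=0, backend=None
                  ) -> pd.DataFrame:
        """Re-solve degree-preserving mutants from scratch."""
        return evaluate.stability_experiment(
            self.model.network, self.model.scheme, self.model.max_levels,
            percents, n_mutants=n_mutants, n_zsamples=n_zsamples, rng=seed,
            backend=backend)

    def enrichment(self, annotation, correction: str | None = None
                   ) -> pd.DataFrame:
        """Per-level hypergeometric over-representation of annotations."""
        return evaluate.level_enrichment(self.assignment, annotation,
                                         correction=correction)

    # -- output -----------------------------------------------------------
    def to_levels_file(self, dest: str | Path | IO[str]) -> None:
        network.write_levels(self.assignment, dest)

    def summary(self, n_zsamples: int = 1000, seed: int = 0) -> str:
        """Human-readable report of the fit."""
        try:
            z = self.zscore(n_samples=n_zsamples, seed=seed)
            zline = (f"Z-score:            {z.z:.2f}  "
                     f"(null mu={z.mu:.2f}, sigma={z.sigma:.2f}, "
                     f"n={z.n_samples})")
        except evaluate.DegenerateNullError:
            zline = "Z-score:            undefined (degenerate null)"
        hist = self.assignment.level_histogram()
        occ = ", ".join(f"L{t + 1}:{hist.get(t, 0)}"
                        for t in range(self.model.max_levels))
        lines = [
            "Hierarchical decomposition",
            "=" * 50,
            f"Nodes / edges:      {self.model.network.n_nodes} / "
            f"{self.model.network.n_edges}",
            f"Scheme:             {self.model.scheme} "
            f"({len(self.model.pair_set)} pairs)",
            f"Max levels (M):     {self.model.max_levels}",
            f"Method / backend:   {self.method} / {self.backend_name}",
            f"Penalty (gamma):    {self.penalty} conflicting pairs",
            f"Proven optimal:     {self.optimal}",
            zline,
            f"Level occupancy:    {occ}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (f"<HierarchyResults penalty={self.penalty} "
                f"M={self.model.max_levels} scheme={self.model.scheme} "
                f"optimal={self.optimal}>")
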