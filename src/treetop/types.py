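"""Shared domain types.

All per-cell structures are index-aligned to ``Embedding.cell_ids``;
serialized files always carry cell ids so alignment can be re-checked
on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "Embedding",
    "Clustering",
    "ClusteringEnsemble",
    "MilestoneGraph",
    "ConnectivityVector",
    "CellConnectivity",
    "Trajectory",
]


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(np.asarray(arr)))
        raise ValueError(f"{what} contains non-finite values at positions {bad[:5].tolist()}")


def _check_unique(ids, what: str) -> None:
    seen, dups = set(), []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class Embedding:
    """A low-dimensional cell embedding: N cells x d coordinates (2 <= d <= 50)."""

    coords: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be a 2-D array (cells x dimensions)")
        n, d = self.coords.shape
        if n < 3:
            raise ValueError(f"need at least 3 cells, got {n}")
        if not 2 <= d <= 50:
            raise ValueError(f"embedding dimensionality must be in [2, 50], got {d}")
        _check_finite(self.coords, "embedding coordinates")
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        _check_unique(self.cell_ids, "cell ids")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


@dataclass
class Clustering:
    """One k-medoids clustering of the cells: integer labels in 1..k."""

    labels: np.ndarray
    k: int
    seed: int
    sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        counts = np.bincount(self.labels, minlength=self.k + 1)[1:]
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=1) > self.k:
            raise ValueError(f"labels must lie in 1..{self.k}")
        if np.any(counts == 0):
            empty = np.nonzero(counts == 0)[0] + 1
            raise ValueError(f"empty clusters: {empty.tolist()}")
        self.sizes = counts
        assert int(self.sizes.sum()) == self.labels.size

    @property
    def n_cells(self) -> int:
        return self.labels.size


@dataclass
class ClusteringEnsemble:
    """The retained members of L clustering runs (L' = len(members) <= L)."""

    members: list[Clustering]
    L_requested: int
    k_range: tuple[int, int]
    min_cluster_size: int

    def __post_init__(self) -> None:
        if self.L_retained > self.L_requested:
            raise ValueError("retained more members than requested runs")
        for j, m in enumerate(self.members):
            if int(m.sizes.min()) < self.min_cluster_size:
                raise ValueError(
                    f"member {j} has a cluster of size {int(m.sizes.min())} "
                    f"< min_cluster_size {self.min_cluster_size}"
                )

    @property
    def L_retained(self) -> int:
        return len(self.members)


@dataclass
class MilestoneGraph:
    """Clusters as graph vertices 1..n_vertices with weighted edges.

    ``degrees[i]`` is the edge count of vertex ``i + 1``; for MSTs the
    degrees are the d_ij entering the connectivity statistic.
    """

    n_vertices: int
    edges: list[tuple[int, int, float]]
    is_tree: bool = False
    degrees: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        edges = []
        deg = np.zeros(self.n_vertices, dtype=int)
        for u, v, w in self.edges:
            u, v, w = int(u), int(v), float(w)
            if not (1 <= u <= self.n_vertices and 1 <= v <= self.n_vertices) or u == v:
                raise ValueError(f"invalid edge ({u}, {v})")
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"invalid edge weight {w} on ({u}, {v})")
            if u > v:
                u, v = v, u
            edges.append((u, v, w))
            deg[u - 1] += 1
            deg[v - 1] += 1
        self.edges = edges
        self.degrees = deg
        if self.is_tree:
            if len(edges) != self.n_vertices - 1:
                raise ValueError("tree must have n_vertices - 1 edges")
            g = self.to_networkx()
            if not nx.is_connected(g):
                raise ValueError("tree must be connected")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(1, self.n_vertices + 1))
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=w)
        return g


@dataclass
class ConnectivityVector:
    """Per-cell max-scaled MST-degree connectivity for one ensemble member."""

    values: np.ndarray
    source: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_finite(self.values, "connectivity values")
        if self.values.size and (self.values.min() <= 0 or self.values.max() != 1.0):
            raise ValueError("scaled connectivity must lie in (0, 1] with max exactly 1")


@dataclass
class CellConnectivity:
    """Arithmetic mean of the scaled connectivity vectors over the ensemble."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_finite(self.values, "cell connectivity")
        if self.values.size and (self.values.min() <= 0 or self.values.max() > 1.0 + 1e-12):
            raise ValueError("cell connectivity must lie in (0, 1]")


@dataclass
class Trajectory:
    """A directed milestone tree with lineages, pseudotime, and branch assignment.

    ``pseudotime`` is a dense N x n_lineages array of arc lengths from the
    root, with NaN marking cells outside a lineage.  ``branch_assignment``
    holds one directed milestone-network edge (from, to) per cell.
    """

    milestone_ids: list[str]
    network: list[tuple[str, str, float]]
    lineages: list[list[str]]
    cell_ids: list[str]
    pseudotime: np.ndarray
    branch_assignment: list[tuple[str, str]]
    root: str
    curves: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.milestone_ids = [str(m) for m in self.milestone_ids]
        _check_unique(self.milestone_ids, "milestone ids")
        ms = set(self.milestone_ids)
        if self.root not in ms:
            raise ValueError(f"root {self.root!r} is not a milestone")
        g = nx.Graph()
        g.add_nodes_from(self.milestone_ids)
        self.network = [(str(a), str(b), float(w)) for a, b, w in self.network]
        for a, b, w in self.network:
            if a not in ms or b not in ms:
                raise ValueError(f"network edge ({a}, {b}) uses unknown milestones")
            if w < 0 or not np.isfinite(w):
                raise ValueError(f"invalid edge length {w} on ({a}, {b})")
            g.add_edge(a, b)
        if g.number_of_edges() != len(self.milestone_ids) - 1 or not nx.is_connected(g):
            raise ValueError("milestone network skeleton must be a tree")
        leaves = {m for m in self.milestone_ids if g.degree[m] == 1 and m != self.root}
        for path in self.lineages:
            if path[0] != self.root:
                raise ValueError(f"lineage {path} does not start at root {self.root}")
            if path[-1] not in leaves and not (len(self.milestone_ids) == 1):
                # a root of degree 1 is still a valid lineage end when k == 2
                if not (g.degree[path[-1]] == 1):
                    raise ValueError(f"lineage {path} does not end at a leaf")
        self.cell_ids = [str(c) for c in self.cell_ids]
        _check_unique(self.cell_ids, "cell ids")
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        n, nl = len(self.cell_ids), len(self.lineages)
        if self.pseudotime.shape != (n, nl):
            raise ValueError(
                f"pseudotime shape {self.pseudotime.shape} != (n_cells={n}, n_lineages={nl})"
            )
        if not np.all(np.any(np.isfinite(self.pseudotime), axis=1)):
            raise ValueError("every cell must have finite pseudotime in at least one lineage")
        with np.errstate(invalid="ignore"):
            if np.any(self.pseudotime[np.isfinite(self.pseudotime)] < -1e-9):
                raise ValueError("pseudotime must be non-negative")
        if len(self.branch_assignment) != n:
            raise ValueError("one branch assignment needed per cell")
        undirected = {frozenset((a, b)) for a, b, _ in self.network}
        self.branch_assignment = [(str(a), str(b)) for a, b in self.branch_assignment]
        for a, b in self.branch_assignment:
            if frozenset((a, b)) not in undirected:
                raise ValueError(f"branch assignment ({a}, {b}) is not a network edge")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_lineages(self) -> int:
        return len(self.lineages)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.milestone_ids)
        for a, b, w in self.network:
            g.add_edge(a, b, weight=w)
        return g
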