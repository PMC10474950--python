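"""Seeded simulator of tree-shaped trajectory datasets with ground truth.

Milestones are placed in low-dimensional space so that adjacent
milestones sit exactly ``edge_length`` apart and non-adjacent milestones
at least ``edge_length`` apart (rejection-sampled layout).  Cells are
sampled along edges (probability proportional to edge length, uniform
progression) with isotropic Gaussian noise, so branch assignment and
pseudotime are unambiguous ground truth.  Topologies follow the usual
taxonomy: linear, bifurcation, multifurcation, and random trees.

The root is milestone ``M1`` by convention; ground-truth pseudotime is
path length from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx
import pandas as pd

from .types import Embedding, Trajectory

__all__ = [
    "SimulationSpec",
    "MilestoneNetwork",
    "simulate_topology",
    "simulate_cells",
    "simulate_expression",
    "simulate_dataset",
]

TOPOLOGIES = ("linear", "bifurcation", "multifurcation", "tree")


@dataclass
class SimulationSpec:
    """Parameters of one simulated dataset (all lengths in embedding units)."""

    topology: str = "bifurcation"
    n_milestones: int = 5
    n_cells: int = 300
    dims: int = 5
    edge_length: float = 1.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.n_milestones < 2:
            raise ValueError("need at least 2 milestones")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dims < 2:
            raise ValueError("dims must be >= 2")


@dataclass
class MilestoneNetwork:
    """Ground-truth milestone layout: ids, coordinates, directed edges."""

    milestone_ids: list[str]
    coords: np.ndarray
    edges: list[tuple[int, int, float]]  # (parent index, child index, length)
    root: str = "M1"


def _tree_edges(spec: SimulationSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    m = spec.n_milestones
    if spec.topology == "linear":
        return [(i, i + 1) for i in range(m - 1)]
    if spec.topology == "bifurcation":
        if m < 4:
            raise ValueError("a bifurcation needs at least 4 milestones")
        stem = [(i, i + 1) for i in range(m - 3)]
        return stem + [(m - 3, m - 2), (m - 3, m - 1)]
    if spec.topology == "multifurcation":
        if m < 5:
            raise ValueError("a multifurcation needs at least 5 milestones (>= 3 leaves)")
        return [(0, 1)] + [(1, j) for j in range(2, m)]
    # random tree from a seeded Pruefer sequence
    if m == 2:
        return [(0, 1)]
    seq = rng.integers(0, m, size=m - 2).tolist()
    g = nx.from_prufer_sequence(seq)
    return [tuple(sorted(e)) for e in g.edges]


def simulate_topology(spec: SimulationSpec) -> MilestoneNetwork:
    """Build the milestone tree and place it in ``spec.dims`` dimensions."""
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(3)[0])
    undirected = _tree_edges(spec, rng)
    g = nx.Graph(undirected)
    g.add_nodes_from(range(spec.n_milestones))
    if not nx.is_tree(g):
        raise ValueError("generated milestone network is not a tree")
    el = spec.edge_length
    for _ in range(200):  # layout attempts
        coords = np.zeros((spec.n_milestones, spec.dims))
        ok = True
        placed = [0]
        for parent, child in nx.bfs_edges(g, 0):
            good = False
            for _ in range(100):
                u = rng.normal(size=spec.dims)
                u /= np.linalg.norm(u)
                cand = coords[parent] + el * u
                others = [p for p in placed if p != parent]
                if all(np.linalg.norm(cand - coords[p]) >= el * (1 - 1e-9) for p in others):
                    coords[child] = cand
                    placed.append(child)
                    good = True
                    break
            if not good:
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError("could not place milestones; reduce n_milestones or edge_length")
    edges = [(p, c, el) for p, c in nx.bfs_edges(g, 0)]
    ids = [f"M{i + 1}" for i in range(spec.n_milestones)]
    return MilestoneNetwork(milestone_ids=ids, coords=coords, edges=edges)


def simulate_cells(net: MilestoneNetwork, spec: SimulationSpec) -> tuple[Embedding, Trajectory]:
    """Sample cells along edges; returns the embedding and the truth trajectory."""
    if spec.n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(3)[1])
    edges = net.edges
    lengths = np.array([w for _, _, w in edges])
    probs = lengths / lengths.sum()
    e_idx = rng.choice(len(edges), size=spec.n_cells, p=probs)
    prog = rng.random(spec.n_cells)
    pos = np.zeros((spec.n_cells, spec.dims))
    for i, (e, r) in enumerate(zip(e_idx, prog)):
        p, c, w = edges[e]
        pos[i] = (1 - r) * net.coords[p] + r * net.coords[c]
    if spec.noise_sd > 0:
        pos = pos + rng.normal(0.0, spec.noise_sd, size=pos.shape)
    cell_ids = [f"cell_{i + 1:04d}" for i in range(spec.n_cells)]
    emb = Embedding(pos, cell_ids)

    depth = {0: 0.0}
    children: dict[int, list[tuple[int, float]]] = {}
    for p, c, w in edges:
        children.setdefault(p, []).append((c, w))
        depth[c] = 0.0
    stack = [0]
    while stack:
        u = stack.pop()
        for c, w in children.get(u, []):
            depth[c] = depth[u] + w
            stack.append(c)
    g = nx.Graph((p, c) for p, c, _ in edges)
    g.add_nodes_from(range(spec.n_milestones))
    leaves = sorted(v for v in g if g.degree[v] == 1 and v != 0) or [0]
    paths = [nx.shortest_path(g, 0, leaf) for leaf in leaves]
    edge_in_path = [
        {(a, b) for a, b in zip(p, p[1:])} for p in paths
    ]
    pt = np.full((spec.n_cells, len(paths)), np.nan)
    branch: list[tuple[str, str]] = []
    for i, (e, r) in enumerate(zip(e_idx, prog)):
        p, c, w = edges[e]
        t = depth[p] + r * w
        for li, edge_set in enumerate(edge_in_path):
            if (p, c) in edge_set:
                pt[i, li] = t
        branch.append((f"M{p + 1}", f"M{c + 1}"))
    truth = Trajectory(
        milestone_ids=net.milestone_ids,
        network=[(f"M{p + 1}", f"M{c + 1}", float(w)) for p, c, w in edges],
        lineages=[[f"M{v + 1}" for v in p] for p in paths],
        cell_ids=cell_ids,
        pseudotime=pt,
        branch_assignment=branch,
        root="M1",
    )
    return emb, truth


def simulate_expression(
    embedding: Embedding,
    n_genes: int,
    seed: int | None = 0,
    noise_sd: float = 0.1,
    mapping: str = "random",
) -> pd.DataFrame:
    """Map coordinates to gene mean levels and add seeded Gaussian noise.

    The random map has orthonormal rows, so pairwise cell distances are
    preserved exactly before noise; a PCA/MDS re-embedding of the output
    therefore recovers the input geometry at the default noise level.
    """
    d = embedding.n_dims
    if n_genes < d:
        raise ValueError(f"n_genes must be >= embedding dimensionality {d}")
    rng = np.random.default_rng(seed)
    if mapping == "identity":
        if n_genes != d:
            raise ValueError("identity mapping requires n_genes == dims")
        expr = embedding.coords.copy()
    elif mapping == "random":
        q, _ = np.linalg.qr(rng.normal(size=(n_genes, d)))
        expr = embedding.coords @ q.T
    else:
        raise ValueError(f"unknown mapping {mapping!r}")
    if noise_sd > 0:
        expr = expr + rng.normal(0.0, noise_sd, size=expr.shape)
    return pd.DataFrame(
        expr,
        index=list(embedding.cell_ids),
        columns=[f"gene_{j + 1:04d}" for j in range(n_genes)],
    )


def simulate_dataset(spec: SimulationSpec) -> tuple[Embedding, Trajectory, MilestoneNetwork]:
    """Topology + cells in one call."""
    net = simulate_topology(spec)
    emb, truth = simulate_cells(net, spec)
    return emb, truth, net
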