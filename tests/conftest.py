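"""Shared fixtures: small deterministic embeddings and trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from treetop import Clustering, ClusteringEnsemble, Embedding, Trajectory


@pytest.fixture(scope="session")
def four_blobs() -> Embedding:
    """200 cells in 4 well-separated 2-D blobs of 50 cells each."""
    rng = np.random.default_rng(42)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
    pts = np.vstack([c + rng.normal(0, 0.5, size=(50, 2)) for c in centers])
    return Embedding(pts, [f"cell_{i}" for i in range(200)])


@pytest.fixture(scope="session")
def blob_labels() -> np.ndarray:
    return np.repeat([1, 2, 3, 4], 50)


def make_linear_trajectory(n_cells: int = 6, length: float = 2.0) -> Trajectory:
    """Two milestones, one edge, cells evenly spread along it."""
    pt = np.linspace(0.1, length - 0.1, n_cells)[:, None]
    return Trajectory(
        milestone_ids=["M1", "M2"],
        network=[("M1", "M2", length)],
        lineages=[["M1", "M2"]],
        cell_ids=[f"c{i}" for i in range(n_cells)],
        pseudotime=pt,
        branch_assignment=[("M1", "M2")] * n_cells,
        root="M1",
    )


def make_y_trajectory(per_edge: int = 4) -> Trajectory:
    """Y-shape A-B, B-C, B-D (unit edges) with cells mid-edge on every edge."""
    edges = [("M1", "M2"), ("M2", "M3"), ("M2", "M4")]
    depth = {"M1": 0.0, "M2": 1.0}
    lineages = [["M1", "M2", "M3"], ["M1", "M2", "M4"]]
    cells, branch, rows = [], [], []
    for ei, (a, b) in enumerate(edges):
        base = depth.get(a, 1.0)
        for j in range(per_edge):
            r = (j + 0.5) / per_edge
            t = base + r
            cells.append(f"c{ei}_{j}")
            branch.append((a, b))
            row = [np.nan, np.nan]
            for li, path in enumerate(lineages):
                if any((a, b) == pair for pair in zip(path, path[1:])):
                    row[li] = t
            rows.append(row)
    return Trajectory(
        milestone_ids=["M1", "M2", "M3", "M4"],
        network=[("M1", "M2", 1.0), ("M2", "M3", 1.0), ("M2", "M4", 1.0)],
        lineages=lineages,
        cell_ids=cells,
        pseudotime=np.array(rows),
        branch_assignment=branch,
        root="M1",
    )


def make_branch_trajectory(groups: list[list[str]], n_edges: int | None = None) -> Trajectory:
    """A star trajectory with one branch (edge) per cell group.

    Useful for hand-computed F1-branches cases: group i's cells are
    assigned to edge (M1, M{i+2}).
    """
    n_edges = n_edges or len(groups)
    milestone_ids = ["M1"] + [f"M{i + 2}" for i in range(n_edges)]
    network = [("M1", f"M{i + 2}", 1.0) for i in range(n_edges)]
    lineages = [["M1", f"M{i + 2}"] for i in range(n_edges)]
    cells, branch, rows = [], [], []
    for gi, group in enumerate(groups):
        for cid in group:
            cells.append(cid)
            branch.append(("M1", f"M{gi + 2}"))
            row = [np.nan] * n_edges
            row[gi] = 0.5
            rows.append(row)
    return Trajectory(
        milestone_ids=milestone_ids,
        network=network,
        lineages=lineages,
        cell_ids=cells,
        pseudotime=np.array(rows),
        branch_assignment=branch,
        root="M1",
    )


def ensemble_of(members: list[Clustering], min_cluster_size: int = 1) -> ClusteringEnsemble:
    return ClusteringEnsemble(
        members=members,
        L_requested=len(members),
        k_range=(min(m.k for m in members), max(m.k for m in members)),
        min_cluster_size=min_cluster_size,
    )
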