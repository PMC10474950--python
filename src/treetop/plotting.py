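"""Plots of connectivity, MSTs, and trajectories over a 2-D embedding."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .types import CellConnectivity, Clustering, Embedding, MilestoneGraph, Trajectory

__all__ = ["plot_connectivity", "plot_mst", "plot_trajectory"]


def _check_2d(embedding: Embedding) -> None:
    if embedding.n_dims != 2:
        raise ValueError(f"plotting needs a 2-D embedding, got d={embedding.n_dims}")


def plot_connectivity(embedding2d: Embedding, conn: CellConnectivity, out: str | Path) -> None:
    """Scatter of the cells colored by cell connectivity, with a colorbar."""
    _check_2d(embedding2d)
    if conn.values.size != embedding2d.n_cells:
        raise ValueError(
            f"connectivity has {conn.values.size} values for {embedding2d.n_cells} cells"
        )
    fig, ax = plt.subplots(figsize=(5, 4))
    vmin = float(conn.values.min())
    vmax = 1.0
    if vmin >= vmax:  # constant connectivity still renders
        vmin = vmax - 1e-6
    sc = ax.scatter(
        embedding2d.coords[:, 0], embedding2d.coords[:, 1],
        c=conn.values, s=12, cmap="viridis", vmin=vmin, vmax=vmax,
    )
    fig.colorbar(sc, ax=ax, label="cell connectivity")
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def plot_mst(
    embedding2d: Embedding, clustering: Clustering, mst: MilestoneGraph, out: str | Path
) -> None:
    """Cells colored by cluster with MST edges drawn between cluster centroids."""
    _check_2d(embedding2d)
    x = embedding2d.coords
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x[:, 0], x[:, 1], c=clustering.labels, s=12, cmap="tab20")
    cent = np.vstack(
        [x[clustering.labels == c].mean(axis=0) for c in range(1, clustering.k + 1)]
    )
    for u, v, _ in mst.edges:
        ax.plot(cent[[u - 1, v - 1], 0], cent[[u - 1, v - 1], 1], "k-", lw=1.5)
    ax.scatter(cent[:, 0], cent[:, 1], c="black", s=40, zorder=3)
    for c in range(clustering.k):
        ax.annotate(str(c + 1), cent[c], textcoords="offset points", xytext=(4, 4))
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def plot_trajectory(embedding2d: Embedding, traj: Trajectory, out: str | Path) -> None:
    """Cells colored by pseudotime with the fitted lineage curves overlaid."""
    _check_2d(embedding2d)
    pt = np.array([row[np.isfinite(row)][0] for row in traj.pseudotime])
    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(embedding2d.coords[:, 0], embedding2d.coords[:, 1], c=pt, s=12, cmap="plasma")
    fig.colorbar(sc, ax=ax, label="pseudotime")
    if traj.curves is not None:
        for curve in traj.curves:
            if curve.shape[1] >= 2:
                ax.plot(curve[:, 0], curve[:, 1], "k-", lw=1.5)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
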