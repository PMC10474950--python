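"""End-to-end estimator: embedding -> clustering ensemble -> connectivity
-> ranked MSTs -> smoothed directed trajectory."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cluster import generate_ensemble
from .connectivity import ensemble_connectivity
from .selection import asw_rank, connectivity_rank, plain_vrc_rank, random_rank, select_top
from .smoothing import choose_root, fit_simultaneous_curves
from .types import Clustering, ClusteringEnsemble, Embedding, MilestoneGraph, Trajectory

logger = logging.getLogger("treetop")

__all__ = ["ConnectivityTrajectory", "trajectory_for_member", "as_embedding"]


def as_embedding(X) -> Embedding:
    if isinstance(X, Embedding):
        return X
    if isinstance(X, pd.DataFrame):
        return Embedding(X.to_numpy(dtype=float), X.index.astype(str).tolist())
    x = np.asarray(X, dtype=float)
    return Embedding(x, [f"cell_{i + 1}" for i in range(x.shape[0])])


def trajectory_for_member(
    embedding: Embedding,
    clustering: Clustering,
    mst: MilestoneGraph,
    root: int | str | None = None,
    start_cell: str | int | None = None,
    max_iter: int = 15,
    tol: float = 1e-3,
    seed: int | None = None,
) -> Trajectory:
    """Smooth one ensemble member's MST into a directed trajectory.

    The root is, in order of precedence: the cluster of ``start_cell``,
    an explicit ``root`` vertex, or the shared-prefix-maximizing vertex.
    """
    if start_cell is not None:
        if isinstance(start_cell, str):
            idx = embedding.cell_ids.index(start_cell)
        else:
            idx = int(start_cell)
        root = int(clustering.labels[idx])
    elif root == "random":
        root = choose_root(mst, mode="random", seed=seed)
    elif root is None:
        root = choose_root(mst, mode="max_shared")
    return fit_simultaneous_curves(
        embedding, clustering, mst, root=int(root), max_iter=max_iter, tol=tol
    )


class ConnectivityTrajectory(BaseEstimator):
    """Cell-connectivity-guided trajectory inference.

    Fits a clustering ensemble (CLARA, k sampled from ``k_range``), builds
    one covariance-distance MST per retained clustering, averages the
    max-scaled MST-degree connectivity into the per-cell connectivity
    statistic, ranks the clusterings by the chosen criterion, and smooths
    the top-ranked MST into a directed trajectory with pseudotime.

    Parameters
    ----------
    n_runs : number of clustering runs L (default 10 000).
    k_range : inclusive (k_min, k_max) from which k is sampled (default (3, 20)).
    min_cluster_size : retain only clusterings whose clusters all have at
        least this many cells (default 5).
    selection : 'connectivity' (VRC on the cell-connectivity vector),
        'vrc', 'asw', or 'random'.
    root : milestone vertex id, 'auto' (maximize the shared lineage prefix)
        or 'random'.
    start_cell : cell id or index whose cluster becomes the root
        (overrides ``root``).
    random_state : master seed for the ensemble (and root/ranking draws).

    Attributes
    ----------
    ensemble_ : the retained clusterings (with L and L').
    cell_connectivity_ : per-cell averaged scaled connectivity, in (0, 1].
    msts_ : one MilestoneGraph per retained member.
    ranking_ : list of (member index, score), best first.
    labels_ : cluster labels of the selected member.
    trajectory_ : the smoothed directed Trajectory.
    pseudotime_ : per-cell pseudotime along each cell's best lineage.
    """

    def __init__(
        self,
        n_runs: int = 10_000,
        k_range: tuple[int, int] = (3, 20),
        min_cluster_size: int = 5,
        n_samples: int = 5,
        sample_size: int | None = None,
        selection: str = "connectivity",
        root: int | str = "auto",
        start_cell: str | int | None = None,
        max_iter: int = 15,
        tol: float = 1e-3,
        random_state: int | None = 0,
    ):
        self.n_runs = n_runs
        self.k_range = k_range
        self.min_cluster_size = min_cluster_size
        self.n_samples = n_samples
        self.sample_size = sample_size
        self.selection = selection
        self.root = root
        self.start_cell = start_cell
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        emb = as_embedding(X)
        self.embedding_ = emb
        self.ensemble_ = generate_ensemble(
            emb,
            L=self.n_runs,
            k_range=self.k_range,
            min_cluster_size=self.min_cluster_size,
            seed=self.random_state,
            n_samples=self.n_samples,
            sample_size=self.sample_size,
        )
        conn, msts, vectors = ensemble_connectivity(emb, self.ensemble_)
        self.cell_connectivity_ = conn
        self.msts_ = msts
        self.connectivity_vectors_ = vectors
        if self.selection == "connectivity":
            self.ranking_ = connectivity_rank(self.ensemble_, conn)
        elif self.selection == "vrc":
            self.ranking_ = plain_vrc_rank(self.ensemble_, emb)
        elif self.selection == "asw":
            self.ranking_ = asw_rank(self.ensemble_, emb)
        elif self.selection == "random":
            self.ranking_ = random_rank(self.ensemble_, seed=self.random_state)
        else:
            raise ValueError(f"unknown selection criterion {self.selection!r}")
        best = select_top(self.ranking_, 1)[0]
        self.selected_member_ = best
        member = self.ensemble_.members[best]
        self.labels_ = member.labels
        root = None if self.root == "auto" else self.root
        self.trajectory_ = trajectory_for_member(
            emb,
            member,
            self.msts_[best],
            root=root,
            start_cell=self.start_cell,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.random_state,
        )
        pt = self.trajectory_.pseudotime
        self.pseudotime_ = np.array(
            [row[np.isfinite(row)][0] if np.any(np.isfinite(row)) else np.nan for row in pt]
        )
        logger.info(
            "pipeline: N=%d, L=%d, L'=%d, selected member %d (k=%d), root %s",
            emb.n_cells, self.n_runs, self.ensemble_.L_retained, best, member.k,
            self.trajectory_.root,
        )
        return self

    def fit_predict(self, X, y=None):
        """Fit and return the selected clustering's labels."""
        return self.fit(X).labels_
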