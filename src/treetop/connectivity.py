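"""Cluster distances, MSTs, and the cell-connectivity statistic.

For each clustering the clusters become graph vertices, between-cluster
distances are Mahalanobis-like quadratic forms built from the cluster
covariances, and an MST over the distance matrix models the milestone
network.  Each cluster's connectivity is its MST degree divided by the
number of clusters; the per-cell vectors are max-scaled to 1 per MST and
averaged arithmetically over the ensemble:

    c_bar = (1 / L') * sum_j  c_j / max(c_j)

High cell connectivity marks cell populations far from the leaf parts
of the trajectory (branching regions); low connectivity marks leaves.
"""

from __future__ import annotations

import numpy as np

from .types import (
    CellConnectivity,
    Clustering,
    ClusteringEnsemble,
    ConnectivityVector,
    Embedding,
    MilestoneGraph,
)

__all__ = [
    "cluster_distances",
    "build_mst",
    "connectivity_vector",
    "aggregate_connectivity",
    "ensemble_connectivity",
]

_COND_MAX = 1e12


def _cluster_moments(x: np.ndarray, labels: np.ndarray, k: int):
    """Centroid, ML covariance, and size per cluster.

    Single-cell clusters get a diagonal covariance from the global
    per-dimension variance so the quadratic form stays defined.
    """
    d = x.shape[1]
    global_var = x.var(axis=0)
    mus, covs, ns = [], [], []
    for g in range(1, k + 1):
        pts = x[labels == g]
        ns.append(len(pts))
        mus.append(pts.mean(axis=0))
        if len(pts) == 1:
            covs.append(np.diag(global_var))
        else:
            c = pts - pts.mean(axis=0)
            covs.append((c.T @ c) / len(pts))
    return np.asarray(mus), np.asarray(covs), np.asarray(ns), d


def cluster_distances(embedding: Embedding, clustering: Clustering) -> np.ndarray:
    """Covariance-based (Mahalanobis-like) distances between clusters.

    d(i, j)^2 = (mu_i - mu_j)^T (S_i + S_j)^{-1} (mu_i - mu_j), where S are
    the cluster covariance matrices in embedding space, so the distance
    accounts for the shape and spread of the clusters.

    Small clusters (< d + 2 cells) or a numerically singular S_i + S_j fall
    back to the diagonal of the covariances; a residual ridge
    1e-6 * trace / d is added if the diagonal is still singular.
    """
    x = embedding.coords
    labels = clustering.labels
    k = clustering.k
    mus, covs, ns, d = _cluster_moments(x, labels, k)
    diags = np.einsum("kii->ki", covs)
    iu, ju = np.triu_indices(k, 1)
    diffs = mus[iu] - mus[ju]
    msum = covs[iu] + covs[ju]
    w = np.linalg.eigvalsh(msum)
    full_ok = (
        (np.minimum(ns[iu], ns[ju]) >= d + 2)
        & (w[:, 0] > w[:, -1] / _COND_MAX)
        & (w[:, -1] > 0)
    )
    q = np.full(iu.size, np.nan)
    if full_ok.any():
        sol = np.linalg.solve(msum[full_ok], diffs[full_ok][..., None])[..., 0]
        q[full_ok] = np.einsum("pd,pd->p", diffs[full_ok], sol)
    fb = ~full_ok
    if fb.any():
        # diagonal fallback, with a residual ridge if still near-singular
        dvec = diags[iu[fb]] + diags[ju[fb]]
        dead = dvec.max(axis=1) <= 0
        if dead.any():
            p = int(np.flatnonzero(fb)[np.flatnonzero(dead)[0]])
            raise ValueError(
                f"covariance sum for cluster pair ({iu[p] + 1}, {ju[p] + 1}) is singular"
            )
        ridge = dvec.min(axis=1) <= dvec.max(axis=1) / _COND_MAX
        dvec[ridge] += (1e-6 * dvec[ridge].sum(axis=1) / d)[:, None]
        q[fb] = np.sum(diffs[fb] ** 2 / dvec, axis=1)
    if not np.all(np.isfinite(q)):
        p = int(np.flatnonzero(~np.isfinite(q))[0])
        raise ValueError(
            f"covariance sum for cluster pair ({iu[p] + 1}, {ju[p] + 1}) is singular"
        )
    dist = np.zeros((k, k))
    dist[iu, ju] = dist[ju, iu] = np.sqrt(np.clip(q, 0.0, None))
    return dist


def build_mst(dist: np.ndarray) -> MilestoneGraph:
    """Minimum spanning tree over a symmetric distance matrix.

    Kruskal with edges pre-inserted in (u, v) order, so ties in weight are
    broken reproducibly.
    """
    dist = np.asarray(dist, dtype=float)
    k = dist.shape[0]
    if dist.shape != (k, k):
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(dist)):
        raise ValueError("distance matrix contains non-finite entries")
    if not np.allclose(dist, dist.T) or np.any(np.diag(dist) != 0) or np.any(dist < 0):
        raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")
    iu, ju = np.triu_indices(k, 1)
    order = np.lexsort((ju, iu, dist[iu, ju]))  # by (weight, u, v)
    parent = list(range(k))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges: list[tuple[int, int, float]] = []
    for idx in order:
        u, v = int(iu[idx]), int(ju[idx])
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            edges.append((u + 1, v + 1, float(dist[u, v])))
            if len(edges) == k - 1:
                break
    edges.sort()
    return MilestoneGraph(n_vertices=k, edges=edges, is_tree=True)


def connectivity_vector(mst: MilestoneGraph, clustering: Clustering) -> ConnectivityVector:
    """Per-cell scaled connectivity for one MST: degree / k, max-scaled to 1."""
    if mst.n_vertices != clustering.k:
        raise ValueError(
            f"MST has {mst.n_vertices} vertices but clustering has k={clustering.k}"
        )
    raw = mst.degrees / clustering.k  # c_ij = d_ij / k_j per cluster
    per_cell = raw[clustering.labels - 1]
    scaled = per_cell / per_cell.max()
    return ConnectivityVector(values=scaled, source=-1)


def aggregate_connectivity(vectors: list[ConnectivityVector]) -> CellConnectivity:
    """Arithmetic mean of the max-scaled connectivity vectors (Eq. above)."""
    if not vectors:
        raise ValueError("need at least one connectivity vector")
    stack = np.vstack([v.values for v in vectors])
    return CellConnectivity(values=stack.mean(axis=0))


def ensemble_connectivity(
    embedding: Embedding, ensemble: ClusteringEnsemble
) -> tuple[CellConnectivity, list[MilestoneGraph], list[ConnectivityVector]]:
    """Distances + MST + connectivity for every member, then the aggregate."""
    msts, vectors = [], []
    for j, member in enumerate(ensemble.members):
        dist = cluster_distances(embedding, member)
        mst = build_mst(dist)
        vec = connectivity_vector(mst, member)
        vec.source = j
        msts.append(mst)
        vectors.append(vec)
    return aggregate_connectivity(vectors), msts, vectors
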