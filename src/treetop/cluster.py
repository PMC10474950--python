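"""k-medoids clustering ensembles via CLARA.

CLARA (Clustering LARge Applications) draws ``n_samples`` subsamples,
runs PAM (BUILD + SWAP) on each, assigns every cell to its nearest
medoid, scores by total dissimilarity over all cells, and keeps the best
subsample's solution.  The ensemble generator repeats this L times with
k drawn uniformly with replacement from a k-range and filters out
clusterings containing clusters smaller than ``min_cluster_size``
(default 5) — the filter that keeps overly small milestones out of the
trajectory search.
"""

from __future__ import annotations

import logging

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin

from .types import Clustering, ClusteringEnsemble, Embedding

logger = logging.getLogger("treetop")

__all__ = ["CLARA", "clara_cluster", "generate_ensemble", "pam"]

_SEED_MASK = 0x7FFFFFFF


@njit(cache=True)
def _pam_kernel(dist: np.ndarray, k: int) -> np.ndarray:  # pragma: no cover
    n = dist.shape[0]
    medoids = np.empty(k, dtype=np.int64)
    is_medoid = np.zeros(n, dtype=np.bool_)
    # BUILD: greedy total-deviation minimization, ties to the lowest index
    best, best_cost = 0, np.inf
    for c in range(n):
        s = 0.0
        for p in range(n):
            s += dist[p, c]
        if s < best_cost:
            best, best_cost = c, s
    medoids[0] = best
    is_medoid[best] = True
    dn = dist[:, best].copy()
    for m in range(1, k):
        best, best_red = -1, -np.inf
        for c in range(n):
            if is_medoid[c]:
                continue
            red = 0.0
            for p in range(n):
                g = dn[p] - dist[p, c]
                if g > 0.0:
                    red += g
            if red > best_red:
                best, best_red = c, red
        medoids[m] = best
        is_medoid[best] = True
        for p in range(n):
            if dist[p, best] < dn[p]:
                dn[p] = dist[p, best]
    medoids = np.sort(medoids)
    # SWAP until no (medoid, candidate) exchange lowers total deviation
    nearest = np.empty(n, dtype=np.int64)
    ds = np.empty(n)
    bsum = np.empty(n)
    delta = np.empty((k, n))
    while True:
        for p in range(n):
            n1, d1, d2 = 0, np.inf, np.inf
            for mi in range(k):
                dpm = dist[p, medoids[mi]]
                if dpm < d1:
                    n1, d2, d1 = mi, d1, dpm
                elif dpm < d2:
                    d2 = dpm
            nearest[p] = n1
            dn[p] = d1
            ds[p] = d2
        for h in range(n):
            bsum[h] = 0.0
        for mi in range(k):
            for h in range(n):
                delta[mi, h] = 0.0
        for p in range(n):
            dnp, dsp, npi = dn[p], ds[p], nearest[p]
            for h in range(n):
                b = dist[p, h] - dnp
                if b > 0.0:
                    b = 0.0
                a = dist[p, h]
                if dsp < a:
                    a = dsp
                a -= dnp
                bsum[h] += b
                delta[npi, h] += a - b
        bi, bh, bd = -1, -1, -1e-12  # first strict minimum in (medoid, candidate) order
        for mi in range(k):
            for h in range(n):
                if is_medoid[h]:
                    continue
                d = delta[mi, h] + bsum[h]
                if d < bd:
                    bi, bh, bd = mi, h, d
        if bi < 0:
            break
        is_medoid[medoids[bi]] = False
        is_medoid[bh] = True
        medoids[bi] = bh
        medoids = np.sort(medoids)
    return medoids


def pam(dist: np.ndarray, k: int) -> np.ndarray:
    """PAM on a full distance matrix: BUILD init + SWAP to a local optimum.

    Returns the sorted medoid indices.  Ties are broken toward the lowest
    index at every step, so the result is deterministic.
    """
    dist = np.ascontiguousarray(dist, dtype=float)
    n = dist.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} points")
    return np.asarray(_pam_kernel(dist, k), dtype=int)


def _clara_labels(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    n_samples: int,
    sample_size: int,
    dist_full: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Run CLARA; returns (labels in 1..k, medoid indices, total dissimilarity)."""
    n = x.shape[0]
    size = min(sample_size, n)
    best = None
    for _ in range(n_samples):
        idx = np.sort(rng.choice(n, size=size, replace=False))
        if dist_full is not None:
            d_sub = dist_full[np.ix_(idx, idx)]
        else:
            d_sub = cdist(x[idx], x[idx])
        med_local = pam(d_sub, k)
        med = idx[med_local]
        d_to_med = dist_full[:, med] if dist_full is not None else cdist(x, x[med])
        cost = float(d_to_med.min(axis=1).sum())
        if best is None or cost < best[0]:
            assign = np.argmin(d_to_med, axis=1)  # ties -> lowest medoid index
            best = (cost, med, assign)
    cost, med, assign = best
    # canonical labeling: clusters numbered by ascending medoid index
    order = np.argsort(med, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return relabel[assign], med[order], cost


class CLARA(ClusterMixin, BaseEstimator):
    """CLARA k-medoids clusterer (subsampled PAM with full-data assignment).

    Parameters
    ----------
    n_clusters : number of medoids k (2 <= k < n_cells).
    n_samples : number of independent subsamples (default 5).
    sample_size : subsample size; default ``40 + 2 * n_clusters``.
    random_state : seed for subsample draws; same seed, same labels.
    """

    def __init__(self, n_clusters: int = 3, n_samples: int = 5,
                 sample_size: int | None = None, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_samples = n_samples
        self.sample_size = sample_size
        self.random_state = random_state

    def fit(self, X, y=None, dist_full: np.ndarray | None = None):
        x, _ = (X.coords, None) if isinstance(X, Embedding) else (np.asarray(X, dtype=float), None)
        n = x.shape[0]
        k = self.n_clusters
        if k < 2:
            raise ValueError("n_clusters must be >= 2")
        if k >= n:
            raise ValueError(f"n_clusters={k} must be < n_cells={n}")
        size = self.sample_size if self.sample_size is not None else 40 + 2 * k
        if size < k:
            raise ValueError(f"sample_size={size} must be >= n_clusters={k}")
        rng = np.random.default_rng(self.random_state)
        labels, med, cost = _clara_labels(x, k, rng, self.n_samples, size, dist_full)
        self.labels_ = labels
        self.medoid_indices_ = med
        self.inertia_ = cost
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def clara_cluster(
    embedding: Embedding,
    k: int,
    seed: int,
    n_samples: int = 5,
    sample_size: int | None = None,
) -> Clustering:
    """One CLARA run on an embedding, returned as a :class:`Clustering`."""
    est = CLARA(n_clusters=k, n_samples=n_samples, sample_size=sample_size, random_state=seed)
    est.fit(embedding)
    return Clustering(labels=est.labels_, k=k, seed=int(seed))


def generate_ensemble(
    embedding: Embedding,
    L: int = 10_000,
    k_range: tuple[int, int] = (3, 20),
    min_cluster_size: int = 5,
    seed: int | None = 0,
    n_samples: int = 5,
    sample_size: int | None = None,
) -> ClusteringEnsemble:
    """Run CLARA L times with k ~ Uniform{k_min..k_max} and filter small clusters.

    Child seeds are split from the master seed with ``SeedSequence.spawn``,
    so member j's result does not depend on the other runs.
    """
    k_min, k_max = int(k_range[0]), int(k_range[1])
    n = embedding.n_cells
    if k_max < k_min:
        raise ValueError(f"k_max {k_max} < k_min {k_min}")
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if k_max >= n:
        raise ValueError(f"k_max {k_max} must be < n_cells {n}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(L + 1)
    ks = np.random.default_rng(children[0]).integers(k_min, k_max + 1, size=L)
    x = embedding.coords
    dist_full = cdist(x, x) if n <= 4000 else None
    members: list[Clustering] = []
    for j in range(L):
        k = int(ks[j])
        child_seed = int(children[j + 1].generate_state(1)[0] & _SEED_MASK)
        size = sample_size if sample_size is not None else 40 + 2 * k
        if size < k:
            size = k
        rng = np.random.default_rng(child_seed)
        labels, _, _ = _clara_labels(x, k, rng, n_samples, size, dist_full)
        sizes = np.bincount(labels, minlength=k + 1)[1:]
        if sizes.min() >= min_cluster_size:
            members.append(Clustering(labels=labels, k=k, seed=child_seed))
    if not members:
        raise ValueError(
            f"all {L} clusterings were filtered out (every run had a cluster with "
            f"fewer than {min_cluster_size} cells); use a smaller min_cluster_size, "
            f"a narrower k-range, or more cells"
        )
    ens = ClusteringEnsemble(
        members=members, L_requested=L, k_range=(k_min, k_max), min_cluster_size=min_cluster_size
    )
    logger.info(
        "ensemble: N=%d, k_range=(%d, %d), L=%d, L'=%d, master_seed=%s",
        n, k_min, k_max, L, ens.L_retained, seed,
    )
    return ens
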