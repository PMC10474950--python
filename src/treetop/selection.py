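"""Ranking ensemble members for trajectory construction.

The guiding criterion ranks clusterings by the variance ratio criterion
(VRC, Calinski-Harabasz) evaluated on the one-dimensional cell-connectivity
vector instead of the full embedding: a clustering scores high when its
clusters have internally similar but mutually different connectivity,
which is what a clustering that captures the tree structure looks like.
ASW, plain VRC on the embedding, and a random criterion are provided as
comparators.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.metrics import silhouette_samples

from .types import CellConnectivity, ClusteringEnsemble, Embedding

__all__ = [
    "vrc",
    "connectivity_rank",
    "asw_rank",
    "plain_vrc_rank",
    "random_rank",
    "select_top",
]

Ranking = list[tuple[int, float]]


def vrc(values: np.ndarray, labels: np.ndarray) -> float:
    """Variance ratio criterion (Calinski-Harabasz score).

    VRC = [B / (k - 1)] / [W / (N - k)] with B the between-cluster and W
    the within-cluster sum of squared deviations.  Returns +inf when the
    within-cluster dispersion is exactly zero.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k, n = uniq.size, x.shape[0]
    if k < 2:
        raise ValueError("VRC needs at least 2 clusters")
    if n <= k:
        raise ValueError(f"VRC needs more points ({n}) than clusters ({k})")
    overall = x.mean(axis=0)
    b = 0.0
    w = 0.0
    for g in uniq:
        pts = x[labels == g]
        mg = pts.mean(axis=0)
        b += len(pts) * float(np.sum((mg - overall) ** 2))
        w += float(np.sum((pts - mg) ** 2))
    if w == 0.0:
        return np.inf
    return (b / (k - 1)) / (w / (n - k))


def _sorted_ranking(scores: list[float], ks: list[int]) -> Ranking:
    """Descending by score; +inf ties prefer larger k, then member index."""
    idx = sorted(range(len(scores)), key=lambda j: (-scores[j], -ks[j], j))
    return [(j, scores[j]) for j in idx]


def connectivity_rank(ensemble: ClusteringEnsemble, cell_conn: CellConnectivity) -> Ranking:
    """Rank members by VRC of the clustering on the 1-D cell-connectivity vector."""
    scores = [vrc(cell_conn.values, m.labels) for m in ensemble.members]
    return _sorted_ranking(scores, [m.k for m in ensemble.members])


def plain_vrc_rank(ensemble: ClusteringEnsemble, embedding: Embedding) -> Ranking:
    """Rank members by VRC on the full embedding (comparison criterion)."""
    scores = [vrc(embedding.coords, m.labels) for m in ensemble.members]
    return _sorted_ranking(scores, [m.k for m in ensemble.members])


def asw_rank(ensemble: ClusteringEnsemble, embedding: Embedding) -> Ranking:
    """Rank members by average silhouette width on Euclidean embedding distances."""
    dist = squareform(pdist(embedding.coords))
    scores = []
    for m in ensemble.members:
        if m.k < 2:
            raise ValueError("silhouette is undefined for a single cluster")
        s = silhouette_samples(dist, m.labels, metric="precomputed")
        scores.append(float(s.mean()))
    return _sorted_ranking(scores, [m.k for m in ensemble.members])


def random_rank(ensemble: ClusteringEnsemble, seed: int | None = 0) -> Ranking:
    """Seeded random permutation of the members (the null comparison)."""
    rng = np.random.default_rng(seed)
    scores = rng.random(ensemble.L_retained)
    idx = np.argsort(-scores, kind="stable")
    return [(int(j), float(scores[j])) for j in idx]


def select_top(ranked: Ranking, n: int) -> list[int]:
    """Indices of the first min(n, L') ranked members."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [j for j, _ in ranked[:n]]
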