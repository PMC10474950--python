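"""Feature extraction into a low-dimensional embedding.

Three reducers are provided: PCA, classical (Torgerson) MDS, and landmark
MDS (LMDS).  The default pipeline entry point is 5-dimensional LMDS on
Euclidean distances between the (already normalized) expression rows;
normalization, QC, HVG selection and batch integration are assumed done
upstream.

All reducers return centered coordinates (column means ~ 0) and are
deterministic: PCA components have their largest-magnitude loading made
positive, MDS eigenpairs are ordered by decreasing eigenvalue with ties
broken by index, and LMDS landmarks are drawn uniformly without
replacement under the given seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .types import Embedding

__all__ = ["pca_embed", "mds_embed", "lmds_embed", "PCAReducer", "ClassicalMDS", "LandmarkMDS"]


def _as_matrix(expr) -> tuple[np.ndarray, list[str]]:
    if isinstance(expr, pd.DataFrame):
        return expr.to_numpy(dtype=float), expr.index.astype(str).tolist()
    if isinstance(expr, Embedding):
        return expr.coords, list(expr.cell_ids)
    x = np.asarray(expr, dtype=float)
    return x, [f"cell_{i + 1}" for i in range(x.shape[0])]


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    # deterministic orientation: largest-|value| coordinate of each column positive
    for j in range(coords.shape[1]):
        col = coords[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            coords[:, j] = -col
    return coords


def _classical_mds_eig(d2: np.ndarray, n_dims: int) -> tuple[np.ndarray, np.ndarray]:
    """Double-center the squared distances and return top eigenpairs."""
    n = d2.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(-vals, kind="stable")[:n_dims]
    return vals[order], vecs[:, order]


class PCAReducer(BaseEstimator):
    """PCA with a deterministic sign convention, emitting :class:`Embedding`."""

    def __init__(self, n_dims: int = 5):
        self.n_dims = n_dims

    def fit_transform(self, expr, y=None) -> Embedding:
        x, ids = _as_matrix(expr)
        if self.n_dims < 2:
            raise ValueError("n_dims must be >= 2")
        if self.n_dims > min(x.shape):
            raise ValueError(f"n_dims {self.n_dims} > min(n_cells, n_genes) = {min(x.shape)}")
        pca = PCA(n_components=self.n_dims, svd_solver="full")
        coords = pca.fit_transform(x)
        coords = _fix_signs(coords)
        self.explained_variance_ = pca.explained_variance_
        self.components_ = pca.components_
        self.embedding_ = Embedding(coords, ids)
        return self.embedding_


class ClassicalMDS(BaseEstimator):
    """Classical (Torgerson) metric MDS on Euclidean row distances."""

    def __init__(self, n_dims: int = 5):
        self.n_dims = n_dims

    def fit_transform(self, expr, y=None) -> Embedding:
        x, ids = _as_matrix(expr)
        if self.n_dims < 2:
            raise ValueError("n_dims must be >= 2")
        d2 = cdist(x, x, metric="sqeuclidean")
        vals, vecs = _classical_mds_eig(d2, self.n_dims)
        coords = vecs * np.sqrt(np.clip(vals, 0.0, None))
        coords = _fix_signs(coords - coords.mean(axis=0))
        self.eigenvalues_ = vals
        self.embedding_ = Embedding(coords, ids)
        return self.embedding_


class LandmarkMDS(BaseEstimator):
    """Landmark MDS: classical MDS on a landmark subset, triangulating the rest.

    With ``n_landmarks >= n_cells`` this reduces to classical MDS up to a
    rigid transformation.  Deterministic given ``random_state``.
    """

    def __init__(self, n_dims: int = 5, n_landmarks: int = 500, random_state: int | None = 0):
        self.n_dims = n_dims
        self.n_landmarks = n_landmarks
        self.random_state = random_state

    def fit_transform(self, expr, y=None) -> Embedding:
        x, ids = _as_matrix(expr)
        n = x.shape[0]
        n_land = min(self.n_landmarks, n)
        if self.n_dims < 2:
            raise ValueError("n_dims must be >= 2")
        if n_land < self.n_dims + 1:
            raise ValueError(
                f"n_landmarks must be >= n_dims + 1 = {self.n_dims + 1}, got {n_land}"
            )
        rng = np.random.default_rng(self.random_state)
        landmarks = np.sort(rng.choice(n, size=n_land, replace=False))
        d2_ll = cdist(x[landmarks], x[landmarks], metric="sqeuclidean")
        vals, vecs = _classical_mds_eig(d2_ll, self.n_dims)
        pos = np.clip(vals, 0.0, None)
        if np.any(pos <= 0):
            raise ValueError("landmark configuration has rank below n_dims")
        # pseudo-inverse triangulation of de Silva & Tenenbaum
        l_sharp = vecs / np.sqrt(pos)  # n_land x n_dims
        d2_all = cdist(x, x[landmarks], metric="sqeuclidean")
        mean_d2 = d2_ll.mean(axis=0)
        coords = -0.5 * (d2_all - mean_d2) @ l_sharp
        coords = _fix_signs(coords - coords.mean(axis=0))
        self.landmarks_ = landmarks
        self.eigenvalues_ = vals
        self.embedding_ = Embedding(coords, ids)
        return self.embedding_


def pca_embed(expr, n_dims: int = 5) -> Embedding:
    """Principal-component embedding (per-gene centering, sign-fixed)."""
    return PCAReducer(n_dims=n_dims).fit_transform(expr)


def mds_embed(expr, n_dims: int = 5) -> Embedding:
    """Classical MDS embedding of Euclidean row distances."""
    return ClassicalMDS(n_dims=n_dims).fit_transform(expr)


def lmds_embed(expr, n_dims: int = 5, n_landmarks: int = 500, seed: int | None = 0) -> Embedding:
    """Landmark MDS embedding; the pipeline default at 5 dimensions."""
    return LandmarkMDS(n_dims=n_dims, n_landmarks=n_landmarks, random_state=seed).fit_transform(expr)
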