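"""Lineage smoothing: from a clustering + MST to a directed trajectory.

Each root-to-leaf path of the MST is a lineage.  One principal curve is
fitted per lineage by the classic alternating scheme: project cells onto
the current curve to get an arc-length parameter, smooth each embedding
coordinate against the parameter (cubic smoothing spline, GCV-selected
penalty), rebuild the curve, and repeat until the total squared
orthogonal distance stabilizes.  Cells belonging to several lineages
(clusters before the first branching point) have their smoothed
positions and arc-length pseudotimes averaged across those lineages each
iteration, so shared stems coincide and stem pseudotime agrees between
lineages exactly.

Pseudotime is raw arc length in embedding units, starting at 0 at the
root end of each lineage.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.interpolate import CubicSpline

from .types import Clustering, Embedding, MilestoneGraph, Trajectory

__all__ = [
    "lineages_from_mst",
    "fit_principal_curve",
    "fit_simultaneous_curves",
    "choose_root",
]

_EPS_LEN = 1e-9


def lineages_from_mst(mst: MilestoneGraph, root: int) -> list[list[int]]:
    """Root-to-leaf vertex paths, one per leaf, ordered by leaf id."""
    g = mst.to_networkx()
    if root not in g:
        raise ValueError(f"root {root} is not a vertex of the MST")
    if not mst.is_tree:
        raise ValueError("lineages require a tree")
    leaves = sorted(v for v in g if g.degree[v] == 1 and v != root)
    if not leaves:  # single vertex
        return [[root]]
    return [nx.shortest_path(g, root, leaf) for leaf in leaves]


def choose_root(mst: MilestoneGraph, mode: str = "max_shared", seed: int | None = None) -> int:
    """Pick a root vertex: uniformly at random, or maximizing the shared prefix.

    ``max_shared`` picks the vertex whose lineages share the longest common
    prefix (in edges) before the first branching point; ties break toward
    the lowest vertex id.
    """
    vertices = list(range(1, mst.n_vertices + 1))
    if mode == "random":
        rng = np.random.default_rng(seed)
        return int(vertices[rng.integers(len(vertices))])
    if mode != "max_shared":
        raise ValueError(f"unknown root mode {mode!r}")
    best, best_len = None, -1
    for r in vertices:
        paths = lineages_from_mst(mst, r)
        prefix = len(paths[0]) - 1
        for p in paths[1:]:
            shared = 0
            for a, b in zip(paths[0], p):
                if a != b:
                    break
                shared += 1
            prefix = min(prefix, shared - 1)
        if prefix > best_len:
            best, best_len = r, prefix
    return int(best)


def _project_polyline(points: np.ndarray, verts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project points onto a polyline; returns (arc-length param, squared dist)."""
    if verts.shape[0] == 1:
        sq = np.sum((points - verts[0]) ** 2, axis=1)
        return np.zeros(points.shape[0]), sq
    a = verts[:-1]
    b = verts[1:] - verts[:-1]
    seg_len2 = np.sum(b * b, axis=1)
    seg_len = np.sqrt(seg_len2)
    safe = np.where(seg_len2 > 0, seg_len2, 1.0)
    # t: n_points x n_segments clipped projection parameter
    t = np.clip(np.einsum("pd,sd->ps", points, b) - np.einsum("sd,sd->s", a, b), 0.0, safe)
    t = t / safe
    proj = a[None, :, :] + t[:, :, None] * b[None, :, :]
    sq = np.sum((points[:, None, :] - proj) ** 2, axis=2)
    seg = np.argmin(sq, axis=1)
    n = points.shape[0]
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    lam = cum[seg] + t[np.arange(n), seg] * seg_len[seg]
    return lam, sq[np.arange(n), seg]


_MAX_SPLINE_POINTS = 100


def _reinsch_penalty(x: np.ndarray) -> np.ndarray:
    """Natural cubic smoothing-spline penalty matrix K with f' K f = int f''^2."""
    m = x.size
    h = np.diff(x)
    delta = np.zeros((m - 2, m))
    rows = np.arange(m - 2)
    delta[rows, rows] = 1.0 / h[:-1]
    delta[rows, rows + 1] = -1.0 / h[:-1] - 1.0 / h[1:]
    delta[rows, rows + 2] = 1.0 / h[1:]
    c = np.diag((h[:-1] + h[1:]) / 3.0)
    off = h[1:-1] / 6.0
    if off.size:
        c[rows[:-1], rows[:-1] + 1] = off
        c[rows[:-1] + 1, rows[:-1]] = off
    return delta.T @ np.linalg.solve(c, delta)


def smoothing_spline_gcv(
    x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None, lam: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted natural cubic smoothing spline, penalty chosen per column by GCV.

    Minimizes sum_i w_i (y_i - f(x_i))^2 + lam * int f''^2 over natural cubic
    splines with knots at the strictly increasing sites ``x``.  ``y`` may
    hold several columns; the Demmler-Reinsch eigendecomposition is shared
    across columns and GCV is minimized on a log-spaced lambda grid per
    column (one O(m) evaluation per candidate).  Returns (fitted values at
    the sites, chosen lam per column).
    """
    x = np.asarray(x, dtype=float)
    y2 = np.asarray(y, dtype=float)
    squeeze = y2.ndim == 1
    if squeeze:
        y2 = y2[:, None]
    m, d = y2.shape
    w = np.ones(m) if w is None else np.asarray(w, dtype=float)
    if m < 4:
        raise ValueError("need at least 4 sites for a cubic smoothing spline")
    sw = np.sqrt(w)
    b = _reinsch_penalty(x) / np.outer(sw, sw)
    mu, u = np.linalg.eigh((b + b.T) / 2.0)
    mu = np.clip(mu, 0.0, None)
    z = u.T @ (sw[:, None] * y2)
    pos = mu[mu > 1e-10 * max(mu.max(), 1e-300)]
    if pos.size == 0:  # penalty vanishes: the fit is the (weighted) line itself
        fit = (u @ z) / sw[:, None]
        lams = np.zeros(d)
        return (fit[:, 0], lams) if squeeze else (fit, lams)
    grid = np.geomspace(1e-7 / pos.max(), 1e7 / pos.min(), 90)
    shrink = grid[:, None] * mu[None, :]  # n_grid x m
    denom = (1.0 - np.sum(1.0 / (1.0 + shrink), axis=1) / m) ** 2
    frac2 = (shrink / (1.0 + shrink)) ** 2
    fit = np.empty((m, d))
    lams = np.empty(d)
    for jd in range(d):
        if lam is None:
            rss = frac2 @ (z[:, jd] ** 2) / m
            with np.errstate(divide="ignore", invalid="ignore"):
                gcv = np.where(denom > 1e-12, rss / denom, np.inf)
            lam_j = float(grid[int(np.argmin(gcv))])
        else:
            lam_j = float(lam)
        fit[:, jd] = (u @ (z[:, jd] / (1.0 + lam_j * mu))) / sw
        lams[jd] = lam_j
    return (fit[:, 0], lams) if squeeze else (fit, lams)


def _smooth_against(lam: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Smooth each coordinate of pts against lam; returns smoothed positions.

    Uses a GCV cubic smoothing spline.  The parameter axis is first
    reduced to at most ``_MAX_SPLINE_POINTS`` weighted bin means (the
    GCV search is quadratic in the number of sites, and the curve is
    needed only at bin resolution); each cell's smoothed position is the
    fitted spline evaluated at its own parameter value.  Lineages with
    fewer than 10 distinct parameter values fall back to a least-squares
    line.
    """
    xu, inv, counts = np.unique(np.round(lam, 12), return_inverse=True, return_counts=True)
    d = pts.shape[1]
    yu = np.zeros((xu.size, d))
    np.add.at(yu, inv, pts)
    yu /= counts[:, None]
    w = counts.astype(float)
    if xu.size > _MAX_SPLINE_POINTS:
        # aggregate into equal-width bins over the parameter range
        edges = np.linspace(xu[0], xu[-1], _MAX_SPLINE_POINTS + 1)
        bins = np.clip(np.searchsorted(edges, xu, side="right") - 1, 0, _MAX_SPLINE_POINTS - 1)
        bw = np.bincount(bins, weights=w, minlength=_MAX_SPLINE_POINTS)
        keep = bw > 0
        bx = np.bincount(bins, weights=w * xu, minlength=_MAX_SPLINE_POINTS)[keep] / bw[keep]
        by = np.vstack([
            np.bincount(bins, weights=w * yu[:, jd], minlength=_MAX_SPLINE_POINTS)[keep]
            for jd in range(d)
        ]).T / bw[keep][:, None]
        fx, fy, fw = bx, by, bw[keep]
    else:
        fx, fy, fw = xu, yu, w
    su = np.empty((xu.size, d))
    if fx.size >= 10:
        try:
            fit, _ = smoothing_spline_gcv(fx, fy, w=fw)
            # the smoothing spline is the natural cubic interpolant of its
            # own fitted site values; evaluate it at every cell's parameter
            su = CubicSpline(fx, fit, bc_type="natural")(xu)
        except Exception:
            for jd in range(d):
                coef = np.polyfit(fx, fy[:, jd], 1, w=fw)
                su[:, jd] = np.polyval(coef, xu)
    elif fx.size >= 2:
        for jd in range(d):
            coef = np.polyfit(fx, fy[:, jd], 1, w=fw)
            su[:, jd] = np.polyval(coef, xu)
    else:
        su = yu.copy()
    return su[inv]


def _polyline_from(lam: np.ndarray, smoothed: np.ndarray) -> np.ndarray:
    """Curve vertices: smoothed positions in parameter order, deduplicated."""
    order = np.argsort(lam, kind="stable")
    verts = smoothed[order]
    keep = np.ones(len(verts), dtype=bool)
    if len(verts) > 1:
        keep[1:] = np.any(np.diff(verts, axis=0) != 0, axis=1)
    verts = verts[keep]
    if verts.shape[0] == 0:
        verts = smoothed[:1]
    return verts


def _line_fit(points: np.ndarray, initial_order: np.ndarray):
    """Straight-segment fallback: first principal component line."""
    mu = points.mean(axis=0)
    c = points - mu
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    u = vt[0]
    t = c @ u
    if np.std(initial_order) > 0 and np.corrcoef(t, initial_order)[0, 1] < 0:
        u, t = -u, -t
    pt = t - t.min()
    curve = np.vstack([mu + t.min() * u, mu + t.max() * u])
    resid = c - np.outer(t, u)
    return curve, pt, np.linalg.norm(resid, axis=1)


def fit_principal_curve(
    points: np.ndarray,
    initial_order: np.ndarray,
    max_iter: int = 15,
    tol: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal curve through points, parameterized from the root end.

    Returns (curve vertices, per-point arc-length pseudotime, per-point
    orthogonal distance).  The total squared orthogonal distance is
    non-increasing across iterations: an iteration that would increase it
    is rejected and the fit stops there.
    """
    points = np.asarray(points, dtype=float)
    initial_order = np.asarray(initial_order, dtype=float)
    n, d = points.shape
    if np.allclose(points, points[0]):
        return points[:1].copy(), np.zeros(n), np.zeros(n)
    if n < 2 * d:
        return _line_fit(points, initial_order)
    lam = initial_order.copy()
    best = None
    total_prev = np.inf
    for _ in range(max_iter):
        smoothed = _smooth_against(lam, points)
        verts = _polyline_from(lam, smoothed)
        lam_new, sq = _project_polyline(points, verts)
        total = float(sq.sum())
        if total > total_prev * (1 + 1e-12):
            break
        best = (verts, lam_new, np.sqrt(sq))
        if total_prev < np.inf and abs(total_prev - total) <= tol * max(total, 1e-30):
            break
        total_prev = total
        lam = lam_new
    if best is None:  # first iteration already rejected (cannot happen: prev=inf)
        smoothed = _smooth_against(lam, points)
        verts = _polyline_from(lam, smoothed)
        lam_new, sq = _project_polyline(points, verts)
        best = (verts, lam_new, np.sqrt(sq))
    return best


def _milestone_ids(k: int) -> list[str]:
    return [f"M{c}" for c in range(1, k + 1)]


def fit_simultaneous_curves(
    embedding: Embedding,
    clustering: Clustering,
    mst: MilestoneGraph,
    root: int | None = None,
    max_iter: int = 15,
    tol: float = 1e-3,
    root_mode: str = "max_shared",
    seed: int | None = None,
) -> Trajectory:
    """Fit one principal curve per lineage and assemble a directed trajectory."""
    if not mst.is_tree:
        raise ValueError("simultaneous curve fitting requires a tree MST")
    if mst.n_vertices != clustering.k:
        raise ValueError("MST vertices must match clustering clusters")
    if root is None:
        root = choose_root(mst, mode=root_mode, seed=seed)
    x = embedding.coords
    labels = clustering.labels
    k = clustering.k
    n = x.shape[0]
    paths = lineages_from_mst(mst, root)
    nl = len(paths)
    centroids = np.vstack([x[labels == c].mean(axis=0) for c in range(1, k + 1)])

    member = np.zeros((n, nl), dtype=bool)
    for li, path in enumerate(paths):
        member[:, li] = np.isin(labels, path)

    lam = np.full((n, nl), np.nan)
    dist = np.full((n, nl), np.nan)
    for li, path in enumerate(paths):
        verts = centroids[np.asarray(path) - 1]
        idx = member[:, li]
        lam[idx, li], sq = _project_polyline(x[idx], verts)
        dist[idx, li] = np.sqrt(sq)

    curves: list[np.ndarray] = [centroids[np.asarray(p) - 1] for p in paths]
    if k == 2:
        # one lineage, two clusters: the curve is the straight centroid
        # segment and pseudotime the (unclipped) projection coordinate
        u = centroids[paths[0][1] - 1] - centroids[paths[0][0] - 1]
        u = u / np.linalg.norm(u)
        proj = (x - centroids[paths[0][0] - 1]) @ u
        lam[:, 0] = proj - proj.min()
        resid = (x - centroids[paths[0][0] - 1]) - np.outer(proj, u)
        dist[:, 0] = np.linalg.norm(resid, axis=1)
    else:
        shared = member.sum(axis=1) > 1
        total_prev = np.inf
        state = None
        for _ in range(max_iter):
            smoothed = np.zeros((n, x.shape[1]))
            for li in range(nl):
                idx = member[:, li]
                smoothed[idx] += _smooth_against(lam[idx, li], x[idx])
            smoothed /= member.sum(axis=1)[:, None]
            lam_new = np.full((n, nl), np.nan)
            dist_new = np.full((n, nl), np.nan)
            new_curves = []
            total = 0.0
            for li in range(nl):
                idx = member[:, li]
                verts = _polyline_from(lam[idx, li], smoothed[idx])
                lam_new[idx, li], sq = _project_polyline(x[idx], verts)
                dist_new[idx, li] = np.sqrt(sq)
                new_curves.append(verts)
                total += float(sq.sum())
            # shared cells: one pseudotime across lineages (stem agreement)
            masked = np.where(member, lam_new, np.nan)
            shared_mean = np.full(n, np.nan)
            shared_mean[shared] = np.nanmean(masked[shared], axis=1)
            for li in range(nl):
                sel = shared & member[:, li]
                lam_new[sel, li] = shared_mean[sel]
            if total > total_prev * (1 + 1e-12):
                break
            state = (lam_new, dist_new, new_curves)
            if total_prev < np.inf and abs(total_prev - total) <= tol * max(total, 1e-30):
                lam, dist, curves = state
                break
            total_prev = total
            lam, dist, curves = lam_new, dist_new, new_curves
        if state is not None:
            lam, dist, curves = state

    lam = np.where(member, lam, np.nan)
    milestone_ids = _milestone_ids(k)

    # milestone pseudotime: mean cell pseudotime per cluster, averaged over lineages
    mpt = np.zeros(k)
    for c in range(1, k + 1):
        vals = []
        for li, path in enumerate(paths):
            if c in path:
                sel = (labels == c) & member[:, li]
                if sel.any():
                    vals.append(float(np.nanmean(lam[sel, li])))
        mpt[c - 1] = np.mean(vals) if vals else 0.0
    mpt -= mpt[root - 1]

    g = mst.to_networkx()
    network: list[tuple[str, str, float]] = []
    depth = {root: 0.0}
    for parent, child in nx.bfs_edges(g, root):
        length = max(mpt[child - 1] - mpt[parent - 1], _EPS_LEN)
        depth[child] = depth[parent] + length
        network.append((f"M{parent}", f"M{child}", float(length)))

    best_lineage = np.nanargmin(np.where(member, dist, np.inf), axis=1)
    branch_assignment: list[tuple[str, str]] = []
    for i in range(n):
        li = int(best_lineage[i])
        path = paths[li]
        depths = np.array([depth[v] for v in path])
        t = lam[i, li]
        e = int(np.clip(np.searchsorted(depths[1:], t, side="left"), 0, len(path) - 2))
        branch_assignment.append((f"M{path[e]}", f"M{path[e + 1]}"))

    return Trajectory(
        milestone_ids=milestone_ids,
        network=network,
        lineages=[[f"M{v}" for v in p] for p in paths],
        cell_ids=list(embedding.cell_ids),
        pseudotime=lam,
        branch_assignment=branch_assignment,
        root=f"M{root}",
        curves=curves,
    )
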