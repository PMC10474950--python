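"""Cluster distances, MSTs, and the cell-connectivity statistic."""

import itertools

import numpy as np
import pytest

from treetop import (
    CellConnectivity,
    Clustering,
    ConnectivityVector,
    Embedding,
    MilestoneGraph,
    aggregate_connectivity,
    build_mst,
    cluster_distances,
    connectivity_vector,
    ensemble_connectivity,
    generate_ensemble,
    simulate_dataset,
    SimulationSpec,
)


def identity_cov_cluster(center: np.ndarray) -> np.ndarray:
    """Four points whose ML covariance is exactly the 2x2 identity."""
    s = np.sqrt(2.0)
    return center + np.array([[s, 0.0], [-s, 0.0], [0.0, s], [0.0, -s]])


class TestClusterDistances:
    def test_hand_computed_quadratic_form(self):
        pts = np.vstack([identity_cov_cluster(np.zeros(2)),
                         identity_cov_cluster(np.array([2.0, 0.0]))])
        emb = Embedding(pts, [f"c{i}" for i in range(8)])
        cl = Clustering(labels=np.repeat([1, 2], 4), k=2, seed=0)
        d = cluster_distances(emb, cl)
        # (2,0) (2I)^-1 (2,0)^T = 2  ->  d = sqrt(2)
        assert d[0, 1] == pytest.approx(np.sqrt(2.0), rel=1e-12)
        assert d[0, 0] == 0 and d[1, 1] == 0

    def test_coincident_clusters_have_zero_distance(self):
        pts = np.vstack([identity_cov_cluster(np.zeros(2))] * 2)
        emb = Embedding(pts, [f"c{i}" for i in range(8)])
        cl = Clustering(labels=np.repeat([1, 2], 4), k=2, seed=0)
        assert cluster_distances(emb, cl)[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_affine_invariance_under_global_scaling(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(4, 2, (30, 3))])
        ids = [f"c{i}" for i in range(60)]
        cl = Clustering(labels=np.repeat([1, 2], 30), k=2, seed=0)
        d1 = cluster_distances(Embedding(pts, ids), cl)
        d2 = cluster_distances(Embedding(pts * 7.5, ids), cl)
        np.testing.assert_allclose(d1, d2, rtol=1e-9)


def spanning_trees_brute_force(dist: np.ndarray) -> float:
    """Minimum total weight over all labeled spanning trees (Pruefer enumeration)."""
    n = dist.shape[0]
    if n == 2:
        return dist[0, 1]
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        # decode the Pruefer sequence into tree edges
        degree = [1] * n
        for v in seq:
            degree[v] += 1
        seq_list = list(seq)
        total = 0.0
        deg = degree[:]
        import heapq
        leaves = [v for v in range(n) if deg[v] == 1]
        heapq.heapify(leaves)
        for v in seq_list:
            leaf = heapq.heappop(leaves)
            total += dist[leaf, v]
            deg[v] -= 1
            if deg[v] == 1:
                heapq.heappush(leaves, v)
        u, w = heapq.heappop(leaves), heapq.heappop(leaves)
        total += dist[u, w]
        best = min(best, total)
    return best


class TestMST:
    def test_forced_triangle(self):
        d = np.array([[0.0, 1, 3], [1, 0, 2], [3, 2, 0]])
        mst = build_mst(d)
        assert sorted(w for _, _, w in mst.edges) == [1, 2]
        assert mst.is_tree

    @pytest.mark.parametrize("n,seed", [(4, s) for s in range(8)] + [(5, s) for s in range(6)])
    def test_matches_spanning_tree_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        d = np.abs(rng.normal(size=(n, n)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        mst = build_mst(d)
        total = sum(w for _, _, w in mst.edges)
        assert total == pytest.approx(spanning_trees_brute_force(d), rel=1e-12)

    def test_two_vertices_single_edge(self):
        mst = build_mst(np.array([[0.0, 2.5], [2.5, 0.0]]))
        assert mst.edges == [(1, 2, 2.5)]
        assert list(mst.degrees) == [1, 1]

    def test_non_finite_rejected(self):
        d = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            build_mst(d)


class TestConnectivityVector:
    def path_mst(self, k):
        return MilestoneGraph(k, [(i, i + 1, 1.0) for i in range(1, k)], is_tree=True)

    def test_path_of_three_clusters(self):
        mst = self.path_mst(3)
        cl = Clustering(labels=np.array([1, 1, 2, 2, 3, 3]), k=3, seed=0)
        vec = connectivity_vector(mst, cl)
        # raw (1/3, 2/3, 1/3) -> scaled (0.5, 1, 0.5)
        np.testing.assert_allclose(vec.values, [0.5, 0.5, 1, 1, 0.5, 0.5])

    def test_star_of_five(self):
        edges = [(1, j, 1.0) for j in range(2, 6)]
        mst = MilestoneGraph(5, edges, is_tree=True)
        cl = Clustering(labels=np.arange(1, 6), k=5, seed=0)
        vec = connectivity_vector(mst, cl)
        np.testing.assert_allclose(vec.values, [1.0, 0.25, 0.25, 0.25, 0.25])

    def test_two_clusters_constant_one(self):
        mst = self.path_mst(2)
        cl = Clustering(labels=np.array([1, 2, 1, 2]), k=2, seed=0)
        np.testing.assert_array_equal(connectivity_vector(mst, cl).values, 1.0)

    def test_vertex_count_mismatch_rejected(self):
        cl = Clustering(labels=np.array([1, 2]), k=2, seed=0)
        with pytest.raises(ValueError, match="vertices"):
            connectivity_vector(self.path_mst(3), cl)


class TestAggregate:
    def test_single_vector_is_identity(self):
        v = ConnectivityVector(values=np.array([0.5, 1.0, 0.25]), source=0)
        np.testing.assert_array_equal(aggregate_connectivity([v]).values, v.values)

    def test_mean_of_two(self):
        a = ConnectivityVector(values=np.array([1.0, 1.0]), source=0)
        b = ConnectivityVector(values=np.array([0.5, 1.0]), source=1)
        np.testing.assert_allclose(aggregate_connectivity([a, b]).values, [0.75, 1.0])

    def test_all_k2_members_give_constant_one(self):
        vs = [ConnectivityVector(values=np.ones(4), source=i) for i in range(3)]
        np.testing.assert_array_equal(aggregate_connectivity(vs).values, 1.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            aggregate_connectivity([])

    def test_order_invariance(self, four_blobs):
        ens = generate_ensemble(four_blobs, L=12, k_range=(3, 6), seed=0)
        _, _, vectors = ensemble_connectivity(four_blobs, ens)
        fwd = aggregate_connectivity(vectors).values
        rev = aggregate_connectivity(vectors[::-1]).values
        np.testing.assert_allclose(fwd, rev, rtol=1e-12)


class TestEnsembleConnectivityProperties:
    def test_degree_sum_and_mean_connectivity_identity(self, four_blobs):
        """Sum of MST degrees is 2(k-1), so mean raw connectivity is 2(k-1)/k^2."""
        ens = generate_ensemble(four_blobs, L=20, k_range=(3, 6), seed=2)
        _, msts, _ = ensemble_connectivity(four_blobs, ens)
        for m, mst in zip(ens.members, msts):
            assert mst.degrees.sum() == 2 * (m.k - 1)
            raw = mst.degrees / m.k
            assert raw.mean() == pytest.approx(2 * (m.k - 1) / m.k**2)

    def test_linear_topology_interior_exceeds_extremes(self):
        """Connectivity is lower near the leaves of a linear trajectory."""
        wins = 0
        for seed in range(20):
            spec = SimulationSpec(topology="linear", n_milestones=4, n_cells=200,
                                  dims=5, noise_sd=0.05, seed=seed)
            emb, truth, _ = simulate_dataset(spec)
            ens = generate_ensemble(emb, L=60, k_range=(3, 6), seed=seed)
            conn, _, _ = ensemble_connectivity(emb, ens)
            pt = np.array([r[np.isfinite(r)][0] for r in truth.pseudotime])
            lo, hi = np.quantile(pt, [0.1, 0.9])
            extreme = (pt <= lo) | (pt >= hi)
            if conn.values[~extreme].mean() > conn.values[extreme].mean():
                wins += 1
        assert wins >= 19

    def test_bifurcation_branch_cells_exceed_leaf_cells(self):
        """Cells near the branching milestone average higher connectivity than leaf cells."""
        for seed in (0, 1, 2):
            spec = SimulationSpec(topology="bifurcation", n_milestones=5, n_cells=250,
                                  dims=5, noise_sd=0.05, seed=seed)
            emb, truth, net = simulate_dataset(spec)
            ens = generate_ensemble(emb, L=60, k_range=(3, 6), seed=seed)
            conn, _, _ = ensemble_connectivity(emb, ens)
            g = truth.to_networkx()
            deg = dict(g.degree)
            branch_idx = [i for i, m in enumerate(truth.milestone_ids) if deg[m] >= 3]
            leaf_idx = [i for i, m in enumerate(truth.milestone_ids)
                        if deg[m] == 1 and m != truth.root]
            d2m = np.linalg.norm(
                emb.coords[:, None, :] - net.coords[None, :, :], axis=2
            )
            nearest = d2m.argmin(axis=1)
            near_branch = np.isin(nearest, branch_idx)
            near_leaf = np.isin(nearest, leaf_idx)
            assert conn.values[near_branch].mean() > conn.values[near_leaf].mean()

    def test_cell_connectivity_bounds(self, four_blobs):
        ens = generate_ensemble(four_blobs, L=25, k_range=(3, 6), seed=3)
        conn, _, vectors = ensemble_connectivity(four_blobs, ens)
        for v in vectors:
            assert v.values.max() == 1.0
            assert v.values.min() > 0
        assert 0 < conn.values.min() and conn.values.max() <= 1.0
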