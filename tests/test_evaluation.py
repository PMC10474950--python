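"""Trajectory-comparison metrics: geodesics, HIM, F1 branches, overall score."""

import networkx as nx
import numpy as np
import pytest

from treetop import (
    cor_distances,
    f1_branches,
    geodesic_distances,
    him_similarity,
    overall_score,
    simulate_dataset,
    SimulationSpec,
)
from conftest import make_branch_trajectory, make_linear_trajectory, make_y_trajectory


class TestGeodesics:
    def test_same_edge_distance_is_progression_gap(self):
        traj = make_linear_trajectory(n_cells=4, length=2.0)
        d = geodesic_distances(traj)
        pt = traj.pseudotime[:, 0]
        np.testing.assert_allclose(d, np.abs(pt[:, None] - pt[None, :]), atol=1e-12)

    def test_y_distances_sum_partial_edges(self):
        traj = make_y_trajectory(per_edge=1)  # one cell mid-way on each unit edge
        d = geodesic_distances(traj)
        ids = traj.cell_ids
        # cells mid-edge on the two branch edges: 0.5 + 0.5 through M2
        i, j = ids.index("c1_0"), ids.index("c2_0")
        assert d[i, j] == pytest.approx(1.0)
        # stem cell at 0.5 on (M1, M2) to a branch cell at 0.5 past M2
        s = ids.index("c0_0")
        assert d[s, i] == pytest.approx(0.5 + 0.5)

    def test_self_distance_zero_and_symmetry(self):
        traj = make_y_trajectory()
        d = geodesic_distances(traj)
        assert np.all(np.diag(d) == 0)
        np.testing.assert_allclose(d, d.T)

    def test_tree_triangle_inequality(self):
        _, truth, _ = simulate_dataset(SimulationSpec(topology="tree", n_milestones=6,
                                                      n_cells=40, seed=3))
        d = geodesic_distances(truth)
        n = d.shape[0]
        rng = np.random.default_rng(0)
        for _ in range(200):
            i, j, k = rng.integers(0, n, 3)
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestCorDistances:
    def test_identity_scores_one(self):
        traj = make_y_trajectory()
        assert cor_distances(traj, traj) == pytest.approx(1.0)

    def test_reversed_linear_trajectory_still_one(self):
        # irregular spacing so no pairwise distances tie by coincidence
        import treetop
        rng = np.random.default_rng(0)
        pt = np.sort(rng.uniform(0.05, 1.95, 8))[:, None]
        fwd = treetop.Trajectory(
            milestone_ids=["M1", "M2"], network=[("M1", "M2", 2.0)],
            lineages=[["M1", "M2"]], cell_ids=[f"c{i}" for i in range(8)],
            pseudotime=pt, branch_assignment=[("M1", "M2")] * 8, root="M1",
        )
        rev = treetop.Trajectory(
            milestone_ids=["M2", "M1"], network=[("M2", "M1", 2.0)],
            lineages=[["M2", "M1"]], cell_ids=fwd.cell_ids, pseudotime=2.0 - pt,
            branch_assignment=[("M2", "M1")] * 8, root="M2",
        )
        assert cor_distances(fwd, rev) == pytest.approx(1.0)

    def test_permuted_positions_decorrelate(self):
        _, truth, _ = simulate_dataset(SimulationSpec(topology="bifurcation",
                                                      n_milestones=5, n_cells=100, seed=1))
        import treetop
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            perm = rng.permutation(truth.n_cells)
            pred = treetop.Trajectory(
                milestone_ids=truth.milestone_ids, network=truth.network,
                lineages=truth.lineages, cell_ids=truth.cell_ids,
                pseudotime=truth.pseudotime[perm],
                branch_assignment=[truth.branch_assignment[i] for i in perm],
                root=truth.root,
            )
            vals.append(cor_distances(truth, pred))
        assert np.mean(vals) < 0.15

    def test_too_few_cells_rejected(self):
        import treetop
        t = treetop.Trajectory(
            milestone_ids=["M1", "M2"], network=[("M1", "M2", 1.0)],
            lineages=[["M1", "M2"]], cell_ids=["a", "b"],
            pseudotime=np.array([[0.2], [0.8]]),
            branch_assignment=[("M1", "M2")] * 2, root="M1",
        )
        with pytest.raises(ValueError, match="3 cells"):
            cor_distances(t, t)


class TestHIM:
    def test_identical_paths_score_one(self):
        p4 = nx.path_graph(4)
        assert him_similarity(p4, p4) == 1.0
        assert him_similarity(p4, p4, simplify=False, canonicalize=False) == 1.0

    def test_empty_vs_complete_calibrates_to_zero(self):
        empty = nx.empty_graph(5)
        complete = nx.complete_graph(5)
        assert him_similarity(empty, complete) == pytest.approx(0.0, abs=1e-6)

    def test_linear_chains_of_any_length_are_equivalent(self):
        # the defining property of the topology comparison
        assert him_similarity(nx.path_graph(3), nx.path_graph(9)) == 1.0
        # raw adjacency comparison keeps the size difference visible
        assert him_similarity(nx.path_graph(3), nx.path_graph(9), simplify=False) < 1.0

    def test_isomorphic_trees_with_permuted_labels_score_one(self):
        g = nx.random_labeled_tree(7, seed=2)
        mapping = dict(zip(g.nodes, np.random.default_rng(0).permutation(list(g.nodes))))
        h = nx.relabel_nodes(g, {k: int(v) for k, v in mapping.items()})
        assert him_similarity(g, h) == 1.0

    def test_star_vs_path_is_imperfect(self):
        assert him_similarity(nx.star_graph(4), nx.path_graph(5)) < 1.0

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            him_similarity(nx.Graph(), nx.path_graph(3))

    def test_works_on_trajectories(self):
        traj = make_y_trajectory()
        assert him_similarity(traj, traj) == 1.0


class TestF1Branches:
    def test_identical_assignments_score_one(self):
        traj = make_y_trajectory()
        assert f1_branches(traj, traj) == pytest.approx(1.0)

    def test_lumped_branches_score_half(self):
        cells = [f"c{i}" for i in range(100)]
        truth = make_branch_trajectory([cells[:50], cells[50:]])
        pred = make_branch_trajectory([cells])
        assert f1_branches(truth, pred) == pytest.approx(0.5)

    def test_half_split_branches(self):
        # each 25-cell predicted branch has Jaccard 25/50 against its truth
        # branch, so recovery = relevance = 0.5 and F1 = 0.5
        cells = [f"c{i}" for i in range(100)]
        truth = make_branch_trajectory([cells[:50], cells[50:]])
        pred = make_branch_trajectory([cells[:25], cells[25:50], cells[50:75], cells[75:]])
        assert f1_branches(truth, pred) == pytest.approx(0.5)

    def test_symmetric_in_its_arguments(self):
        cells = [f"c{i}" for i in range(60)]
        rng = np.random.default_rng(5)
        cut1 = sorted(rng.choice(np.arange(1, 59), 2, replace=False))
        a = make_branch_trajectory([cells[:cut1[0]], cells[cut1[0]:cut1[1]], cells[cut1[1]:]])
        b = make_branch_trajectory([cells[:20], cells[20:40], cells[40:]])
        assert f1_branches(a, b) == pytest.approx(f1_branches(b, a))

    def test_cell_set_mismatch_rejected(self):
        a = make_branch_trajectory([["x", "y", "z"]])
        b = make_branch_trajectory([["x", "y", "w"]])
        with pytest.raises(ValueError, match="same cells"):
            f1_branches(a, b)


class TestOverallScore:
    def test_perfect_metrics_score_one(self):
        assert overall_score(1.0, 1.0, 1.0) == 1.0

    def test_any_zero_collapses_the_score(self):
        assert overall_score(1.0, 0.0, 1.0) == 0.0

    def test_hand_computed_geometric_mean(self):
        assert overall_score(1.0, 1.0, 0.25) == pytest.approx(0.25 ** (1 / 3))

    def test_four_metric_variant(self):
        assert overall_score(1.0, 1.0, 1.0, featureimp=0.5) == pytest.approx(0.5 ** 0.25)

    def test_negative_metric_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            overall_score(-0.1, 1.0, 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_bounded_by_min_and_max_inputs(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.01, 1.0, 3)
        s = overall_score(*vals)
        assert min(vals) - 1e-12 <= s <= max(vals) + 1e-12
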