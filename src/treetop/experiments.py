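"""Scripted experiments over synthetic data.

Two protocols, both fully seeded:

* ``selection_comparison`` — rank one clustering ensemble per dataset with
  several criteria (connectivity-guided VRC, ASW, plain VRC, random),
  smooth the top-n members of each into trajectories, score them against
  ground truth, and report the mean and best overall score per criterion.
* ``robustness_experiment`` — repeat end-to-end inference across master
  seeds for increasing ensemble sizes L and report the spread of the
  overall score, which should tighten as the connectivity average
  stabilizes.

Both give each method the dataset's start cell (the cell with minimal
ground-truth pseudotime) as the root hint, mirroring how benchmark
frameworks pass the start milestone to every method.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cluster import generate_ensemble
from .connectivity import ensemble_connectivity
from .evaluation import evaluate_trajectory
from .pipeline import trajectory_for_member
from .selection import asw_rank, connectivity_rank, plain_vrc_rank, random_rank, select_top
from .synthetic import SimulationSpec, simulate_dataset
from .types import Trajectory

logger = logging.getLogger("treetop")

__all__ = ["default_datasets", "selection_comparison", "robustness_experiment"]

_TOPOLOGY_CYCLE = [
    ("linear", 4),
    ("bifurcation", 5),
    ("multifurcation", 6),
    ("tree", 7),
]


def default_datasets(n_datasets: int, noise_sd: float = 0.1, n_cells: int = 300,
                     dims: int = 5, seed: int = 0) -> list[SimulationSpec]:
    """Mixed-topology dataset specs cycling through the topology taxonomy."""
    specs = []
    for i in range(n_datasets):
        topo, m = _TOPOLOGY_CYCLE[i % len(_TOPOLOGY_CYCLE)]
        specs.append(SimulationSpec(topology=topo, n_milestones=m, n_cells=n_cells,
                                    dims=dims, noise_sd=noise_sd, seed=seed + i))
    return specs


def _start_cell(truth: Trajectory) -> int:
    pt = np.where(np.isfinite(truth.pseudotime), truth.pseudotime, np.inf)
    return int(np.argmin(pt.min(axis=1)))


def selection_comparison(
    n_datasets: int = 10,
    L: int = 300,
    k_range: tuple[int, int] = (3, 8),
    n_top: int = 10,
    noise_sd: float = 0.1,
    seed: int = 0,
    criteria: tuple[str, ...] = ("connectivity", "asw", "vrc", "random"),
) -> pd.DataFrame:
    """Per-dataset mean and best overall score of each criterion's top-n members.

    Returns one row per (dataset, criterion) with columns ``mean_overall``
    and ``best_overall`` over the criterion's top-n trajectories.
    """
    rows = []
    for di, spec in enumerate(default_datasets(n_datasets, noise_sd=noise_sd, seed=seed)):
        emb, truth, _ = simulate_dataset(spec)
        start = _start_cell(truth)
        ens = generate_ensemble(emb, L=L, k_range=k_range, seed=spec.seed)
        conn, msts, _ = ensemble_connectivity(emb, ens)
        rankings = {}
        for crit in criteria:
            if crit == "connectivity":
                rankings[crit] = connectivity_rank(ens, conn)
            elif crit == "asw":
                rankings[crit] = asw_rank(ens, emb)
            elif crit == "vrc":
                rankings[crit] = plain_vrc_rank(ens, emb)
            elif crit == "random":
                rankings[crit] = random_rank(ens, seed=spec.seed)
            else:
                raise ValueError(f"unknown criterion {crit!r}")
        needed = sorted({j for r in rankings.values() for j in select_top(r, n_top)})
        scores: dict[int, float] = {}
        for j in needed:
            traj = trajectory_for_member(emb, ens.members[j], msts[j], start_cell=start)
            scores[j] = evaluate_trajectory(truth, traj)["overall3"]
        for crit, ranking in rankings.items():
            top = [scores[j] for j in select_top(ranking, n_top)]
            rows.append({
                "dataset": di, "topology": spec.topology, "criterion": crit,
                "mean_overall": float(np.mean(top)), "best_overall": float(np.max(top)),
            })
        logger.info("selection_comparison: dataset %d (%s) done", di, spec.topology)
    return pd.DataFrame(rows)


def robustness_experiment(
    n_datasets: int = 3,
    L_values: tuple[int, ...] = (100, 500, 2500),
    n_seeds: int = 10,
    k_range: tuple[int, int] = (3, 8),
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Spread of the top-ranked trajectory's overall score across master seeds.

    Returns one row per (dataset, L) with the mean and standard deviation
    of overall3 over ``n_seeds`` repeated runs.
    """
    rows = []
    for di, spec in enumerate(default_datasets(n_datasets, noise_sd=noise_sd, seed=seed)):
        emb, truth, _ = simulate_dataset(spec)
        start = _start_cell(truth)
        for L in L_values:
            vals = []
            for rep in range(n_seeds):
                master = 10_000 * (di + 1) + 100 * L + rep + seed
                ens = generate_ensemble(emb, L=L, k_range=k_range, seed=master)
                conn, msts, _ = ensemble_connectivity(emb, ens)
                best = select_top(connectivity_rank(ens, conn), 1)[0]
                traj = trajectory_for_member(emb, ens.members[best], msts[best],
                                             start_cell=start)
                vals.append(evaluate_trajectory(truth, traj)["overall3"])
            rows.append({
                "dataset": di, "topology": spec.topology, "L": L,
                "mean_overall": float(np.mean(vals)), "sd_overall": float(np.std(vals, ddof=1)),
            })
            logger.info("robustness: dataset %d L=%d sd=%.4f", di, L, rows[-1]["sd_overall"])
    return pd.DataFrame(rows)
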