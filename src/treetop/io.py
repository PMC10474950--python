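"""Readers and writers: expression matrices, embeddings, trajectory JSON.

The trajectory file format is a single JSON document with an explicit
``schema_version``; pseudotime is stored as a dense cell x lineage table
with ``null`` marking cells outside a lineage.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from .types import Embedding, Trajectory

SCHEMA_VERSION = 1

__all__ = [
    "read_expression",
    "read_embedding",
    "write_embedding",
    "write_trajectory",
    "read_trajectory",
]


def _validated_frame(values: np.ndarray, cells: list[str], genes: list[str]) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    if values.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix shape {values.shape} does not match {len(cells)} cell "
            f"and {len(genes)} gene names"
        )
    for what, names in (("cell", cells), ("gene", genes)):
        dup = pd.Index(names)[pd.Index(names).duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate {what} names: {dup}")
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"non-finite expression value at cell {cells[i]!r}, gene {genes[j]!r}")
    return pd.DataFrame(values, index=list(cells), columns=list(genes))


def read_expression(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a cell x gene expression matrix (MatrixMarket or delimited text).

    MTX files must be MatrixMarket coordinate format with companion plain-text
    name files ``<stem>.rows.txt`` (cell ids, one per line) and
    ``<stem>.cols.txt`` (gene names).  CSV/TSV files carry a header row of
    gene names and a first column of cell ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mtx" if path.suffix.lower() == ".mtx" else "csv"
    if format == "mtx":
        mat = mmread(path)
        mat = mat.toarray() if hasattr(mat, "toarray") else np.asarray(mat)
        rows = Path(str(path.with_suffix("")) + ".rows.txt")
        cols = Path(str(path.with_suffix("")) + ".cols.txt")
        for p in (rows, cols):
            if not p.exists():
                raise FileNotFoundError(f"companion name file {p} not found")
        cells = rows.read_text().split()
        genes = cols.read_text().split()
        return _validated_frame(np.asarray(mat, dtype=float), cells, genes)
    if format == "csv":
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        return _validated_frame(df.to_numpy(dtype=float), df.index.astype(str).tolist(),
                                df.columns.astype(str).tolist())
    raise ValueError(f"unknown expression format {format!r}")


def write_embedding(emb: Embedding, path: str | Path) -> None:
    """Write an embedding as CSV with header ``cell_id,dim1..dimd``."""
    df = pd.DataFrame(
        emb.coords,
        index=pd.Index(emb.cell_ids, name="cell_id"),
        columns=[f"dim{i + 1}" for i in range(emb.n_dims)],
    )
    df.to_csv(path)


def read_embedding(path: str | Path) -> Embedding:
    df = pd.read_csv(path, index_col=0)
    return Embedding(df.to_numpy(dtype=float), df.index.astype(str).tolist())


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Serialize a trajectory to JSON (invariants are re-validated first)."""
    # reconstructing re-runs every Trajectory invariant, incl. the tree check
    Trajectory(
        milestone_ids=traj.milestone_ids,
        network=traj.network,
        lineages=traj.lineages,
        cell_ids=traj.cell_ids,
        pseudotime=traj.pseudotime,
        branch_assignment=traj.branch_assignment,
        root=traj.root,
        curves=traj.curves,
    )
    pt = [[None if not np.isfinite(v) else float(v) for v in row] for row in traj.pseudotime]
    doc = {
        "schema_version": SCHEMA_VERSION,
        "milestone_ids": traj.milestone_ids,
        "root": traj.root,
        "network": [[a, b, w] for a, b, w in traj.network],
        "lineages": traj.lineages,
        "cell_ids": traj.cell_ids,
        "pseudotime": pt,
        "branch_assignment": [[a, b] for a, b in traj.branch_assignment],
        "curves": None if traj.curves is None else [c.tolist() for c in traj.curves],
    }
    Path(path).write_text(json.dumps(doc))


def read_trajectory(path: str | Path) -> Trajectory:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported trajectory schema_version {doc.get('schema_version')!r}; "
            f"expected {SCHEMA_VERSION}"
        )
    required = {"milestone_ids", "root", "network", "lineages", "cell_ids",
                "pseudotime", "branch_assignment"}
    missing = required - doc.keys()
    if missing:
        raise ValueError(f"trajectory file missing fields: {sorted(missing)}")
    pt = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in doc["pseudotime"]],
        dtype=float,
    ).reshape(len(doc["cell_ids"]), len(doc["lineages"]))
    curves = doc.get("curves")
    return Trajectory(
        milestone_ids=doc["milestone_ids"],
        network=[(a, b, float(w)) for a, b, w in doc["network"]],
        lineages=[list(p) for p in doc["lineages"]],
        cell_ids=doc["cell_ids"],
        pseudotime=pt,
        branch_assignment=[(a, b) for a, b in doc["branch_assignment"]],
        root=doc["root"],
        curves=None if curves is None else [np.asarray(c, dtype=float) for c in curves],
    )
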