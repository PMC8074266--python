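"""Reading and writing adjacency-matrix data sets.

Three interchangeable formats:

* a single ``.npz`` archive holding the stacked dense matrices, the shared
  observation mask and a JSON metadata string (lossless round trip);
* a directory of per-subject edge-list TSV files (``node_i  node_j  weight``,
  0-based, undirected, each unordered pair listed once, no diagonal);
* a directory of per-subject dense CSV matrices.

Symmetry is validated on read; inconsistent duplicate pairs and subjects
with differing node counts are rejected.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np

from .model import AdjacencyDataset

__all__ = ["read_dataset", "write_dataset"]

_ASYM_TOL = 1e-6


def write_dataset(
    dataset: AdjacencyDataset,
    path: str | Path,
    fmt: str | None = None,
    metadata: dict | None = None,
) -> None:
    """Write a data set; format from ``fmt`` or inferred from the path.

    ``fmt`` is one of ``npz`` (archive), ``tsv`` (edge-list directory) or
    ``csv`` (dense-matrix directory).
    """
    path = Path(path)
    if fmt is None:
        fmt = "npz" if path.suffix == ".npz" else "tsv"
    if fmt == "npz":
        np.savez(
            path,
            matrices=dataset.matrices,
            observed=dataset.observed,
            meta=json.dumps(metadata or {}),
        )
        return
    path.mkdir(parents=True, exist_ok=True)
    n = dataset.n_nodes
    if fmt == "tsv":
        iu = np.triu_indices(n, k=1)
        for k in range(dataset.N):
            w = dataset.matrices[k][iu]
            arr = np.column_stack([iu[0], iu[1], w])
            np.savetxt(
                path / f"subject_{k:04d}.tsv",
                arr,
                fmt=["%d", "%d", "%.17g"],
                delimiter="\t",
            )
    elif fmt == "csv":
        for k in range(dataset.N):
            np.savetxt(
                path / f"subject_{k:04d}.csv",
                dataset.matrices[k],
                delimiter=",",
                fmt="%.17g",
            )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _read_edge_list(fname: Path) -> np.ndarray:
    raw = np.loadtxt(fname, delimiter="\t", ndmin=2)
    if raw.shape[1] != 3:
        raise ValueError(f"{fname}: expected 3 columns (i, j, weight)")
    ii = raw[:, 0].astype(int)
    jj = raw[:, 1].astype(int)
    ww = raw[:, 2]
    if np.any(ii == jj):
        raise ValueError(f"{fname}: diagonal entries not allowed in edge lists")
    n = int(max(ii.max(), jj.max())) + 1
    A = np.zeros((n, n))
    seen = np.zeros((n, n), dtype=bool)
    lo = np.minimum(ii, jj)
    hi = np.maximum(ii, jj)
    for a, b, w in zip(lo, hi, ww):
        if seen[a, b] and A[a, b] != w:
            raise ValueError(
                f"{fname}: pair ({a}, {b}) listed twice with inconsistent weights"
            )
        seen[a, b] = True
        A[a, b] = A[b, a] = w
    return A


def read_dataset(path: str | Path) -> AdjacencyDataset:
    """Read a data set from any supported format (see module docstring)."""
    path = Path(path)
    if path.is_file() and path.suffix == ".npz":
        arr = np.load(path, allow_pickle=False)
        return AdjacencyDataset(arr["matrices"], arr["observed"])
    if not path.is_dir():
        raise FileNotFoundError(f"no such data set: {path}")
    tsvs = sorted(path.glob("*.tsv"))
    csvs = sorted(path.glob("*.csv"))
    if tsvs:
        mats = [_read_edge_list(f) for f in tsvs]
    elif csvs:
        mats = []
        for f in csvs:
            A = np.loadtxt(f, delimiter=",", ndmin=2)
            if A.shape[0] != A.shape[1]:
                raise ValueError(f"{f}: matrix is not square")
            if np.max(np.abs(A - A.T)) > _ASYM_TOL:
                raise ValueError(f"{f}: matrix is not symmetric")
            mats.append(A)
    else:
        raise ValueError(f"{path}: no .tsv or .csv files found")
    sizes = {m.shape[0] for m in mats}
    if len(sizes) != 1:
        raise ValueError(f"inconsistent node counts across subjects: {sizes}")
    return AdjacencyDataset(np.stack(mats))
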