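"""Plain-text readers and writers for matrices, networks, and partitions.

Formats: delimited text matrices (rows = series/vertices), TSV edge lists
with a header naming the orientation convention, two-column partition TSVs
(vertex_id, module_id), and JSON metadata sidecars.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_edge_list",
    "read_edge_list",
    "write_partition",
    "read_partition",
    "write_metadata",
    "read_metadata",
]

_EDGE_HEADER = (
    "# directed edge list (source\ttarget); in the dense adjacency "
    "convention entry (i, j) = 1 means edge j -> i (row = target)\n"
)


def write_matrix(path, M: np.ndarray, delimiter: str = "\t") -> None:
    np.savetxt(path, np.asarray(M), fmt="%.12g", delimiter=delimiter)


def read_matrix(path, delimiter: str = "\t") -> np.ndarray:
    """Read a delimited text matrix, reporting the offending line on error."""
    try:
        return np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as err:
        raise ValueError(f"malformed matrix file {path}: {err}") from err


def write_edge_list(path, adj: np.ndarray) -> None:
    adj = np.asarray(getattr(adj, "adjacency", adj))
    targets, sources = np.nonzero(adj)
    with open(path, "w") as fh:
        fh.write(_EDGE_HEADER)
        fh.write("source\ttarget\n")
        for s, t in zip(sources, targets):
            fh.write(f"{s}\t{t}\n")


def read_edge_list(path, n_vertices: int | None = None) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns) != ["source", "target"]:
        raise ValueError(
            f"malformed edge list {path}: expected columns source, target, "
            f"got {list(df.columns)}"
        )
    if n_vertices is None:
        n_vertices = int(max(df["source"].max(), df["target"].max())) + 1
    adj = np.zeros((n_vertices, n_vertices), dtype=np.int8)
    adj[df["target"].to_numpy(), df["source"].to_numpy()] = 1
    return adj


def write_partition(path, labels: np.ndarray) -> None:
    labels = np.asarray(getattr(labels, "labels", labels))
    with open(path, "w") as fh:
        fh.write("vertex_id\tmodule_id\n")
        for v, m in enumerate(labels):
            fh.write(f"{v}\t{m}\n")


def read_partition(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["vertex_id", "module_id"]:
        raise ValueError(f"malformed partition file {path}")
    return df.sort_values("vertex_id")["module_id"].to_numpy()


def write_metadata(path, meta: dict) -> None:
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_metadata(path) -> dict:
    return json.loads(Path(path).read_text())
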