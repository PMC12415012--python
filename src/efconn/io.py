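"""Reading subject correlation matrices and writing group graphs.

A subject connectome is a symmetric ROI×ROI Pearson-correlation matrix with
unit diagonal. Two file dialects are accepted: a square numeric matrix
(CSV/TSV, with or without an ROI-id header row/column) and a long format
``roi_i,roi_j,r`` listing the upper triangle.

Group graphs are undirected with integer edge weights (participant counts)
and can be exported as GraphML, an edge-list CSV, or an adjacency CSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

TASKS = ("initiation", "inhibition", "shifting", "twoback")

_TASK_ALIASES = {
    "initiation": "initiation",
    "inhibition": "inhibition",
    "shifting": "shifting",
    "twoback": "twoback",
    "2-back": "twoback",
    "2back": "twoback",
}

SYMMETRY_TOL = 1e-9


def normalize_task(task: str) -> str:
    key = task.strip().lower().replace("_", "-")
    key = _TASK_ALIASES.get(key.replace("-", ""), _TASK_ALIASES.get(key))
    if key is None:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    return key


@dataclass
class SubjectConnectome:
    """One subject's correlation matrix for one task."""

    subject_id: str
    task: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.task = normalize_task(self.task)
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(
                f"connectome {self.subject_id}/{self.task}: matrix must be "
                f"square, got shape {m.shape}")
        asym = np.max(np.abs(m - m.T)) if m.size else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(
                f"connectome {self.subject_id}/{self.task}: asymmetry "
                f"{asym:.3g} exceeds tolerance {SYMMETRY_TOL}")
        if np.max(np.abs(m)) > 1 + 1e-12:
            raise ValueError(
                f"connectome {self.subject_id}/{self.task}: correlation "
                "entries must lie in [-1, 1]")
        if not np.allclose(np.diag(m), 1.0, atol=1e-9):
            raise ValueError(
                f"connectome {self.subject_id}/{self.task}: diagonal must be 1")
        self.matrix = m

    @property
    def n_roi(self) -> int:
        return self.matrix.shape[0]


def _looks_like_ids(values) -> bool:
    try:
        ids = [float(v) for v in values]
    except (TypeError, ValueError):
        return True  # non-numeric labels
    return all(v == int(v) for v in ids) and len(set(ids)) == len(ids)


def _read_square(df: pd.DataFrame) -> np.ndarray:
    """Square dialect; tolerate an ROI-id header row and/or index column."""
    # a leading row of labels/NaN is a header
    first = df.iloc[0]
    if first.isna().any() or not all(_is_number(x) for x in first):
        df = df.iloc[1:].reset_index(drop=True)
    arr = df.to_numpy()
    if arr.shape[0] == arr.shape[1] + 1 and _looks_like_ids(arr[0]):
        arr = arr[1:]  # all-numeric id header row
    if arr.shape[1] == arr.shape[0] + 1 and _looks_like_ids(arr[:, 0]):
        arr = arr[:, 1:]  # id index column
    if arr.shape[0] != arr.shape[1]:
        raise ValueError(f"matrix file is not square: shape {arr.shape}")
    return arr.astype(float)


def read_subject_matrix(path, task: str, subject_id: str,
                        n_roi: "int | None" = None) -> SubjectConnectome:
    """Read one subject matrix, auto-detecting dialect.

    Long format requires the header ``roi_i,roi_j,r`` (upper triangle is
    sufficient); anything else is treated as a square matrix.  ``n_roi``
    sizes the matrix for long-format files (defaults to max id seen).
    """
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    header_tokens = [t.strip().lower() for t in first.strip().split(sep)]
    if header_tokens[:3] == ["roi_i", "roi_j", "r"]:
        df = pd.read_csv(path, sep=sep)
        n = int(n_roi or max(df["roi_i"].max(), df["roi_j"].max()))
        m = np.zeros((n, n))
        np.fill_diagonal(m, 1.0)
        for i, j, r in df.itertuples(index=False):
            m[int(i) - 1, int(j) - 1] = r
            m[int(j) - 1, int(i) - 1] = r
        return SubjectConnectome(subject_id, task, m)
    # square dialect: parse without assuming a header, then strip an
    # ROI-id header row / index column if present
    df = pd.read_csv(path, sep=sep, header=None)
    try:
        m = _read_square(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    return SubjectConnectome(subject_id, task, m)


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_subject_matrix(conn: SubjectConnectome, path) -> None:
    np.savetxt(path, conn.matrix, delimiter=",", fmt="%.6f")


GRAPH_FORMATS = ("graphml", "edgelist_csv", "adjacency_csv")


def write_graph(graph: nx.Graph, path, format: str = "graphml") -> None:
    """Export a group graph; integer weights and node ids survive round-trip."""
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "edgelist_csv":
        rows = [(u, v, int(d["weight"])) for u, v, d in graph.edges(data=True)]
        df = pd.DataFrame(rows, columns=["source", "target", "weight"])
        # isolated-node-free by construction, but keep the node set explicit
        # for empty graphs via a side comment line? CSV stays minimal: the
        # node set is recoverable from the edges (no isolated nodes allowed).
        df.to_csv(path, index=False)
    elif format == "adjacency_csv":
        nodes = sorted(graph.nodes)
        m = nx.to_numpy_array(graph, nodelist=nodes, weight="weight", dtype=int)
        pd.DataFrame(m, index=nodes, columns=nodes).to_csv(path)
    else:
        raise ValueError(f"unknown graph format {format!r}; "
                         f"expected one of {GRAPH_FORMATS}")


def read_graph(path, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        g = nx.read_graphml(path, node_type=int)
        out = nx.Graph()
        out.add_nodes_from(g.nodes)
        out.add_weighted_edges_from(
            (u, v, int(d["weight"])) for u, v, d in g.edges(data=True))
        out.graph.update(g.graph)
        return out
    if format == "edgelist_csv":
        df = pd.read_csv(path)
        g = nx.Graph()
        g.add_weighted_edges_from(
            (int(r.source), int(r.target), int(r.weight))
            for r in df.itertuples(index=False))
        return g
    if format == "adjacency_csv":
        df = pd.read_csv(path, index_col=0)
        nodes = [int(c) for c in df.columns]
        g = nx.Graph()
        g.add_nodes_from(nodes)
        m = df.to_numpy()
        for a in range(len(nodes)):
            for b in range(a + 1, len(nodes)):
                if m[a, b]:
                    g.add_edge(nodes[a], nodes[b], weight=int(m[a, b]))
        return g
    raise ValueError(f"unknown graph format {format!r}; "
                     f"expected one of {GRAPH_FORMATS}")
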