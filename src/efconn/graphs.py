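"""Group-graph construction from per-subject correlation matrices.

The construction has three steps, applied in order:

1. **Binarize** each subject's matrix at a high correlation threshold
   (default r > 0.75, strict): a pair is "connected" in that subject iff
   its correlation strictly exceeds the threshold. Negative correlations
   are never suprathreshold.
2. **Aggregate** across subjects: the count matrix entry (i, j) is the
   number of subjects in whom the pair was connected.
3. **Filter**: rows/columns of excluded ROIs (visual/motor networks) are
   removed; edges seen in fewer than ``min_subjects`` participants
   (default 10) are dropped; nodes left without any edge are dropped.

The result is an undirected graph whose integer edge weights count
participants — reliability weights, not correlation magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .io import SubjectConnectome

DEFAULT_R_THRESHOLD = 0.75
DEFAULT_MIN_SUBJECTS = 10


def binarize(connectome: "SubjectConnectome | np.ndarray",
             r_th: float = DEFAULT_R_THRESHOLD) -> np.ndarray:
    """Binary adjacency: 1 iff r_ij > r_th strictly and i != j."""
    if not 0 < r_th < 1:
        raise ValueError(f"r_th must lie in (0, 1), got {r_th}")
    m = connectome.matrix if isinstance(connectome, SubjectConnectome) \
        else np.asarray(connectome, dtype=float)
    b = (m > r_th)
    np.fill_diagonal(b, False)
    return b


@dataclass
class CountMatrix:
    """Cross-subject edge-frequency counts (symmetric, zero diagonal)."""

    counts: np.ndarray
    r_threshold: float
    n_subjects: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("count matrix must be square")
        if (c < 0).any() or (c > self.n_subjects).any():
            raise ValueError("counts must lie in [0, n_subjects]")
        if not (c == c.T).all():
            raise ValueError("count matrix must be symmetric")
        if np.diag(c).any():
            raise ValueError("count matrix must have zero diagonal")
        self.counts = c.astype(int)

    @property
    def n_roi(self) -> int:
        return self.counts.shape[0]


def aggregate_counts(binaries: Sequence[np.ndarray],
                     r_threshold: float = DEFAULT_R_THRESHOLD) -> CountMatrix:
    """Sum per-subject binary adjacencies into a count matrix."""
    binaries = list(binaries)
    if not binaries:
        raise ValueError("need at least one subject to aggregate")
    shape = binaries[0].shape
    for b in binaries:
        if b.shape != shape:
            raise ValueError(f"mismatched matrix sizes: {b.shape} vs {shape}")
    total = np.zeros(shape, dtype=int)
    for b in binaries:
        total += b.astype(int)
    return CountMatrix(total, r_threshold, len(binaries))


def build_group_graph(counts: CountMatrix,
                      excluded: Iterable[int] = (),
                      min_subjects: int = DEFAULT_MIN_SUBJECTS,
                      task: "str | None" = None) -> nx.Graph:
    """Build the filtered group graph from a count matrix.

    Nodes are 1-based ROI ids. Exclusion (atlas-level) precedes the
    edge-frequency filter; nodes isolated by filtering are dropped, so the
    node set lists only connected ROIs.
    """
    if min_subjects < 1:
        raise ValueError(f"min_subjects must be >= 1, got {min_subjects}")
    excluded = set(excluded)
    c = counts.counts
    g = nx.Graph(task=task, r_threshold=counts.r_threshold,
                 min_subjects=min_subjects, n_subjects=counts.n_subjects)
    rows, cols = np.nonzero(np.triu(c >= min_subjects, k=1))
    for a, b in zip(rows, cols):
        i, j = int(a) + 1, int(b) + 1
        if i in excluded or j in excluded:
            continue
        g.add_edge(i, j, weight=int(c[a, b]))
    return g


def counts_from_graph(graph: nx.Graph, n_roi: int) -> CountMatrix:
    """Re-express a group graph as a count matrix (for idempotence checks)."""
    c = np.zeros((n_roi, n_roi), dtype=int)
    for u, v, d in graph.edges(data=True):
        c[u - 1, v - 1] = c[v - 1, u - 1] = int(d["weight"])
    return CountMatrix(c, graph.graph.get("r_threshold", DEFAULT_R_THRESHOLD),
                       graph.graph.get("n_subjects", int(c.max(initial=1))))


def build_from_cohort(cohort: Sequence[SubjectConnectome],
                      excluded: Iterable[int] = (),
                      r_th: float = DEFAULT_R_THRESHOLD,
                      min_subjects: int = DEFAULT_MIN_SUBJECTS,
                      task: "str | None" = None) -> nx.Graph:
    """Convenience: binarize + aggregate + filter in one call."""
    counts = aggregate_counts([binarize(c, r_th) for c in cohort], r_th)
    if task is None and cohort:
        task = cohort[0].task
    return build_group_graph(counts, excluded, min_subjects, task)
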