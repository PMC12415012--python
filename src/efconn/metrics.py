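"""Per-node centralities and the degree distribution.

Conventions (chosen to match the published per-node tables):

* degree — number of incident edges;
* strength — sum of incident integer weights;
* betweenness — unnormalized shortest-path betweenness, endpoints
  excluded, geodesic ties split evenly;
* closeness — 1 / (sum of shortest-path distances to all *reachable*
  nodes), computed within components. A member of an isolated dyad has
  closeness exactly 1.

Path-based metrics default to binary hop distances: participant-count
weights are reliability weights, not lengths. ``inverse_weight`` treats
edge length as 1/w for a principled weighted alternative.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

PATH_SCHEMES = ("binary", "inverse_weight")


def _length_attr(graph: nx.Graph, path_scheme: str) -> "str | None":
    if path_scheme == "binary":
        return None
    if path_scheme == "inverse_weight":
        for _, _, d in graph.edges(data=True):
            d["length"] = 1.0 / d["weight"]
        return "length"
    raise ValueError(f"unknown path scheme {path_scheme!r}; "
                     f"expected one of {PATH_SCHEMES}")


def closeness(graph: nx.Graph, path_scheme: str = "binary") -> dict:
    """Reciprocal total distance to reachable nodes (unnormalized)."""
    attr = _length_attr(graph, path_scheme)
    out = {}
    for node in graph.nodes:
        if attr is None:
            dists = nx.single_source_shortest_path_length(graph, node)
        else:
            dists = nx.single_source_dijkstra_path_length(graph, node,
                                                          weight=attr)
        total = sum(d for n, d in dists.items() if n != node)
        out[node] = 1.0 / total if total > 0 else 0.0
    return out


def compute_node_metrics(graph: nx.Graph,
                         path_scheme: str = "binary") -> pd.DataFrame:
    """Degree/strength/betweenness/closeness table, indexed by roi_id."""
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot compute node metrics on an empty graph")
    attr = _length_attr(graph, path_scheme)
    btw = nx.betweenness_centrality(graph, normalized=False, weight=attr)
    clo = closeness(graph, path_scheme)
    df = pd.DataFrame({
        "degree": dict(graph.degree),
        "strength": dict(graph.degree(weight="weight")),
        "betweenness": btw,
        "closeness": clo,
    })
    df.index.name = "roi_id"
    return df.sort_index()


def degree_distribution(graph_or_degrees) -> pd.DataFrame:
    """Fraction of nodes at each observed degree; fractions sum to 1.

    Accepts a graph or any iterable of integer degrees (e.g. a published
    degree table's value column).
    """
    if isinstance(graph_or_degrees, nx.Graph):
        if graph_or_degrees.number_of_nodes() == 0:
            raise ValueError("cannot compute a degree distribution of an "
                             "empty graph")
        degrees = [d for _, d in graph_or_degrees.degree]
    else:
        degrees = [int(d) for d in graph_or_degrees]
        if not degrees:
            raise ValueError("empty degree sequence")
    values, counts = np.unique(degrees, return_counts=True)
    return pd.DataFrame({"degree": values.astype(int),
                         "fraction": counts / counts.sum()})


def sorted_metric_table(metrics: pd.DataFrame, metric: str) -> pd.DataFrame:
    """One-metric view sorted descending, mirroring the published tables."""
    out = metrics[[metric]].rename(columns={metric: "value"}).reset_index()
    return out.sort_values(["value", "roi_id"],
                           ascending=[False, True]).reset_index(drop=True)
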