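"""Whole-graph metrics and random-reference null graphs.

The group graphs are sparse and disconnected (isolated dyads survive the
edge-frequency filter), so the conventions are connectedness-robust:

* characteristic path length L — mean hop distance over *connected*
  unordered pairs only;
* global efficiency E — mean of 1/d over *all* unordered pairs, with 0
  for unreachable pairs;
* small-world sigma — (C/C_rand) / (L/L_rand) against an Erdős–Rényi
  G(n, m) reference, forced to 0 whenever mean clustering C is 0;
* assortativity — Pearson correlation of endpoint degrees over both
  orientations of every edge; undefined (NaN) when a marginal has zero
  variance (e.g. regular graphs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .metrics import _length_attr


def characteristic_path_length(graph: nx.Graph,
                               path_scheme: str = "binary") -> float:
    """Mean shortest-path distance over connected unordered pairs (NaN if none)."""
    attr = _length_attr(graph, path_scheme)
    total, pairs = 0.0, 0
    for node, dists in _all_pairs(graph, attr):
        for other, d in dists.items():
            if other != node:
                total += d
                pairs += 1
    # ordered pairs each counted twice; the mean is unchanged
    return total / pairs if pairs else float("nan")


def global_efficiency(graph: nx.Graph, path_scheme: str = "binary") -> float:
    """Mean inverse distance over ALL unordered pairs (0 for unreachable)."""
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    attr = _length_attr(graph, path_scheme)
    inv = 0.0
    for node, dists in _all_pairs(graph, attr):
        for other, d in dists.items():
            if other != node and d > 0:
                inv += 1.0 / d
    return inv / (n * (n - 1))


def _all_pairs(graph, attr):
    if attr is None:
        yield from nx.all_pairs_shortest_path_length(graph)
    else:
        yield from nx.all_pairs_dijkstra_path_length(graph, weight=attr)


def assortativity(graph: nx.Graph) -> float:
    """Degree–degree Pearson correlation over directed edge copies."""
    if graph.number_of_edges() < 2:
        raise ValueError("assortativity needs at least 2 edges")
    deg = dict(graph.degree)
    x, y = [], []
    for u, v in graph.edges:
        x.extend((deg[u], deg[v]))
        y.extend((deg[v], deg[u]))
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class RandomReference:
    """Seeded G(n, m) ensemble summaries used for ratio-based metrics."""

    n: int
    m: int
    replicates: int
    seed: int
    l_rand: float
    c_rand: float
    model: str = "er_gnm"


def random_reference(n: int, m: int, replicates: int = 100,
                     seed: int = 0, model: str = "er_gnm",
                     degree_sequence=None) -> RandomReference:
    """Mean path length / clustering over seeded null-model replicates.

    ``er_gnm`` draws uniform simple graphs with exactly n nodes and m
    edges; ``configuration`` rewires a supplied degree sequence
    (multi-edges/self-loops collapsed).
    """
    if not 0 <= m <= n * (n - 1) // 2:
        raise ValueError(f"m={m} out of range for n={n}")
    rng = np.random.default_rng(seed)
    ls, cs = [], []
    for _ in range(replicates if replicates >= 1 else _raise_replicates()):
        rseed = int(rng.integers(2**31))
        if model == "er_gnm":
            g = nx.gnm_random_graph(n, m, seed=rseed)
        elif model == "configuration":
            if degree_sequence is None:
                raise ValueError("configuration model needs a degree_sequence")
            g = nx.Graph(nx.configuration_model(degree_sequence, seed=rseed))
            g.remove_edges_from(nx.selfloop_edges(g))
        else:
            raise ValueError(f"unknown null model {model!r}")
        l = characteristic_path_length(g)
        if not math.isnan(l):
            ls.append(l)
        cs.append(nx.average_clustering(g))
    l_rand = float(np.mean(ls)) if ls else float("nan")
    c_rand = float(np.mean(cs)) if cs else float("nan")
    return RandomReference(n, m, replicates, seed, l_rand, c_rand, model)


def _raise_replicates():
    raise ValueError("replicates must be >= 1")


@dataclass
class GlobalMetricsTable:
    modularity: float
    global_efficiency: float
    char_path_length: float
    path_length_ratio: float
    assortativity: float
    edge_density: float
    small_world_sigma: float
    transitivity: float
    mean_clustering: float
    reference: "RandomReference | None" = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "modularity", "global_efficiency", "char_path_length",
            "path_length_ratio", "assortativity", "edge_density",
            "small_world_sigma", "transitivity", "mean_clustering")}


def global_metrics(graph: nx.Graph, partition, ref: RandomReference,
                   path_scheme: str = "binary") -> GlobalMetricsTable:
    """The nine whole-graph metrics for one task graph.

    ``partition`` is a CommunityPartition (communities module) whose
    modularity is reported; it must cover exactly the graph's nodes.
    """
    from .communities import modularity as modularity_of

    if set(partition.mapping) != set(graph.nodes):
        raise ValueError("partition node set does not match graph")
    n, m = graph.number_of_nodes(), graph.number_of_edges()
    q = modularity_of(graph, partition.mapping)
    eff = global_efficiency(graph, path_scheme)
    l = characteristic_path_length(graph, path_scheme)
    density = 2 * m / (n * (n - 1)) if n > 1 else 0.0
    trans = nx.transitivity(graph)
    clust = nx.average_clustering(graph)
    try:
        assort = assortativity(graph)
    except ValueError:
        assort = float("nan")
    ratio = l / ref.l_rand if ref.l_rand and not math.isnan(ref.l_rand) \
        else float("nan")
    if clust == 0:
        sigma = 0.0
    elif ref.c_rand and ratio and not math.isnan(ratio) and ratio != 0:
        sigma = (clust / ref.c_rand) / ratio
    else:
        sigma = float("nan")
    return GlobalMetricsTable(q, eff, l, ratio, assort, density, sigma,
                              trans, clust, ref)
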