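"""Community detection: Louvain, divisive edge-betweenness, modularity.

Two detectors are provided and compared:

* **Louvain** — weighted-modularity maximization via the standard
  two-phase local-move/aggregate heuristic (seeded, deterministic given
  the seed).
* **Edge betweenness (divisive)** — repeatedly remove the edge with the
  highest betweenness (recomputed after every removal, binary distances;
  ties broken by the lexicographically smallest (source, target) pair),
  recording a dendrogram; the returned partition is the connected-component
  structure with maximal weighted modularity over the removal sequence.

Modularity is the weighted Newman quality
Q = Σ_c [ W_c/W − (S_c / 2W)² ] with W the total edge weight, W_c the
intra-community weight and S_c the community's strength sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score


@dataclass
class CommunityPartition:
    """node -> dense 0-based community id, with the score of this partition."""

    mapping: dict
    method: str
    q: float
    seed: "int | None" = None
    resolution: float = 1.0

    def communities(self) -> list[set]:
        out: dict[int, set] = {}
        for node, cid in self.mapping.items():
            out.setdefault(cid, set()).add(node)
        return [out[c] for c in sorted(out)]

    @property
    def n_communities(self) -> int:
        return len(set(self.mapping.values()))


def _dense_relabel(groups: "list[set]") -> dict:
    """Stable dense ids: communities ordered by their smallest node."""
    mapping = {}
    for cid, grp in enumerate(sorted(groups, key=min)):
        for node in grp:
            mapping[node] = cid
    return mapping


def modularity(graph: nx.Graph, mapping: dict) -> float:
    """Weighted Newman modularity of a node -> community mapping."""
    missing = set(graph.nodes) - set(mapping)
    if missing:
        raise ValueError(f"partition is missing nodes {sorted(missing)[:5]}")
    groups: dict = {}
    for node in graph.nodes:
        groups.setdefault(mapping[node], set()).add(node)
    return nx.community.modularity(graph, groups.values(), weight="weight")


def louvain(graph: nx.Graph, seed: int = 0,
            resolution: float = 1.0) -> CommunityPartition:
    """Seeded Louvain partition of the weighted graph."""
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty graph")
    groups = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed)
    mapping = _dense_relabel([set(g) for g in groups])
    return CommunityPartition(mapping, "louvain", modularity(graph, mapping),
                              seed=seed, resolution=resolution)


@dataclass
class Dendrogram:
    """Record of a divisive edge-betweenness run.

    ``removals`` lists (edge, betweenness-at-removal) in removal order;
    ``memberships`` holds the component structure before any removal and
    after each one; ``best_index`` points at the maximal-modularity state
    (0 = intact graph).
    """

    removals: list = field(default_factory=list)
    memberships: list = field(default_factory=list)
    qs: list = field(default_factory=list)
    best_index: int = 0

    @property
    def n_leaves(self) -> int:
        return len(self.memberships[0]) if self.memberships else 0

    def records(self) -> list[dict]:
        return [{"source": u, "target": v, "betweenness": b}
                for (u, v), b in self.removals]


def edge_betweenness_communities(
        graph: nx.Graph) -> tuple[Dendrogram, CommunityPartition]:
    """Divisive (Girvan–Newman style) communities with a full dendrogram."""
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty graph")
    work = nx.Graph()
    work.add_nodes_from(graph.nodes)
    work.add_edges_from(graph.edges)
    dendro = Dendrogram()

    def snapshot():
        comps = [set(c) for c in nx.connected_components(work)]
        mapping = _dense_relabel(comps)
        dendro.memberships.append(mapping)
        dendro.qs.append(modularity(graph, mapping))

    snapshot()
    while work.number_of_edges() > 0:
        eb = nx.edge_betweenness_centrality(work, normalized=False, weight=None)
        best_val = max(eb.values())
        # deterministic tie-break: lexicographically smallest sorted edge
        edge = min(tuple(sorted(e)) for e, v in eb.items()
                   if v >= best_val - 1e-12)
        work.remove_edge(*edge)
        dendro.removals.append((edge, best_val))
        snapshot()
    dendro.best_index = max(range(len(dendro.qs)), key=dendro.qs.__getitem__)
    mapping = dendro.memberships[dendro.best_index]
    part = CommunityPartition(mapping, "edge_betweenness",
                              dendro.qs[dendro.best_index])
    return dendro, part


def compare_partitions(p1: CommunityPartition,
                       p2: CommunityPartition) -> tuple[float, float]:
    """(adjusted Rand index, normalized mutual information) of two partitions."""
    if set(p1.mapping) != set(p2.mapping):
        raise ValueError("partitions cover different node sets")
    nodes = sorted(p1.mapping)
    a = [p1.mapping[n] for n in nodes]
    b = [p2.mapping[n] for n in nodes]
    return (float(adjusted_rand_score(a, b)),
            float(normalized_mutual_info_score(a, b)))
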