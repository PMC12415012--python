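"""Expected-force centrality: entropy-based spreading power of a node.

Expected force measures a node's influence as the entropy of the "force of
infection" over all states reachable by exactly two transmission events of
a susceptible–infected process seeded at the node:

1. the first event infects a neighbour j of the seed i along edge (i, j);
2. the second infects a node x outside {i, j} along some edge from i or j;
   each distinct ordered (edge1, edge2) pair is one enumeration, so a node
   adjacent to both i and j is counted once per connecting edge.

For enumeration J with final cluster C(J) = {i, j, x}, the cluster force
d(J) is the number of edges (or, weighted, the total weight of edges)
leaving C(J) — edges with exactly one endpoint inside. With normalized
forces d̄_J = π_J·d(J) / Σ_K π_K·d(K), the expected force is the entropy

    ExF(i) = − Σ_J d̄_J · ln d̄_J        (natural log; nats)

where π_J = 1 in the unweighted case and π_J ∝ w(edge1)·w(edge2) in the
weighted case (enumerations replicated in proportion to how likely the
transmission sequence is). With all weights equal the two variants
coincide. If every reachable cluster has zero boundary (e.g. the seed's
component is a triangle or a dyad), ExF is 0: nothing further can spread.
"""

from __future__ import annotations

import math

import networkx as nx
import pandas as pd


def _node_expected_force(graph: nx.Graph, seed, weighted: bool) -> float:
    enums = []  # (pi_J, d_J)
    for j in graph.neighbors(seed):
        w1 = graph[seed][j]["weight"] if weighted else 1.0
        # second transmission: any edge from the infected pair to outside
        for u in (seed, j):
            for x in graph.neighbors(u):
                if x == seed or x == j:
                    continue
                w2 = graph[u][x]["weight"] if weighted else 1.0
                cluster = {seed, j, x}
                d = 0.0
                for c in cluster:
                    for y in graph.neighbors(c):
                        if y not in cluster:
                            d += graph[c][y]["weight"] if weighted else 1.0
                enums.append((w1 * w2, d))
    total = sum(pi * d for pi, d in enums)
    if total <= 0:
        return 0.0
    exf = 0.0
    for pi, d in enums:
        share = pi * d / total
        if share > 0:
            exf -= share * math.log(share)
    return exf


def expected_force(graph: nx.Graph, weighted: bool = True) -> pd.DataFrame:
    """Expected force for every node; columns roi_id, expected_force."""
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot compute expected force on an empty graph")
    rows = [(node, _node_expected_force(graph, node, weighted))
            for node in graph.nodes]
    df = pd.DataFrame(rows, columns=["roi_id", "expected_force"])
    df.attrs["weighted"] = weighted
    return df.sort_values(["expected_force", "roi_id"],
                          ascending=[False, True]).reset_index(drop=True)
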