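import networkx as nx
import numpy as np
import pytest


def wgraph(edges):
    """Weighted graph from (u, v, w) triples."""
    g = nx.Graph()
    g.add_weighted_edges_from(edges)
    return g


def ugraph(edges):
    """Unit-weight graph from (u, v) pairs."""
    return wgraph([(u, v, 1) for u, v in edges])


@pytest.fixture(scope="session")
def atlas_graphs_small():
    """All non-trivial graphs on 2..7 nodes from the graph atlas,
    unit weights."""
    out = []
    for g in nx.graph_atlas_g():
        if g.number_of_nodes() >= 2 and g.number_of_edges() >= 1:
            h = nx.Graph()
            h.add_nodes_from(g.nodes)
            h.add_edges_from((u, v, {"weight": 1}) for u, v in g.edges)
            out.append(h)
    return out


@pytest.fixture(scope="session")
def atlas_graphs_connected(atlas_graphs_small):
    return [g for g in atlas_graphs_small if nx.is_connected(g)]


# ---------------------------------------------------------------------------
# independent brute-force oracles (deliberately naive; no networkx algorithms)

def bfs_distances(adj, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def adj_of(graph):
    return {u: sorted(graph.neighbors(u)) for u in graph.nodes}


def enumerate_geodesics(adj, s, t):
    """All shortest s->t paths by DFS bounded at the BFS distance."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    limit = dist[t]
    paths = []

    def walk(node, path):
        if len(path) - 1 > limit:
            return
        if node == t and len(path) - 1 == limit:
            paths.append(list(path))
            return
        for nb in adj[node]:
            if nb not in path:
                walk(nb, path + [nb])

    walk(s, [s])
    return paths


def brute_betweenness(graph):
    adj = adj_of(graph)
    nodes = sorted(graph.nodes)
    b = {n: 0.0 for n in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = enumerate_geodesics(adj, s, t)
            if not paths:
                continue
            for p in paths:
                for interior in p[1:-1]:
                    b[interior] += 1.0 / len(paths)
    return b


def brute_closeness(graph):
    adj = adj_of(graph)
    out = {}
    for n in graph.nodes:
        total = sum(d for m, d in bfs_distances(adj, n).items() if m != n)
        out[n] = 1.0 / total if total else 0.0
    return out


def brute_path_length_and_efficiency(graph):
    adj = adj_of(graph)
    nodes = sorted(graph.nodes)
    dists = []
    inv_sum = 0.0
    n_pairs = 0
    for i, s in enumerate(nodes):
        d = bfs_distances(adj, s)
        for t in nodes[i + 1:]:
            n_pairs += 1
            if t in d:
                dists.append(d[t])
                inv_sum += 1.0 / d[t]
    L = sum(dists) / len(dists) if dists else float("nan")
    E = inv_sum / n_pairs if n_pairs else 0.0
    return L, E


def brute_modularity(graph, mapping):
    """Double-loop over ordered node pairs."""
    two_w = 2.0 * sum(d.get("weight", 1) for _, _, d in graph.edges(data=True))
    if two_w == 0:
        return 0.0
    strength = {n: sum(d.get("weight", 1)
                       for _, _, d in graph.edges(n, data=True))
                for n in graph.nodes}
    q = 0.0
    for i in graph.nodes:
        for j in graph.nodes:
            if mapping[i] != mapping[j]:
                continue
            a = graph[i][j].get("weight", 1) if graph.has_edge(i, j) else 0.0
            if i == j:
                a = 0.0
            q += a / two_w - strength[i] * strength[j] / two_w**2
    return q


def brute_expected_force(graph, seed_node, weighted=False):
    """Direct two-transmission enumeration over ordered edge pairs."""
    import math
    edges = []
    for u, v, d in graph.edges(data=True):
        w = d.get("weight", 1) if weighted else 1.0
        edges.append((u, v, w))
    enums = []
    for (a1, b1, w1) in edges:
        for first in ((a1, b1), (b1, a1)):
            src, j = first
            if src != seed_node:
                continue
            cluster1 = {seed_node, j}
            for (a2, b2, w2) in edges:
                inside = (a2 in cluster1) + (b2 in cluster1)
                if inside != 1:
                    continue
                x = b2 if a2 in cluster1 else a2
                cluster = cluster1 | {x}
                dJ = 0.0
                for (a3, b3, w3) in edges:
                    if (a3 in cluster) + (b3 in cluster) == 1:
                        dJ += w3
                enums.append((w1 * w2, dJ))
    total = sum(p * d for p, d in enums)
    if total <= 0:
        return 0.0
    exf = 0.0
    for p, d in enums:
        share = p * d / total
        if share > 0:
            exf -= share * math.log(share)
    return exf
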