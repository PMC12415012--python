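import networkx as nx
import numpy as np
import pytest

from efconn.communities import (compare_partitions, CommunityPartition,
                                edge_betweenness_communities, louvain,
                                modularity)
from tests.conftest import brute_modularity, ugraph, wgraph


def two_triangles():
    return ugraph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


def bridged_triangles():
    g = two_triangles()
    g.add_edge(2, 3, weight=1)
    return g


class TestModularity:
    def test_two_disjoint_triangles(self):
        part = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
        assert modularity(two_triangles(), part) == pytest.approx(0.5)

    def test_single_block_is_zero(self):
        g = wgraph([(0, 1, 5), (1, 2, 3), (0, 2, 2)])
        assert modularity(g, {n: 0 for n in g.nodes}) == pytest.approx(0.0)

    def test_single_edge_partitions(self):
        g = ugraph([(0, 1)])
        assert modularity(g, {0: 0, 1: 0}) == pytest.approx(0.0)
        assert modularity(g, {0: 0, 1: 1}) == pytest.approx(-0.5)

    def test_missing_node_rejected(self):
        with pytest.raises(ValueError):
            modularity(ugraph([(0, 1)]), {0: 0})

    def test_matches_double_loop_oracle(self, atlas_graphs_small):
        rng = np.random.default_rng(0)
        for g in atlas_graphs_small[::7]:
            for _, _, d in g.edges(data=True):
                d["weight"] = int(rng.integers(1, 9))
            mapping = {n: int(rng.integers(0, 3)) for n in g.nodes}
            assert modularity(g, mapping) == pytest.approx(
                brute_modularity(g, mapping), abs=1e-12)
            assert modularity(g, mapping) <= 1.0


class TestLouvain:
    def test_two_triangles_found(self):
        part = louvain(two_triangles(), seed=0)
        assert part.n_communities == 2
        assert part.q == pytest.approx(0.5)

    def test_single_edge_one_community(self):
        part = louvain(ugraph([(0, 1)]), seed=0)
        assert part.n_communities == 1 and part.q == pytest.approx(0.0)

    def test_isolated_dyads_form_own_communities(self):
        g = wgraph([(45, 147, 54), (50, 156, 38), (66, 170, 28)])
        part = louvain(g, seed=0)
        assert part.n_communities == 3
        assert part.mapping[45] == part.mapping[147]
        assert part.mapping[45] != part.mapping[50]

    def test_deterministic_given_seed(self):
        g = nx.gnm_random_graph(30, 60, seed=9)
        nx.set_edge_attributes(g, 1, "weight")
        assert louvain(g, seed=3).mapping == louvain(g, seed=3).mapping

    def test_beats_singletons_and_nonnegative_on_disconnected(self):
        g = wgraph([(0, 1, 2), (1, 2, 2), (3, 4, 1)])
        part = louvain(g, seed=0)
        singles = modularity(g, {n: i for i, n in enumerate(g.nodes)})
        assert part.q >= singles
        assert part.q >= 0


class TestEdgeBetweennessCommunities:
    def test_bridge_removed_first(self):
        dendro, part = edge_betweenness_communities(bridged_triangles())
        assert dendro.removals[0][0] == (2, 3)
        assert part.n_communities == 2
        assert {frozenset({0, 1, 2}), frozenset({3, 4, 5})} == \
            set(map(frozenset, part.communities()))

    def test_components_never_merge(self):
        dendro, _ = edge_betweenness_communities(two_triangles())
        n_comps = [len(set(m.values())) for m in dendro.memberships]
        assert n_comps == sorted(n_comps)

    def test_dendrogram_leaf_count_and_final_state(self):
        g = nx.gnm_random_graph(9, 14, seed=1)
        nx.set_edge_attributes(g, 1, "weight")
        dendro, _ = edge_betweenness_communities(g)
        assert dendro.n_leaves == 9
        assert len(dendro.removals) == 14
        assert len(set(dendro.memberships[-1].values())) == 9

    def test_deterministic_tie_break(self):
        g = ugraph([(1, 2), (3, 4)])  # both edges tie at betweenness 1
        dendro, _ = edge_betweenness_communities(g)
        assert dendro.removals[0][0] == (1, 2)


class TestComparePartitions:
    def part(self, mapping, q=0.0):
        return CommunityPartition(mapping, "louvain", q)

    def test_identity(self):
        p = self.part({0: 0, 1: 0, 2: 1, 3: 1})
        ari, nmi = compare_partitions(p, p)
        assert ari == 1.0 and nmi == 1.0

    def test_chance_level(self):
        a = self.part({i: 0 for i in range(6)})
        b = self.part({i: i for i in range(6)})
        ari, _ = compare_partitions(a, b)
        assert ari == pytest.approx(0.0)

    def test_against_contingency_formula(self):
        from math import comb
        m1 = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
        m2 = {0: 0, 1: 0, 2: 1, 3: 1, 4: 1, 5: 1}
        # contingency 2x2: [[2,1],[0,3]]
        sum_ij = comb(2, 2) + comb(1, 2) + comb(3, 2)
        a_sum = comb(3, 2) + comb(3, 2)
        b_sum = comb(2, 2) + comb(4, 2)
        n2 = comb(6, 2)
        expected = (sum_ij - a_sum * b_sum / n2) / \
                   ((a_sum + b_sum) / 2 - a_sum * b_sum / n2)
        ari, _ = compare_partitions(self.part(m1), self.part(m2))
        assert ari == pytest.approx(expected)

    def test_node_set_mismatch(self):
        with pytest.raises(ValueError):
            compare_partitions(self.part({0: 0}), self.part({1: 0}))


def test_louvain_and_divisive_agree_on_planted_two_blocks():
    # two strongly intra-connected blocks with one weak cross edge
    rng = np.random.default_rng(0)
    g = nx.Graph()
    for base in (0, 10):
        nodes = range(base, base + 10)
        for u in nodes:
            for v in nodes:
                if u < v and rng.random() < 0.8:
                    g.add_edge(u, v, weight=50)
    g.add_edge(0, 10, weight=1)
    lv = louvain(g, seed=0)
    _, eb = edge_betweenness_communities(g)
    ari, _ = compare_partitions(lv, eb)
    assert ari >= 0.9
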