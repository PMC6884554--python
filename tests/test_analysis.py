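"""Degree, modularity and greedy community detection."""

import itertools

import networkx as nx
import numpy as np
import pytest
from networkx.algorithms import community as nx_community
from sklearn.metrics import adjusted_rand_score

from colocnet.analysis import (
    Partition,
    degree_report,
    detect_communities,
    modularity,
    subdivide,
)
from colocnet.contacts import ConfigError


class TestDegreeReport:
    def test_star(self):
        g = nx.star_graph(6)
        report = degree_report(g)
        assert report[0] == (0, 6)
        assert all(d == 1 for _, d in report[1:])

    def test_empty_graph(self):
        assert degree_report(nx.Graph()) == []

    def test_handshake_identity(self):
        g = nx.gnp_random_graph(30, 0.2, seed=4)
        assert sum(d for _, d in degree_report(g)) == 2 * g.number_of_edges()


def _modularity_double_sum(g, communities):
    """Direct double-sum oracle: Q = (1/2m) sum_ij (A_ij - d_i d_j / 2m) delta."""
    m = g.number_of_edges()
    label = {n: i for i, c in enumerate(communities) for n in c}
    a = nx.to_numpy_array(g)
    nodes = list(g.nodes)
    q = 0.0
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if label[u] == label[v]:
                q += a[i, j] - g.degree(u) * g.degree(v) / (2 * m)
    return q / (2 * m)


class TestModularity:
    def test_single_community_is_zero(self):
        g = nx.gnp_random_graph(12, 0.3, seed=1)
        assert modularity(g, [set(g.nodes)]) == pytest.approx(0.0, abs=1e-12)

    def test_two_disconnected_cliques_half(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        split = [set(range(4)), set(range(4, 8))]
        assert modularity(g, split) == pytest.approx(0.5, abs=1e-12)

    def test_no_edges_error(self):
        with pytest.raises(ConfigError):
            modularity(nx.empty_graph(3), [{0, 1, 2}])

    def test_partition_must_cover(self):
        g = nx.path_graph(4)
        with pytest.raises(ValueError):
            modularity(g, [{0, 1}])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(15, 0.25, seed=seed)
        if g.number_of_edges() == 0:
            g.add_edge(0, 1)
        labels = rng.integers(0, 3, size=15)
        communities = [
            {n for n in g.nodes if labels[n] == k} for k in range(3)
        ]
        communities = [c for c in communities if c]
        assert modularity(g, communities) == pytest.approx(
            _modularity_double_sum(g, communities), abs=1e-9
        )


def _exhaustive_best_partition(g):
    """Maximal-modularity partition by enumerating all set partitions."""

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1 :]
            yield [[first]] + part

    edges = list(g.edges)
    degree = dict(g.degree)
    m = len(edges)

    def q_of(part):
        label = {n: i for i, p in enumerate(part) for n in p}
        intra = [0] * len(part)
        for u, v in edges:
            if label[u] == label[v]:
                intra[label[u]] += 1
        q = 0.0
        for i, p in enumerate(part):
            d = sum(degree[n] for n in p)
            q += intra[i] / m - (d / (2 * m)) ** 2
        return q

    best, best_q = None, -2.0
    for part in partitions(list(g.nodes)):
        q = q_of(part)
        if q > best_q + 1e-12:
            best, best_q = part, q
    return {frozenset(p) for p in best}, best_q


class TestDetectCommunities:
    def test_two_cliques_one_bridge(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        partition = detect_communities(g)
        expected, best_q = _exhaustive_best_partition(g)
        assert set(partition.communities) == expected
        assert partition.modularity_q == pytest.approx(best_q, abs=1e-9)

    def test_single_clique_single_community(self):
        g = nx.complete_graph(5)
        partition = detect_communities(g)
        assert set(partition.communities) == {frozenset(range(5))}
        _, best_q = _exhaustive_best_partition(g)
        assert partition.modularity_q == pytest.approx(best_q, abs=1e-9)

    def test_three_disconnected_triangles(self):
        g = nx.disjoint_union_all([nx.complete_graph(3)] * 3)
        partition = detect_communities(g)
        assert set(partition.communities) == {
            frozenset({0, 1, 2}), frozenset({3, 4, 5}), frozenset({6, 7, 8})
        }

    def test_never_below_singleton_modularity(self):
        for seed in range(8):
            g = nx.gnp_random_graph(20, 0.15, seed=seed)
            if g.number_of_edges() == 0:
                continue
            singleton_q = modularity(g, [{n} for n in g.nodes])
            assert detect_communities(g).modularity_q >= singleton_q - 1e-12

    def test_agrees_with_networkx_greedy_on_clean_structure(self):
        """Independent cross-check on a graph with unambiguous communities."""
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        g.add_edge(0, 6)
        ours = set(detect_communities(g).communities)
        theirs = {frozenset(c) for c in nx_community.greedy_modularity_communities(g)}
        assert ours == theirs

    def test_communities_respect_components(self):
        g = nx.disjoint_union(nx.gnp_random_graph(8, 0.5, seed=2),
                              nx.gnp_random_graph(8, 0.5, seed=3))
        partition = detect_communities(g)
        comps = list(nx.connected_components(g))
        for community in partition.communities:
            assert any(set(community) <= comp for comp in comps)

    def test_planted_partition_recovery(self):
        """Two planted 10-node modules (p_in=0.9, p_out=0.02): ARI >= 0.9 in >= 18/20."""
        successes = 0
        for seed in range(20):
            g = nx.planted_partition_graph(2, 10, 0.9, 0.02, seed=seed)
            truth = [0] * 10 + [1] * 10
            labels = detect_communities(g).node_labels()
            pred = [labels[n] for n in range(20)]
            if adjusted_rand_score(truth, pred) >= 0.9:
                successes += 1
        assert successes >= 18

    def test_incremental_q_matches_from_scratch_at_every_merge(self):
        """Replaying greedy merges: incremental Q equals recomputed Q (1e-9)."""
        g = nx.gnp_random_graph(18, 0.2, seed=6)
        m = g.number_of_edges()
        comms = [{n} for n in g.nodes]
        q_inc = modularity(g, comms)
        while True:
            best = None
            for i, j in itertools.combinations(range(len(comms)), 2):
                e_ij = sum(
                    1 for u in comms[i] for v in comms[j] if g.has_edge(u, v)
                )
                if e_ij == 0:
                    continue
                d_i = sum(g.degree(n) for n in comms[i])
                d_j = sum(g.degree(n) for n in comms[j])
                dq = e_ij / m - d_i * d_j / (2 * m * m)
                if best is None or dq > best[0]:
                    best = (dq, i, j)
            if best is None or best[0] <= 0:
                break
            dq, i, j = best
            comms[i] |= comms.pop(j)
            q_inc += dq
            assert modularity(g, comms) == pytest.approx(q_inc, abs=1e-9)


class TestSubdivide:
    def _bridged_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(0, 5)
        return g

    def test_large_community_split_into_labelled_subcommunities(self):
        g = self._bridged_cliques()
        parent = Partition((frozenset(g.nodes),), ("1",), modularity(g, [set(g.nodes)]))
        refined = subdivide(g, parent, min_size=4)
        assert sorted(refined.labels) == ["1.1", "1.2"]
        expected, _ = _exhaustive_best_partition(g)
        assert set(refined.communities) == expected

    def test_small_community_unchanged(self):
        g = self._bridged_cliques()
        parent = Partition((frozenset(g.nodes),), ("1",), 0.0)
        refined = subdivide(g, parent, min_size=10)
        assert refined.communities == parent.communities

    def test_min_size_validation(self):
        g = self._bridged_cliques()
        parent = detect_communities(g)
        with pytest.raises(ConfigError):
            subdivide(g, parent, min_size=1)

    def test_label_structure_stable_under_node_permutation(self):
        g = self._bridged_cliques()
        mapping = {n: (n * 7 + 3) % 10 + 100 for n in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        part_g = subdivide(g, detect_communities(g), min_size=4)
        part_h = subdivide(h, detect_communities(h), min_size=4)
        mapped = {frozenset(mapping[n] for n in c) for c in part_g.communities}
        assert mapped == set(part_h.communities)
        assert sorted(part_g.labels) == sorted(part_h.labels)
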