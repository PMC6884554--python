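"""Original network construction, blacklist, extension and components."""

import itertools

import numpy as np
import pandas as pd
import pytest

from colocnet.contacts import CONTACT_COLUMNS, ContactSet
from colocnet.egr import GeneAnnotation, build_egrs
from colocnet.genome import GenomeLayout, GenomicInterval
from colocnet.network import (
    blacklist_filter,
    build_original_network,
    components,
    extend_network,
    isolated_nodes,
)

BIN = 100_000
LAYOUT = GenomeLayout(("chrA", "chrB", "chrC"), (3_000_000,) * 3, BIN)


def make_egrs(spans):
    """spans: list of (chrom, first_bin, last_bin)."""
    genes = [
        GeneAnnotation(
            f"G{i}", f"G{i}", chrom, (first - 1) * BIN + 1, last * BIN, "+", True
        )
        for i, (chrom, first, last) in enumerate(spans)
    ]
    return build_egrs(genes, [], BIN, LAYOUT)


def contact_set(rows, threshold=64.0):
    df = pd.DataFrame(rows, columns=CONTACT_COLUMNS)
    return ContactSet(df, BIN, threshold=threshold)


class TestOriginalNetwork:
    def test_strong_contact_creates_weighted_edge(self):
        egrs = make_egrs([("chrA", 1, 2), ("chrB", 5, 6)])
        strong = contact_set([("chrA", 2, "chrB", 5, 70, 70.0)])
        g = build_original_network(egrs, strong, [], LAYOUT)
        assert g.number_of_edges() == 1
        ((u, v, data),) = g.edges(data=True)
        assert data["weight"] == 70.0 and data["edge_type"] == "inter"

    def test_max_weight_over_fragment_pairs(self):
        egrs = make_egrs([("chrA", 1, 2), ("chrB", 5, 6)])
        strong = contact_set(
            [("chrA", 1, "chrB", 5, 70, 70.0), ("chrA", 2, "chrB", 6, 90, 90.0)]
        )
        g = build_original_network(egrs, strong, [], LAYOUT)
        ((u, v, data),) = g.edges(data=True)
        assert data["weight"] == 90.0

    def test_below_threshold_contact_ignored(self):
        egrs = make_egrs([("chrA", 1, 2), ("chrB", 5, 6)])
        # a pre-thresholded set would not contain 63; emulate an empty result
        strong = contact_set([("chrA", 2, "chrB", 5, 63, 63.0)])
        from colocnet.contacts import strong_contacts

        g = build_original_network(egrs, strong_contacts(strong, 64), [], LAYOUT)
        assert g.number_of_edges() == 0
        assert set(isolated_nodes(g)) == set(g.nodes)

    def test_matches_all_fragment_pairs_oracle(self):
        rng = np.random.default_rng(17)
        spans = [("chrA", 1, 2), ("chrA", 10, 11), ("chrB", 3, 5),
                 ("chrB", 20, 20), ("chrC", 7, 9)]
        egrs = make_egrs(spans)
        rows = []
        chroms = ("chrA", "chrB", "chrC")
        for _ in range(60):
            ca, cb = rng.choice(3, size=2, replace=False)
            ba, bb = int(rng.integers(1, 25)), int(rng.integers(1, 25))
            norm = float(rng.uniform(64, 150))
            rows.append((chroms[ca], ba, chroms[cb], bb, norm, norm))
        strong = contact_set(rows)
        g = build_original_network(egrs, strong, [], LAYOUT)
        # brute force: check every region pair and every fragment pair
        lut = {}
        for chrom_a, bin_a, chrom_b, bin_b, _, norm in rows:
            lut[(chrom_a, bin_a, chrom_b, bin_b)] = max(
                lut.get((chrom_a, bin_a, chrom_b, bin_b), 0), norm
            )
        for ea, eb in itertools.combinations(egrs, 2):
            best = 0.0
            for x in ea.region.bins():
                for y in eb.region.bins():
                    key1 = (ea.region.chrom, x, eb.region.chrom, y)
                    key2 = (eb.region.chrom, y, ea.region.chrom, x)
                    best = max(best, lut.get(key1, 0.0), lut.get(key2, 0.0))
            if best > 0:
                assert g[ea.id][eb.id]["weight"] == pytest.approx(best)
            else:
                assert not g.has_edge(ea.id, eb.id)

    def test_bin_grid_mismatch_rejected(self):
        egrs = make_egrs([("chrA", 1, 2)])
        df = pd.DataFrame(
            [("chrA", 1, "chrB", 2, 70, 70.0)], columns=CONTACT_COLUMNS
        )
        with pytest.raises(Exception, match="grid"):
            build_original_network(egrs, ContactSet(df, 10_000), [], LAYOUT)


class TestBlacklist:
    def _graph(self):
        egrs = make_egrs([("chrA", 1, 2), ("chrB", 5, 6), ("chrC", 9, 9)])
        strong = contact_set(
            [("chrA", 1, "chrB", 5, 70, 70.0), ("chrB", 6, "chrC", 9, 80, 80.0)]
        )
        return build_original_network(egrs, strong, [], LAYOUT)

    def test_blacklisted_node_and_edges_removed(self):
        g = self._graph()
        filtered, _ = blacklist_filter(
            g, [GenomicInterval("chrB", 400_001, 500_000)]
        )
        assert "chrB:5-6" not in filtered
        assert filtered.number_of_edges() == 0

    def test_empty_blacklist_is_identity(self):
        g = self._graph()
        filtered, reported = blacklist_filter(g, [])
        assert set(filtered.nodes) == set(g.nodes)
        assert filtered.number_of_edges() == g.number_of_edges()
        assert reported == []

    def test_promiscuous_node_reported_not_removed(self):
        egrs = make_egrs([("chrA", 1, 1), ("chrB", 5, 5)])
        rows = [("chrA", 1, "chrB", b, 70, 70.0) for b in range(1, 25)]
        g = build_original_network(egrs, contact_set(rows), [], LAYOUT)
        filtered, reported = blacklist_filter(g, [], promiscuity_fraction=0.1)
        # chrA:1 touches 24 of 90 bins (27%) > 10%
        assert reported == ["chrA:1-1"]
        assert "chrA:1-1" in filtered


class TestExtension:
    def test_neighbour_bins_amalgamate_into_novel_node(self):
        egrs = make_egrs([("chrA", 4, 5)])
        strong = contact_set(
            [("chrB", 10, "chrA", 4, 70, 70.0), ("chrB", 11, "chrA", 5, 80, 80.0)]
        )
        original = build_original_network(egrs, strong, [], LAYOUT)
        # the single EGR has edges to no other *node*, hence isolated; give it
        # a companion node so it survives extension
        egrs = make_egrs([("chrA", 4, 5), ("chrC", 2, 2)])
        strong = contact_set(
            [
                ("chrB", 10, "chrA", 4, 70, 70.0),
                ("chrB", 11, "chrA", 5, 80, 80.0),
                ("chrA", 4, "chrC", 2, 65, 65.0),
            ]
        )
        original = build_original_network(egrs, strong, [], LAYOUT)
        extended = extend_network(original, strong, LAYOUT)
        assert "chrB:10-11" in extended
        data = extended.nodes["chrB:10-11"]
        assert data["node_class"] == "novel"
        assert extended["chrB:10-11"]["chrA:4-5"]["weight"] == 80.0

    def test_novel_bin_adjacent_to_original_merges_into_it(self):
        egrs = make_egrs([("chrA", 4, 5), ("chrB", 10, 10)])
        strong = contact_set(
            [
                ("chrA", 4, "chrB", 10, 70, 70.0),  # original edge
                ("chrB", 10, "chrA", 6, 90, 90.0),  # neighbour adjacent to chrA:4-5
            ]
        )
        original = build_original_network(egrs, strong, [], LAYOUT)
        extended = extend_network(original, strong, LAYOUT)
        assert "chrA:4-6" in extended
        data = extended.nodes["chrA:4-6"]
        assert data["node_class"] == "guilty-EGR"  # class preserved on merge
        assert data["novel_bins"] == (6,)

    def test_isolated_original_nodes_excluded(self):
        egrs = make_egrs([("chrA", 1, 1), ("chrB", 5, 5), ("chrC", 9, 9)])
        strong = contact_set([("chrA", 1, "chrB", 5, 70, 70.0)])
        original = build_original_network(egrs, strong, [], LAYOUT)
        assert isolated_nodes(original) == ["chrC:9-9"]
        extended = extend_network(original, strong, LAYOUT)
        assert "chrC:9-9" not in extended

    def test_matches_neighbourhood_oracle_and_invariants(self):
        rng = np.random.default_rng(23)
        spans = [("chrA", 2, 3), ("chrB", 8, 9), ("chrC", 14, 15)]
        egrs = make_egrs(spans)
        chroms = ("chrA", "chrB", "chrC")
        rows = []
        for _ in range(50):
            ca, cb = rng.choice(3, size=2, replace=False)
            rows.append(
                (chroms[ca], int(rng.integers(1, 30)), chroms[cb],
                 int(rng.integers(1, 30)), 70.0, float(rng.uniform(64, 150)))
            )
        strong = contact_set(rows)
        original = build_original_network(egrs, strong, [], LAYOUT)
        extended = extend_network(original, strong, LAYOUT)

        kept_bins = {
            (d["region"].chrom, b)
            for n, d in original.nodes(data=True)
            if not d["isolated"]
            for b in d["region"].bins()
        }
        neighbour_bins = set()
        for chrom_a, bin_a, chrom_b, bin_b, _, _ in rows:
            a, b = (chrom_a, bin_a), (chrom_b, bin_b)
            if a in kept_bins and b not in kept_bins:
                neighbour_bins.add(b)
            if b in kept_bins and a not in kept_bins:
                neighbour_bins.add(a)
        covered = {
            (d["region"].chrom, b)
            for _, d in extended.nodes(data=True)
            for b in d["region"].bins()
        }
        # conservation: extended bins = original kept bins + added neighbours
        assert covered == kept_bins | neighbour_bins
        # no orphan additions
        for node, data in extended.nodes(data=True):
            if data["node_class"] == "novel":
                bins = {(data["region"].chrom, b) for b in data["region"].bins()}
                assert bins <= neighbour_bins
        # monotonicity: original (non-isolated) adjacency is preserved
        old_new = {
            n: next(
                m for m, d in extended.nodes(data=True)
                if n in d.get("origin_nodes", ())
            )
            for n, d in original.nodes(data=True)
            if not d["isolated"]
        }
        for u, v in original.edges:
            if u in old_new and v in old_new and old_new[u] != old_new[v]:
                assert extended.has_edge(old_new[u], old_new[v])
        # symmetry holds by construction in an undirected graph
        import networkx as nx

        mat = nx.to_numpy_array(extended)
        assert (mat == mat.T).all()


class TestComponents:
    def test_two_disjoint_edges(self):
        import networkx as nx

        g = nx.Graph([("a", "b"), ("c", "d")])
        for n in g.nodes:
            g.nodes[n]["region"] = None
        assert [len(c) for c in components(g)] == [2, 2]

    def test_path_is_single_component(self):
        import networkx as nx

        g = nx.path_graph(5)
        assert len(components(g)) == 1

    def test_matches_union_find_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(40, 0.04, seed=9)
        parent = list(range(40))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for u, v in g.edges:
            parent[find(u)] = find(v)
        expected = {}
        for n in g.nodes:
            expected.setdefault(find(n), set()).add(n)
        got = components(g)
        assert sorted(map(len, got), reverse=True) == sorted(
            map(len, expected.values()), reverse=True
        )
        assert {frozenset(c) for c in got} == {
            frozenset(c) for c in expected.values()
        }
        # ordering: sizes descending, ties by smallest node id
        sizes = [len(c) for c in got]
        assert sizes == sorted(sizes, reverse=True)
        for a, b in zip(got, got[1:]):
            if len(a) == len(b):
                assert min(a) < min(b)
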