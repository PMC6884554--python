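"""Degree centrality and greedy modularity community detection.

Communities are found by agglomerative greedy modularity maximization
(Clauset-Newman-Moore style): start from singleton communities and
repeatedly merge the *connected* pair with the largest modularity gain
while that gain is positive. Merging non-adjacent communities can never
increase modularity, so disconnected components are never joined and the
procedure effectively runs per component. Ties break deterministically on
the lexicographically smallest community-label pair, where a community's
label is its smallest member node id. Large communities can be re-clustered
once on their induced subgraphs, yielding two-level hierarchical labels
("1", "1.4", ...).

Both degree and modularity are computed on the unweighted graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from .contacts import ConfigError


@dataclass(frozen=True)
class Partition:
    """Disjoint node communities covering a graph, with hierarchical labels."""

    communities: tuple[frozenset, ...]
    labels: tuple[str, ...]
    modularity_q: float

    def __post_init__(self) -> None:
        if len(self.communities) != len(self.labels):
            raise ValueError("communities and labels length mismatch")

    def node_labels(self) -> dict:
        return {
            node: label
            for community, label in zip(self.communities, self.labels)
            for node in community
        }

    def __len__(self) -> int:
        return len(self.communities)


def degree_report(network: nx.Graph) -> list[tuple[str, int]]:
    """(node, unweighted degree), degree descending, ties by node id."""
    return sorted(network.degree(), key=lambda item: (-item[1], item[0]))


def modularity(network: nx.Graph, communities: Sequence[frozenset | set]) -> float:
    """Newman modularity Q = sum_c [ l_c/m - (d_c/2m)^2 ] (unweighted)."""
    m = network.number_of_edges()
    if m == 0:
        raise ConfigError("modularity undefined for a graph with no edges")
    nodes = set(network.nodes)
    seen: set = set()
    for community in communities:
        if seen & set(community):
            raise ValueError("communities are not disjoint")
        seen |= set(community)
    if seen != nodes:
        raise ValueError("partition does not cover all nodes")
    q = 0.0
    for community in communities:
        cset = set(community)
        l_c = sum(1 for u, v in network.edges(cset) if u in cset and v in cset)
        d_c = sum(network.degree(n) for n in cset)
        q += l_c / m - (d_c / (2 * m)) ** 2
    return q


def _greedy_merge(network: nx.Graph) -> list[frozenset]:
    """Agglomerative CNM merge loop; returns unordered communities."""
    m = network.number_of_edges()
    members: dict = {node: {node} for node in network.nodes}
    deg_sum: dict = {node: network.degree(node) for node in network.nodes}
    between: dict[tuple, int] = {}
    for u, v in network.edges:
        if u == v:
            continue
        key = (u, v) if u < v else (v, u)
        between[key] = between.get(key, 0) + 1

    while between:
        best_key = None
        best_dq = 0.0
        for key in sorted(between):
            li, lj = key
            dq = between[key] / m - deg_sum[li] * deg_sum[lj] / (2.0 * m * m)
            if dq > best_dq + 1e-12:
                best_dq = dq
                best_key = key
        if best_key is None or best_dq <= 0:
            break
        li, lj = best_key  # li < lj: lj is absorbed into li
        members[li] |= members.pop(lj)
        deg_sum[li] += deg_sum.pop(lj)
        del between[best_key]
        for key in [k for k in between if lj in k]:
            other = key[0] if key[1] == lj else key[1]
            count = between.pop(key)
            if other == li:
                continue  # edges now internal
            new_key = (li, other) if li < other else (other, li)
            between[new_key] = between.get(new_key, 0) + count
    return [frozenset(c) for c in members.values()]


def _order_communities(communities: list[frozenset]) -> list[frozenset]:
    return sorted(communities, key=lambda c: (-len(c), min(c)))


def detect_communities(network: nx.Graph) -> Partition:
    """Greedy modularity partition with deterministic labels "1", "2", ...

    Communities are numbered by size descending, ties by smallest node id.
    An edgeless graph yields singleton communities with Q = 0.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    if network.number_of_edges() == 0:
        comms = _order_communities([frozenset({n}) for n in network.nodes])
        labels = tuple(str(i + 1) for i in range(len(comms)))
        return Partition(tuple(comms), labels, 0.0)
    comms = _order_communities(_greedy_merge(network))
    labels = tuple(str(i + 1) for i in range(len(comms)))
    return Partition(tuple(comms), labels, modularity(network, comms))


def subdivide(
    network: nx.Graph, partition: Partition, min_size: int = 40
) -> Partition:
    """Re-cluster communities larger than ``min_size`` on induced subgraphs.

    One level of recursion only: a split community "k" yields subcommunities
    "k.1", "k.2", ... (numbered by size descending); smaller communities
    pass through unchanged. ``modularity_q`` is that of the resulting flat
    partition on the full graph.
    """
    if min_size < 2:
        raise ConfigError(f"min_size must be >= 2, got {min_size}")
    out_comms: list[frozenset] = []
    out_labels: list[str] = []
    for community, label in zip(partition.communities, partition.labels):
        if len(community) <= min_size:
            out_comms.append(community)
            out_labels.append(label)
            continue
        sub = detect_communities(network.subgraph(community).copy())
        if len(sub) == 1:
            out_comms.append(community)
            out_labels.append(label)
            continue
        for j, subcommunity in enumerate(sub.communities, start=1):
            out_comms.append(subcommunity)
            out_labels.append(f"{label}.{j}")
    q = modularity(network, out_comms) if network.number_of_edges() else 0.0
    return Partition(tuple(out_comms), tuple(out_labels), q)
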