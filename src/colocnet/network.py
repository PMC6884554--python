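"""Region interaction networks: original build, blacklist, first-neighbour extension.

The *original network* has one node per extended gene region or regulatory
footprint; two nodes on different chromosomes are joined by an inter edge
when at least one pair of their constituent 100 kb bins shows a strong
(thresholded, normalized) Hi-C contact, with the maximum such count kept as
edge weight (metadata only — degree and community analyses are unweighted).
Capture-derived intra-chromosomal links are added as intra edges. Nodes
with no edge at all are flagged isolated and excluded before extension.

The *extended network* adds every 100 kb bin with a strong contact to a
constituent bin of a non-isolated original node (first nearest neighbours).
All adjacent bins — original and added alike — amalgamate into longer
regions; a resulting region inheriting no original node is a *novel* node.
Edges are re-derived: two nodes are linked iff at least one constituent
fragment pair interacts strongly; intra links are carried over.

A blacklist removes promiscuously interacting regions (such as a bin that
contacts nearly every other bin, typically an assembly artifact) together
with their incident edges; a promiscuity detector reports — without
removing — nodes whose strong-contact partners cover more than a configured
fraction of all genomic bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .contacts import ContactSet
from .egr import ExtendedGeneRegion, IntraLink
from .genome import (
    BinnedRegion,
    CoordinateError,
    GenomeLayout,
    GenomicInterval,
    amalgamate,
)

GUILTY = "guilty-EGR"
REGULATORY = "regulatory"
NOVEL = "novel"

_CLASS_RANK = {GUILTY: 0, REGULATORY: 1, NOVEL: 2}


def _bin_owner_map(graph: nx.Graph) -> dict[tuple[str, int], str]:
    owner: dict[tuple[str, int], str] = {}
    for node, data in graph.nodes(data=True):
        region: BinnedRegion = data["region"]
        for label in region.bins():
            owner[(region.chrom, label)] = node
    return owner


def _strong_partner_counts(
    graph: nx.Graph, strong: ContactSet
) -> None:
    """Attach per-node counts of distinct strong-contact partner bins."""
    owner = _bin_owner_map(graph)
    partners: dict[str, set[tuple[str, int]]] = {n: set() for n in graph.nodes}
    for row in strong.defined.itertuples(index=False):
        a = (row.chrom_a, int(row.bin_a))
        b = (row.chrom_b, int(row.bin_b))
        if a in owner:
            partners[owner[a]].add(b)
        if b in owner:
            partners[owner[b]].add(a)
    for node, bins in partners.items():
        graph.nodes[node]["n_partner_bins"] = len(bins)


def build_original_network(
    egrs: Sequence[ExtendedGeneRegion],
    strong_inter: ContactSet,
    intra: Sequence[IntraLink] = (),
    layout: GenomeLayout | None = None,
) -> nx.Graph:
    """Original network over EGR / regulatory-footprint nodes.

    ``strong_inter`` must already be thresholded and on the same bin grid as
    the regions. Isolated nodes (no inter or intra edge) are retained but
    flagged ``isolated=True``.
    """
    if egrs and strong_inter.bin_size != egrs[0].region.bin_size:
        raise CoordinateError(
            f"bin grid mismatch: contacts at {strong_inter.bin_size}, "
            f"regions at {egrs[0].region.bin_size}"
        )
    graph = nx.Graph(
        threshold=strong_inter.threshold,
        provenance="original",
        blacklist_applied=False,
        total_bins=layout.total_bins() if layout is not None else None,
    )
    for egr in sorted(egrs, key=lambda e: e.region):
        graph.add_node(
            egr.id,
            region=egr.region,
            node_class=egr.node_class,
            member_genes=frozenset(egr.member_genes),
        )
    owner = _bin_owner_map(graph)
    for row in strong_inter.defined.itertuples(index=False):
        na = owner.get((row.chrom_a, int(row.bin_a)))
        nb = owner.get((row.chrom_b, int(row.bin_b)))
        if na is None or nb is None or na == nb:
            continue
        w = float(row.norm)
        if graph.has_edge(na, nb):
            graph[na][nb]["weight"] = max(graph[na][nb]["weight"], w)
        else:
            graph.add_edge(na, nb, edge_type="inter", weight=w)
    for link in intra:
        if link.region_a not in graph or link.region_b not in graph:
            continue
        if graph.has_edge(link.region_a, link.region_b):
            graph[link.region_a][link.region_b]["intra_support"] = link.support
        else:
            graph.add_edge(
                link.region_a,
                link.region_b,
                edge_type="intra",
                weight=float(link.support),
                intra_support=link.support,
            )
    for node in graph.nodes:
        graph.nodes[node]["isolated"] = graph.degree(node) == 0
    _strong_partner_counts(graph, strong_inter)
    return graph


def blacklist_filter(
    network: nx.Graph,
    blacklist: Iterable[GenomicInterval] = (),
    promiscuity_fraction: float | None = None,
) -> tuple[nx.Graph, list[str]]:
    """Remove blacklisted nodes; report (never auto-remove) promiscuous ones.

    A node overlapping any blacklist interval is deleted with its incident
    edges. When ``promiscuity_fraction`` is given, nodes whose strong-contact
    partner bins exceed that fraction of all genomic bins are returned in the
    report list.
    """
    blacklist = list(blacklist)
    graph = network.copy()
    removed = [
        node
        for node, data in graph.nodes(data=True)
        if any(data["region"].interval().overlaps(iv) for iv in blacklist)
    ]
    graph.remove_nodes_from(removed)
    if removed:
        graph.graph["blacklist_applied"] = True
        # isolation may change once a promiscuous partner disappears
        for node in graph.nodes:
            graph.nodes[node]["isolated"] = graph.degree(node) == 0
    reported: list[str] = []
    if promiscuity_fraction is not None:
        total = graph.graph.get("total_bins")
        if total:
            reported = sorted(
                node
                for node, data in graph.nodes(data=True)
                if data.get("n_partner_bins", 0) / total > promiscuity_fraction
            )
    return graph, reported


def extend_network(
    original: nx.Graph,
    strong_inter: ContactSet,
    layout: GenomeLayout | None = None,
) -> nx.Graph:
    """First-nearest-neighbour extension with amalgamation.

    Isolated original nodes are excluded first. Every bin with a strong
    contact to a constituent bin of a kept node is added; all bins are
    re-amalgamated, so added bins adjacent to an original node merge into it
    (class and gene membership preserved; a chain of novel bins can even
    bridge two original nodes into one). Edges are re-derived from the
    strong contacts; intra edges carry over between the merged nodes.
    """
    kept = [n for n, d in original.nodes(data=True) if not d.get("isolated")]
    sub = original.subgraph(kept)
    old_owner = {
        (d["region"].chrom, label): n
        for n, d in sub.nodes(data=True)
        for label in d["region"].bins()
    }
    original_bins = set(old_owner)
    added: set[tuple[str, int]] = set()
    records = strong_inter.defined
    for row in records.itertuples(index=False):
        a = (row.chrom_a, int(row.bin_a))
        b = (row.chrom_b, int(row.bin_b))
        if a in original_bins and b not in original_bins:
            added.add(b)
        elif b in original_bins and a not in original_bins:
            added.add(a)

    bin_size = strong_inter.bin_size
    runs = amalgamate(original_bins | added, bin_size)
    graph = nx.Graph(
        threshold=strong_inter.threshold,
        provenance="extended",
        blacklist_applied=original.graph.get("blacklist_applied", False),
        total_bins=original.graph.get("total_bins")
        or (layout.total_bins() if layout is not None else None),
    )
    old_to_new: dict[str, str] = {}
    for run in runs:
        member_old = sorted(
            {
                old_owner[(run.chrom, label)]
                for label in run.bins()
                if (run.chrom, label) in old_owner
            }
        )
        classes = [sub.nodes[n]["node_class"] for n in member_old]
        node_class = min(classes, key=_CLASS_RANK.get) if classes else NOVEL
        genes: frozenset[str] = frozenset().union(
            *(sub.nodes[n]["member_genes"] for n in member_old)
        ) if member_old else frozenset()
        novel_bins = tuple(
            sorted(label for label in run.bins() if (run.chrom, label) not in original_bins)
        )
        node_id = run.label()
        graph.add_node(
            node_id,
            region=run,
            node_class=node_class,
            member_genes=genes,
            origin_nodes=tuple(member_old),
            novel_bins=novel_bins,
        )
        for old in member_old:
            old_to_new[old] = node_id

    owner = _bin_owner_map(graph)
    for row in records.itertuples(index=False):
        na = owner.get((row.chrom_a, int(row.bin_a)))
        nb = owner.get((row.chrom_b, int(row.bin_b)))
        if na is None or nb is None or na == nb:
            continue
        w = float(row.norm)
        if graph.has_edge(na, nb):
            graph[na][nb]["weight"] = max(graph[na][nb]["weight"], w)
        else:
            graph.add_edge(na, nb, edge_type="inter", weight=w)
    for u, v, data in sub.edges(data=True):
        if data.get("edge_type") != "intra" and "intra_support" not in data:
            continue
        nu, nv = old_to_new[u], old_to_new[v]
        if nu == nv:
            continue
        support = data.get("intra_support", 0)
        if graph.has_edge(nu, nv):
            graph[nu][nv]["intra_support"] = max(
                graph[nu][nv].get("intra_support", 0), support
            )
        else:
            graph.add_edge(
                nu, nv, edge_type="intra", weight=float(support), intra_support=support
            )
    for node in graph.nodes:
        graph.nodes[node]["isolated"] = graph.degree(node) == 0
    _strong_partner_counts(graph, strong_inter)
    return graph


def components(network: nx.Graph) -> list[set[str]]:
    """Connected components, largest (giant) first; ties by smallest node id."""
    comps = [set(c) for c in nx.connected_components(network)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def isolated_nodes(network: nx.Graph) -> list[str]:
    return sorted(n for n, d in network.nodes(data=True) if d.get("isolated"))
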