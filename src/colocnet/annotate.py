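"""Feature-to-node mapping, GWAS significance flags, ORA and report export.

Genes and SNPs are assigned to network nodes by genomic position: a SNP
belongs to the unique node whose span contains it (node spans are disjoint);
a gene is assigned to every node it overlaps, with an ambiguity flag when
it straddles more than one. SNPs below the genome-wide significance
threshold (p < 5e-8, strict) are flagged; chromosome X SNPs are accepted
but flagged, since GWAS summary sets routinely exclude them while chrX
regions may still appear as network nodes.

A generic upper-tail hypergeometric over-representation test (Bonferroni or
Benjamini-Hochberg adjusted) is provided for user-supplied gene sets.
The report writer emits plain TSV/JSON artifacts and is byte-deterministic
for a fixed run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .analysis import Partition, degree_report
from .egr import GeneAnnotation
from .genome import CoordinateError, GenomeLayout
from .network import NOVEL, components, isolated_nodes

GENOME_WIDE_SIGNIFICANCE = 5e-8


def read_snp_table(path: str | Path) -> pd.DataFrame:
    """TSV with header rsid/chrom/pos/p_value."""
    table = pd.read_csv(path, sep="\t")
    required = ("rsid", "chrom", "pos", "p_value")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing SNP columns {missing}")
    table["pos"] = table["pos"].astype(int)
    if ((table["p_value"] <= 0) | (table["p_value"] > 1)).any():
        raise ValueError(f"{path}: p-values must lie in (0, 1]")
    return table


@dataclass
class NodeAnnotation:
    node_id: str
    genes: tuple[str, ...] = ()
    ambiguous_genes: tuple[str, ...] = ()
    snps: tuple[str, ...] = ()
    n_significant_snps: int = 0
    novel_flag: bool = False


@dataclass
class FeatureMap:
    annotations: dict[str, NodeAnnotation]
    unassigned_genes: tuple[str, ...]
    unassigned_snps: tuple[str, ...]
    flagged_chrx_snps: tuple[str, ...]


def _node_trees(network: nx.Graph) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for node, data in network.nodes(data=True):
        iv = data["region"].interval()
        # IntervalTree is half-open; +1 converts the inclusive end
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end + 1, node)
    return trees


def map_features(
    network: nx.Graph,
    genes: Sequence[GeneAnnotation],
    snps: pd.DataFrame,
    significance: float = GENOME_WIDE_SIGNIFICANCE,
    layout: GenomeLayout | None = None,
    chrx_names: tuple[str, ...] = ("chrX", "X", "23", "chr23"),
) -> FeatureMap:
    """Assign genes (any bp overlap) and SNPs (position) to node spans."""
    trees = _node_trees(network)
    per_node: dict[str, NodeAnnotation] = {
        node: NodeAnnotation(
            node_id=node, novel_flag=data.get("node_class") == NOVEL
        )
        for node, data in network.nodes(data=True)
    }
    gene_hits: dict[str, list[str]] = {n: [] for n in per_node}
    ambiguous: dict[str, set[str]] = {n: set() for n in per_node}
    unassigned_genes: list[str] = []
    for gene in genes:
        tree = trees.get(gene.chrom)
        hits = sorted(h.data for h in tree.overlap(gene.start, gene.end + 1)) if tree else []
        if not hits:
            unassigned_genes.append(gene.symbol)
            continue
        for node in hits:
            gene_hits[node].append(gene.symbol)
            if len(hits) > 1:
                ambiguous[node].add(gene.symbol)

    snp_hits: dict[str, list[str]] = {n: [] for n in per_node}
    sig_counts: dict[str, int] = {n: 0 for n in per_node}
    unassigned_snps: list[str] = []
    flagged_chrx: list[str] = []
    for row in snps.itertuples(index=False):
        chrom, pos = str(row.chrom), int(row.pos)
        if layout is not None:
            layout.check_position(chrom, pos)
        if chrom in chrx_names:
            flagged_chrx.append(str(row.rsid))
        tree = trees.get(chrom)
        hits = sorted(h.data for h in tree.overlap(pos, pos + 1)) if tree else []
        if not hits:
            unassigned_snps.append(str(row.rsid))
            continue
        node = hits[0]  # node spans are disjoint: at most one hit
        snp_hits[node].append(str(row.rsid))
        if row.p_value < significance:
            sig_counts[node] += 1

    for node, ann in per_node.items():
        ann.genes = tuple(sorted(set(gene_hits[node])))
        ann.ambiguous_genes = tuple(sorted(ambiguous[node]))
        ann.snps = tuple(sorted(set(snp_hits[node])))
        ann.n_significant_snps = sig_counts[node]
    return FeatureMap(
        annotations=per_node,
        unassigned_genes=tuple(sorted(set(unassigned_genes))),
        unassigned_snps=tuple(sorted(set(unassigned_snps))),
        flagged_chrx_snps=tuple(sorted(set(flagged_chrx))),
    )


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    overlap: int
    term_size: int
    query_size: int
    universe_size: int
    raw_p: float
    adjusted_p: float
    method: str


def hypergeometric_ora(
    query_genes: set[str] | Sequence[str],
    universe_genes: set[str] | Sequence[str],
    term_sets: Mapping[str, set[str] | Sequence[str]],
    correction: str = "benjamini-hochberg",
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation of each term in the query."""
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query_genes)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    if correction not in ("bonferroni", "benjamini-hochberg", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    terms = sorted(term_sets)
    raw = []
    rows = []
    for term in terms:
        tset = set(term_sets[term]) & universe
        k = len(query & tset)
        # P(X >= k) drawing |query| from universe with |term| successes
        p = float(hypergeom.sf(k - 1, len(universe), len(tset), len(query)))
        raw.append(min(p, 1.0))
        rows.append((term, k, len(tset)))
    if correction == "bonferroni":
        adjusted = np.minimum(np.asarray(raw) * len(raw), 1.0)
    elif correction == "benjamini-hochberg":
        adjusted = multipletests(raw, method="fdr_bh")[1]
    else:
        adjusted = np.asarray(raw)
    results = [
        EnrichmentResult(
            term=term,
            overlap=k,
            term_size=tsize,
            query_size=len(query),
            universe_size=len(universe),
            raw_p=p,
            adjusted_p=float(ap),
            method=correction,
        )
        for (term, k, tsize), p, ap in zip(rows, raw, adjusted)
    ]
    return sorted(results, key=lambda r: (r.adjusted_p, r.raw_p, r.term))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set file: term, description, genes... (tab-separated)."""
    terms: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        terms[parts[0]] = set(parts[2:])
    return terms


# ---------------------------------------------------------------------------
# report bundle


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(
    network: nx.Graph,
    feature_map: FeatureMap,
    partition: Partition | None,
    outdir: str | Path,
    metadata: Mapping | None = None,
    input_paths: Sequence[str | Path] = (),
) -> dict[str, Path]:
    """Write the full report bundle (TSV tables + JSON metadata), deterministically."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    comps = components(network)
    node_component = {
        node: rank + 1 for rank, comp in enumerate(comps) for node in comp
    }
    labels = partition.node_labels() if partition is not None else {}
    degrees = dict(network.degree())

    def fmt(value: float) -> str:
        return repr(round(float(value), 10))

    rows = []
    for node in sorted(network.nodes):
        data = network.nodes[node]
        region = data["region"]
        iv = region.interval()
        ann = feature_map.annotations[node]
        rows.append(
            "\t".join(
                [
                    node,
                    iv.chrom,
                    str(iv.start),
                    str(iv.end),
                    str(region.first_bin),
                    str(region.last_bin),
                    data.get("node_class", ""),
                    str(degrees[node]),
                    str(node_component[node]),
                    labels.get(node, ""),
                    ",".join(ann.genes),
                    ",".join(ann.ambiguous_genes),
                    str(len(ann.snps)),
                    str(ann.n_significant_snps),
                ]
            )
        )
    header = (
        "node\tchrom\tstart\tend\tfirst_bin\tlast_bin\tclass\tdegree\t"
        "component\tcommunity\tgenes\tambiguous_genes\tn_snps\tn_significant_snps"
    )
    written["nodes"] = outdir / "nodes.tsv"
    written["nodes"].write_text("\n".join([header] + rows) + "\n")

    edge_rows = [
        f"{u}\t{v}\t{d.get('edge_type', '')}\t{fmt(d.get('weight', 0.0))}"
        for u, v, d in sorted(
            ((min(u, v), max(u, v), d) for u, v, d in network.edges(data=True))
        )
    ]
    written["edges"] = outdir / "edges.tsv"
    written["edges"].write_text(
        "\n".join(["node_a\tnode_b\ttype\tweight"] + edge_rows) + "\n"
    )

    written["isolated"] = outdir / "isolated_regions.tsv"
    written["isolated"].write_text(
        "\n".join(["node"] + isolated_nodes(network)) + "\n"
    )

    written["degrees"] = outdir / "degree_ranking.tsv"
    written["degrees"].write_text(
        "\n".join(
            ["node\tdegree"] + [f"{n}\t{d}" for n, d in degree_report(network)]
        )
        + "\n"
    )

    if partition is not None:
        comm_rows = []
        for community, label in zip(partition.communities, partition.labels):
            for node in sorted(community):
                ann = feature_map.annotations[node]
                comm_rows.append(
                    f"{label}\t{node}\t{','.join(ann.genes)}\t{len(ann.snps)}"
                )
        written["communities"] = outdir / "communities.tsv"
        written["communities"].write_text(
            "\n".join(["community\tnode\tgenes\tn_snps"] + sorted(comm_rows)) + "\n"
        )

    novel = [
        n for n, d in network.nodes(data=True) if d.get("node_class") == NOVEL
    ]
    novel_genes = sorted(
        {g for n in novel for g in feature_map.annotations[n].genes}
    )
    novel_mb = sum(network.nodes[n]["region"].span_bp() for n in novel) / 1e6
    summary = {
        "novel_region_count": len(novel),
        "novel_total_mb": round(novel_mb, 6),
        "novel_gene_count": len(novel_genes),
        "n_nodes": network.number_of_nodes(),
        "n_edges": network.number_of_edges(),
        "n_components": len(comps),
        "giant_component_size": len(comps[0]) if comps else 0,
    }
    written["summary"] = outdir / "novel_summary.json"
    written["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    meta = dict(metadata or {})
    meta.setdefault("threshold", network.graph.get("threshold"))
    meta["input_digests"] = {
        str(Path(p).name): _digest(Path(p)) for p in sorted(map(str, input_paths))
    }
    meta["unassigned_genes"] = list(feature_map.unassigned_genes)
    meta["unassigned_snps"] = len(feature_map.unassigned_snps)
    meta["chrx_flagged_snps"] = len(feature_map.flagged_chrx_snps)
    written["metadata"] = outdir / "run_metadata.json"
    written["metadata"].write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return written
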