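"""End-to-end orchestration with plain-text checkpoints and a run config.

Stage order: (optional) cell-line selection -> EGR construction -> contact
thresholding -> original network -> blacklist + first-neighbour extension ->
community analysis -> annotation and report. Each stage writes plain TSV /
JSON checkpoints into the output directory, so any stage's input can be
inspected or substituted, and a rerun with ``resume=True`` reloads finished
stages and reproduces the remaining ones byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd
import yaml

from . import analysis, annotate, contacts, egr, eqtl, genome, network

logger = logging.getLogger("colocnet")

STAGES = ("cellline", "egrs", "contacts", "original", "extended", "analyze", "annotate")


@dataclass
class RunConfig:
    """Inputs and parameters of one run; defaults match the method's standard values."""

    chrom_sizes: str
    contacts_dir: str
    norm_dir: str
    capture_promoter_other: str
    capture_promoter_promoter: str
    genes: str
    outdir: str
    snps: str | None = None
    eqtl: str | None = None
    eqtl_contacts_dir: str | None = None
    cell_lines: list[str] = field(default_factory=list)
    bin_size: int = 100_000
    threshold: float | None = 64.0
    top_fraction: float | None = None
    strong_p_cut: float = 1e-6
    significance: float = 5e-8
    blacklist: str | None = None
    promiscuity_fraction: float | None = 0.1
    auto_blacklist_promiscuous: bool = False
    min_community_size: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.threshold is None) == (self.top_fraction is None):
            raise contacts.ConfigError(
                "exactly one of threshold / top_fraction must be set"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


@dataclass
class PipelineResult:
    layout: genome.GenomeLayout
    egrs: list
    intra: list
    strong: contacts.ContactSet
    original: nx.Graph
    extended: nx.Graph
    analysis_graph: nx.Graph
    promiscuous: list[str]
    partition: analysis.Partition | None
    hierarchical: analysis.Partition | None
    feature_map: annotate.FeatureMap | None
    cell_line_scores: list[eqtl.CellLineScore]
    selected_cell_line: str | None
    report_paths: dict[str, Path]
    threshold_used: float


# ---------------------------------------------------------------------------
# graph checkpoints


def write_graph_checkpoint(graph: nx.Graph, stem: Path) -> None:
    node_rows = ["node\tchrom\tfirst_bin\tlast_bin\tclass\tisolated\tn_partner_bins\tgenes"]
    for node in sorted(graph.nodes):
        data = graph.nodes[node]
        region = data["region"]
        node_rows.append(
            "\t".join(
                [
                    node,
                    region.chrom,
                    str(region.first_bin),
                    str(region.last_bin),
                    data.get("node_class", ""),
                    str(int(bool(data.get("isolated")))),
                    str(data.get("n_partner_bins", 0)),
                    ",".join(sorted(data.get("member_genes", ()))),
                ]
            )
        )
    Path(f"{stem}_nodes.tsv").write_text("\n".join(node_rows) + "\n")
    edge_rows = ["node_a\tnode_b\ttype\tweight\tintra_support"]
    for u, v, data in sorted(
        (min(u, v), max(u, v), d) for u, v, d in graph.edges(data=True)
    ):
        edge_rows.append(
            f"{u}\t{v}\t{data.get('edge_type', '')}\t{data.get('weight', 0.0)!r}\t"
            f"{data.get('intra_support', '')}"
        )
    Path(f"{stem}_edges.tsv").write_text("\n".join(edge_rows) + "\n")
    meta = {k: v for k, v in graph.graph.items()}
    Path(f"{stem}_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_graph_checkpoint(stem: Path, bin_size: int) -> nx.Graph:
    meta = json.loads(Path(f"{stem}_meta.json").read_text())
    graph = nx.Graph(**meta)
    nodes = pd.read_csv(f"{stem}_nodes.tsv", sep="\t", keep_default_na=False)
    for node, chrom, first_bin, last_bin, cls, isolated, n_partner, genes in (
        nodes.itertuples(index=False, name=None)
    ):
        graph.add_node(
            str(node),
            region=genome.BinnedRegion(str(chrom), int(first_bin), int(last_bin), bin_size),
            node_class=str(cls),
            isolated=bool(int(isolated)),
            n_partner_bins=int(n_partner),
            member_genes=frozenset(g for g in str(genes).split(",") if g),
        )
    edges = pd.read_csv(f"{stem}_edges.tsv", sep="\t", keep_default_na=False)
    for row in edges.itertuples(index=False):
        attrs = {"edge_type": str(row.type), "weight": float(row.weight)}
        if str(row.intra_support):
            attrs["intra_support"] = int(float(row.intra_support))
        graph.add_edge(str(row.node_a), str(row.node_b), **attrs)
    return graph


def export_graphml(graph: nx.Graph, path: str | Path) -> None:
    """GraphML export for interactive viewers (scalar attributes only)."""
    clean = nx.Graph()
    for node, data in graph.nodes(data=True):
        region = data["region"]
        clean.add_node(
            node,
            chrom=region.chrom,
            start=region.interval().start,
            end=region.interval().end,
            node_class=data.get("node_class", ""),
            genes=",".join(sorted(data.get("member_genes", ()))),
        )
    for u, v, data in graph.edges(data=True):
        clean.add_edge(
            u, v, edge_type=data.get("edge_type", ""), weight=float(data.get("weight", 0))
        )
    nx.write_graphml(clean, str(path))


# ---------------------------------------------------------------------------
# stages


def _chrom_pairs(layout: genome.GenomeLayout):
    names = layout.chrom_names
    for i, ca in enumerate(names):
        for cb in names[i + 1 :]:
            yield ca, cb


def load_strong_contacts(
    config: RunConfig, layout: genome.GenomeLayout
) -> tuple[contacts.ContactSet, float]:
    frames = []
    cdir = Path(config.contacts_dir)
    for ca, cb in _chrom_pairs(layout):
        path = cdir / f"{ca}_{cb}.txt"
        if path.exists():
            frames.append(contacts.read_sparse_contacts(path, ca, cb, config.bin_size))
    if not frames:
        raise contacts.ConfigError(f"no contact files found in {cdir}")
    df = pd.concat(frames, ignore_index=True)
    vectors = {}
    for chrom in layout.chrom_names:
        vpath = Path(config.norm_dir) / f"{chrom}.txt"
        if vpath.exists():
            vectors[chrom] = contacts.read_norm_vector(vpath, layout.n_bins(chrom))
    df = contacts.apply_normalization(df, vectors)
    cset = contacts.ContactSet(
        df,
        config.bin_size,
        threshold=config.threshold if config.threshold is not None else 64.0,
        top_fraction=config.top_fraction if config.top_fraction is not None else 0.0005,
    )
    if config.top_fraction is not None:
        threshold = contacts.threshold_from_quantile(cset, config.top_fraction)
    else:
        threshold = float(config.threshold)
    strong = contacts.strong_contacts(cset, threshold)
    logger.info(
        "contacts: %d records, threshold %.4g, %d strong", len(cset), threshold, len(strong)
    )
    return strong, threshold


def select_cell_line(
    config: RunConfig, layout: genome.GenomeLayout
) -> tuple[str | None, list[eqtl.CellLineScore]]:
    if config.eqtl is None or config.eqtl_contacts_dir is None or not config.cell_lines:
        return None, []
    pairs = eqtl.read_eqtl_table(config.eqtl)
    pairs = eqtl.filter_and_dedupe(eqtl.bin_pairs(pairs))
    scores = []
    threshold = config.threshold if config.threshold is not None else 64.0
    for line_name in config.cell_lines:
        line_dir = Path(config.eqtl_contacts_dir) / line_name
        per_scale: dict[int, contacts.ContactSet] = {}
        for scale in eqtl.SCALES:
            frames = []
            for chrom in layout.chrom_names:
                path = line_dir / f"{chrom}_{scale}.txt"
                if path.exists():
                    frames.append(
                        contacts.read_sparse_contacts(path, chrom, chrom, scale)
                    )
            if frames:
                df = pd.concat(frames, ignore_index=True)
                # these tables carry pre-normalized counts
                per_scale[scale] = contacts.ContactSet(
                    df.assign(norm=df["raw"]), scale, threshold=threshold
                )
        if not per_scale:
            continue
        scores.append(
            eqtl.score_cell_line(
                line_name, pairs, per_scale, threshold, config.strong_p_cut
            )
        )
    if not scores:
        return None, []
    ranking = eqtl.rank_cell_lines(scores)
    logger.info(
        "cell line selected: %s (strong eQTL fraction %.3f)",
        ranking[0].cell_line,
        ranking[0].strong_eqtl_fraction,
    )
    return ranking[0].cell_line, ranking


def build_regions(config: RunConfig, layout: genome.GenomeLayout):
    genes = egr.read_gene_table(config.genes)
    capture = pd.concat(
        [
            contacts.read_capture_interactions(
                config.capture_promoter_other, "promoter-other"
            ),
            contacts.read_capture_interactions(
                config.capture_promoter_promoter, "promoter-promoter"
            ),
        ],
        ignore_index=True,
    )
    guilty = [g for g in genes if g.guilty]
    regulatory = []
    for gene in guilty:
        regulatory.extend(egr.regulatory_boundaries(capture, gene.symbol))
    egrs = egr.build_egrs(guilty, regulatory, config.bin_size, layout)
    links = egr.intra_links(egrs, capture)
    logger.info(
        "EGRs: %d guilty genes -> %d regions (%d guilty-EGR), %d intra links",
        len(guilty),
        len(egrs),
        sum(1 for e in egrs if e.node_class == "guilty-EGR"),
        len(links),
    )
    return genes, egrs, links


def _read_blacklist(config: RunConfig) -> list[genome.GenomicInterval]:
    if config.blacklist is None:
        return []
    return [iv for iv, _ in genome.read_bed(config.blacklist)]


def run(
    config: RunConfig, resume: bool = False, stop_after: str | None = None
) -> PipelineResult:
    """Execute the pipeline, writing checkpoints and the final report bundle."""
    if stop_after is not None and stop_after not in STAGES:
        raise contacts.ConfigError(f"unknown stage {stop_after!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = genome.read_chrom_sizes(config.chrom_sizes, config.bin_size)

    def done(stage: str) -> bool:
        return stop_after == stage

    # -- cell line -------------------------------------------------------------
    selected, scores = select_cell_line(config, layout)
    if scores:
        rows = ["cell_line\tfraction_nonzero\tstrong_eqtl_fraction\tlog_fisher_p"]
        for s in scores:
            rows.append(
                f"{s.cell_line}\t{s.fraction_nonzero!r}\t"
                f"{s.strong_eqtl_fraction!r}\t{s.log_fisher_p!r}"
            )
        (outdir / "cellline_scores.tsv").write_text("\n".join(rows) + "\n")
        (outdir / "selected_cell_line.json").write_text(
            json.dumps({"selected": selected}, sort_keys=True) + "\n"
        )
    empty = PipelineResult(
        layout, [], [], None, None, None, None, [], None, None, None,
        scores, selected, {}, float("nan"),
    )
    if done("cellline"):
        return empty

    # -- EGRs ------------------------------------------------------------------
    genes, egrs, links = build_regions(config, layout)
    egr_rows = ["region\tchrom\tstart\tend\tfirst_bin\tlast_bin\tclass\tgenes"]
    for e in egrs:
        iv = e.region.interval()
        egr_rows.append(
            f"{e.id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{e.region.first_bin}\t"
            f"{e.region.last_bin}\t{e.node_class}\t{','.join(sorted(e.member_genes))}"
        )
    (outdir / "egrs.tsv").write_text("\n".join(egr_rows) + "\n")
    (outdir / "intra_links.tsv").write_text(
        "\n".join(
            ["region_a\tregion_b\tsupport"]
            + [f"{l.region_a}\t{l.region_b}\t{l.support}" for l in links]
        )
        + "\n"
    )
    empty.egrs, empty.intra = egrs, links
    if done("egrs"):
        return empty

    # -- strong contacts -------------------------------------------------------
    strong_path = outdir / "strong_contacts.tsv"
    if resume and strong_path.exists():
        df = pd.read_csv(strong_path, sep="\t")
        meta = json.loads((outdir / "strong_contacts_meta.json").read_text())
        threshold_used = meta["threshold"]
        strong = contacts.ContactSet(df, config.bin_size, threshold=threshold_used)
    else:
        strong, threshold_used = load_strong_contacts(config, layout)
        strong.records.to_csv(strong_path, sep="\t", index=False)
        (outdir / "strong_contacts_meta.json").write_text(
            json.dumps({"threshold": threshold_used}, sort_keys=True) + "\n"
        )
    empty.strong = strong
    empty.threshold_used = threshold_used
    if done("contacts"):
        return empty

    # -- original network ------------------------------------------------------
    orig_stem = outdir / "original"
    if resume and Path(f"{orig_stem}_meta.json").exists():
        original = read_graph_checkpoint(orig_stem, config.bin_size)
    else:
        original = network.build_original_network(egrs, strong, links, layout)
        write_graph_checkpoint(original, orig_stem)
    logger.info(
        "original network: %d nodes, %d edges, %d isolated",
        original.number_of_nodes(),
        original.number_of_edges(),
        len(network.isolated_nodes(original)),
    )
    empty.original = original
    if done("original"):
        return empty

    # -- extension + blacklist -------------------------------------------------
    extended = network.extend_network(original, strong, layout)
    write_graph_checkpoint(extended, outdir / "extended")
    export_graphml(extended, outdir / "extended.graphml")
    blacklist = _read_blacklist(config)
    analysis_graph, promiscuous = network.blacklist_filter(
        extended, blacklist, config.promiscuity_fraction
    )
    (outdir / "promiscuous_nodes.tsv").write_text(
        "\n".join(["node"] + promiscuous) + "\n"
    )
    if config.auto_blacklist_promiscuous and promiscuous:
        extra = [
            extended.nodes[n]["region"].interval() for n in promiscuous
        ]
        analysis_graph, _ = network.blacklist_filter(analysis_graph, extra, None)
    logger.info(
        "extended network: %d nodes, %d edges; analysed: %d nodes",
        extended.number_of_nodes(),
        extended.number_of_edges(),
        analysis_graph.number_of_nodes(),
    )
    empty.extended = extended
    empty.analysis_graph = analysis_graph
    empty.promiscuous = promiscuous
    if done("extended"):
        return empty

    # -- communities -----------------------------------------------------------
    partition = analysis.detect_communities(analysis_graph)
    hierarchical = analysis.subdivide(
        analysis_graph, partition, config.min_community_size
    )
    comps = network.components(analysis_graph)
    logger.info(
        "components: %d (giant %d nodes); communities: %d (Q=%.4f)",
        len(comps),
        len(comps[0]) if comps else 0,
        len(partition),
        partition.modularity_q,
    )
    empty.partition = partition
    empty.hierarchical = hierarchical
    if done("analyze"):
        return empty

    # -- annotation + report ---------------------------------------------------
    snps = (
        annotate.read_snp_table(config.snps)
        if config.snps is not None
        else pd.DataFrame(columns=["rsid", "chrom", "pos", "p_value"])
    )
    feature_map = annotate.map_features(
        analysis_graph, genes, snps, config.significance
    )
    metadata = {
        "seed": config.seed,
        "bin_size": config.bin_size,
        "threshold_used": threshold_used,
        "significance": config.significance,
        "strong_p_cut": config.strong_p_cut,
        "min_community_size": config.min_community_size,
        "selected_cell_line": selected,
    }
    inputs = [config.chrom_sizes, config.genes]
    if config.snps:
        inputs.append(config.snps)
    report_paths = annotate.write_report(
        analysis_graph,
        feature_map,
        hierarchical,
        outdir / "report",
        metadata,
        inputs,
    )
    empty.feature_map = feature_map
    empty.report_paths = report_paths
    return empty


def bundle_config(bundle, outdir: Path, **overrides) -> RunConfig:
    """RunConfig pointing at a generated synthetic bundle."""
    manifest = bundle.manifest
    defaults = dict(
        chrom_sizes=str(bundle.chrom_sizes),
        contacts_dir=str(bundle.root / "contacts"),
        norm_dir=str(bundle.root / "norm"),
        capture_promoter_other=str(bundle.capture_promoter_other),
        capture_promoter_promoter=str(bundle.capture_promoter_promoter),
        genes=str(bundle.genes),
        snps=str(bundle.snps),
        eqtl=str(bundle.eqtl),
        eqtl_contacts_dir=str(bundle.root / "eqtl_contacts"),
        cell_lines=list(manifest["cell_lines"]),
        bin_size=manifest["bin_size"],
        threshold=manifest["threshold"],
        promiscuity_fraction=manifest["promiscuity_fraction"],
        auto_blacklist_promiscuous=True,
        seed=manifest["seed"],
        outdir=str(outdir),
    )
    defaults.update(overrides)
    return RunConfig(**defaults)


def recovery_trial(seed: int, workdir: str | Path):
    """Generate the default scenario at ``seed``, run the pipeline, score recovery."""
    from .synthetic import SyntheticScenario, evaluate_recovery, generate

    workdir = Path(workdir)
    bundle = generate(SyntheticScenario(seed=seed), workdir / "bundle")
    config = bundle_config(bundle, workdir / "run")
    result = run(config)
    metrics = evaluate_recovery(
        result.extended,
        result.partition,
        result.original,
        result.promiscuous,
        result.selected_cell_line,
        bundle.manifest,
    )
    return result, metrics, bundle
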