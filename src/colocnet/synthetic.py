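"""Seeded toy-data generator with planted ground truth.

The generator emulates the statistical structure the guilt-by-proxy method
relies on, at desk scale:

* sparse inter-chromosomal contact dumps with a geometric-tailed count
  distribution, so that strong contacts (normalized count >= 64) are a rare
  upper tail — about 0.05% of records under the default scenario;
* two planted inter-chromosomal modules: small sets of bins, spread over
  the three toy chromosomes, whose cross-chromosome bin pairs interact
  strongly with probability 0.9 (0.02 between modules), each module bin
  housing one "guilty" gene;
* planted isolated guilty genes whose bins, by construction, carry no
  strong contact at all;
* one planted promiscuous hub bin contacting most other-chromosome bins,
  emulating the kind of assembly artifact that must be blacklisted;
* Capture Hi-C tables giving each guilty gene a promoter/enhancer footprint
  inside its own bin, plus promoter-promoter interactions within modules;
* a GWAS SNP table with a handful of planted genome-wide-significant SNPs
  inside module bins;
* an eQTL table and per-"cell line" intra-chromosomal contact tables in
  which low-p eQTL pairs land on strong contacts much more often for the
  planted best cell line than for the others (the intra tables carry
  pre-normalized counts, as processed dumps do).

Every file round-trips through the package readers, and one pseudo-random
stream per file type is derived from the master seed so adding a file type
never perturbs existing ones. The same seed always yields a byte-identical
bundle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contacts import (
    ConfigError,
    ContactSet,
    apply_normalization,
    read_norm_vector,
    read_sparse_contacts,
)
from .eqtl import assign_scale
from .genome import GenomeLayout, pos_to_bin

Bin = tuple[str, int]

DEFAULT_MODULES: tuple[tuple[Bin, ...], ...] = (
    (("chr1", 10), ("chr1", 20), ("chr2", 10), ("chr2", 20), ("chr3", 10)),
    (("chr1", 60), ("chr1", 70), ("chr2", 60), ("chr3", 60), ("chr3", 70)),
)


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters and planted ground truth of one synthetic study."""

    seed: int = 0
    chrom_names: tuple[str, ...] = ("chr1", "chr2", "chr3")
    chrom_length: int = 10_000_000
    bin_size: int = 100_000
    threshold: float = 64.0
    top_fraction: float = 0.0005
    modules: tuple[tuple[Bin, ...], ...] = DEFAULT_MODULES
    module_within_prob: float = 0.9
    module_between_prob: float = 0.02
    isolated_gene_bins: tuple[Bin, ...] = (("chr1", 90), ("chr2", 90))
    hub_bins: tuple[Bin, ...] = (("chr1", 95),)
    hub_contact_prob: float = 0.9
    background_geom_p: float = 0.35
    unmappable_bins: tuple[int, ...] = (3, 97)
    n_background_genes: int = 60
    n_snps: int = 500
    n_significant_snps: int = 6
    n_eqtl_pairs: int = 400
    eqtl_low_p_fraction: float = 0.3
    cell_lines: tuple[str, ...] = ("GM12878", "IMR90", "HMEC")
    eqtl_enrichment: tuple[tuple[str, float], ...] = (
        ("GM12878", 0.61),
        ("IMR90", 0.10),
        ("HMEC", 0.098),
    )
    eqtl_background_strong: float = 0.05
    eqtl_nonzero_prob: float = 0.97
    promiscuity_fraction: float = 0.1

    def __post_init__(self) -> None:
        layout = self.layout()
        module_bins = {b for module in self.modules for b in module}
        hub = set(self.hub_bins)
        if module_bins & hub:
            raise ConfigError("planted modules overlap hub bins")
        if module_bins & set(self.isolated_gene_bins):
            raise ConfigError("planted modules overlap isolated gene bins")
        for chrom, label in module_bins | hub | set(self.isolated_gene_bins):
            if chrom not in self.chrom_names or not 1 <= label <= layout.n_bins(chrom):
                raise ConfigError(f"planted bin {chrom}:{label} outside layout")
        for prob in (
            self.module_within_prob,
            self.module_between_prob,
            self.hub_contact_prob,
            self.eqtl_low_p_fraction,
            self.eqtl_background_strong,
            self.eqtl_nonzero_prob,
        ):
            if not 0 <= prob <= 1:
                raise ConfigError(f"probability outside [0, 1]: {prob}")

    def layout(self) -> GenomeLayout:
        return GenomeLayout(
            self.chrom_names,
            tuple(self.chrom_length for _ in self.chrom_names),
            self.bin_size,
        )

    @property
    def best_cell_line(self) -> str:
        return max(self.eqtl_enrichment, key=lambda item: item[1])[0]

    def rng(self, stream: int) -> np.random.Generator:
        # one independent stream per file type
        return np.random.default_rng([self.seed, stream])


@dataclass
class SyntheticBundle:
    """Paths of a generated input bundle plus its ground-truth manifest."""

    root: Path
    chrom_sizes: Path
    contact_files: dict[tuple[str, str], Path]
    norm_files: dict[str, Path]
    capture_promoter_other: Path
    capture_promoter_promoter: Path
    genes: Path
    snps: Path
    eqtl: Path
    eqtl_contact_dirs: dict[str, Path]
    manifest_path: Path
    manifest: dict

    def all_input_paths(self) -> list[Path]:
        paths = [self.chrom_sizes, self.capture_promoter_other,
                 self.capture_promoter_promoter, self.genes, self.snps, self.eqtl]
        paths += list(self.contact_files.values()) + list(self.norm_files.values())
        return paths


def _format_count(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(float(value))


def _gene_body(chrom: str, label: int, bin_size: int) -> tuple[int, int]:
    start = (label - 1) * bin_size + 30_001
    return start, start + 19_999


def generate(scenario: SyntheticScenario, outdir: str | Path) -> SyntheticBundle:
    """Write the full input bundle and ground-truth manifest under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    layout = scenario.layout()
    bs = scenario.bin_size
    chroms = scenario.chrom_names

    chrom_sizes = out / "chrom.sizes"
    chrom_sizes.write_text(
        "".join(f"{c}\t{layout.length_of(c)}\n" for c in chroms)
    )

    # --- normalization vectors ------------------------------------------------
    rng_norm = scenario.rng(6)
    norm_dir = out / "norm"
    norm_dir.mkdir(exist_ok=True)
    factors: dict[str, np.ndarray] = {}
    norm_files: dict[str, Path] = {}
    for chrom in chroms:
        vec = np.exp(rng_norm.normal(0.0, 0.15, size=layout.n_bins(chrom)))
        for label in scenario.unmappable_bins:
            if 1 <= label <= len(vec):
                vec[label - 1] = np.nan
        factors[chrom] = vec
        path = norm_dir / f"{chrom}.txt"
        path.write_text("".join(f"{v:.10g}\n" for v in vec))
        norm_files[chrom] = path

    # --- inter-chromosomal contacts ------------------------------------------
    rng_c = scenario.rng(1)
    module_of: dict[Bin, int] = {
        b: i for i, module in enumerate(scenario.modules) for b in module
    }
    protected = set(scenario.isolated_gene_bins)
    hub_set = set(scenario.hub_bins)

    def planted_norm() -> float:
        return 70.0 + rng_c.exponential(30.0)

    contacts_dir = out / "contacts"
    contacts_dir.mkdir(exist_ok=True)
    contact_files: dict[tuple[str, str], Path] = {}
    for i, ca in enumerate(chroms):
        for cb in chroms[i + 1 :]:
            na, nb = layout.n_bins(ca), layout.n_bins(cb)
            raw = rng_c.geometric(scenario.background_geom_p, size=(na, nb)).astype(float)
            fa, fb = factors[ca], factors[cb]
            # cap counts on protected (planted-isolated) bins so no strong
            # contact can ever touch them
            for chrom, label in protected:
                if chrom == ca:
                    cap = np.floor(
                        (scenario.threshold - 1.0) * fa[label - 1] * fb
                    )
                    raw[label - 1, :] = np.minimum(raw[label - 1, :], np.nan_to_num(cap, nan=1.0))
                elif chrom == cb:
                    cap = np.floor(
                        (scenario.threshold - 1.0) * fa * fb[label - 1]
                    )
                    raw[:, label - 1] = np.minimum(raw[:, label - 1], np.nan_to_num(cap, nan=1.0))

            def plant(bin_a: int, bin_b: int) -> None:
                f = fa[bin_a - 1] * fb[bin_b - 1]
                if math.isnan(f) or f <= 0:
                    return
                raw[bin_a - 1, bin_b - 1] = max(1.0, round(planted_norm() * f))

            # module structure
            bins_a = [b for b in module_of if b[0] == ca]
            bins_b = [b for b in module_of if b[0] == cb]
            for a in sorted(bins_a):
                for b in sorted(bins_b):
                    same = module_of[a] == module_of[b]
                    prob = (
                        scenario.module_within_prob
                        if same
                        else scenario.module_between_prob
                    )
                    if rng_c.random() < prob:
                        plant(a[1], b[1])
            # promiscuous hub
            for chrom, label in sorted(hub_set):
                if chrom == ca:
                    partners = [
                        j + 1
                        for j in range(nb)
                        if (cb, j + 1) not in protected
                        and not math.isnan(fb[j])
                    ]
                    for partner in partners:
                        if rng_c.random() < scenario.hub_contact_prob:
                            plant(label, partner)
                elif chrom == cb:
                    partners = [
                        j + 1
                        for j in range(na)
                        if (ca, j + 1) not in protected
                        and not math.isnan(fa[j])
                    ]
                    for partner in partners:
                        if rng_c.random() < scenario.hub_contact_prob:
                            plant(partner, label)

            path = contacts_dir / f"{ca}_{cb}.txt"
            lines = []
            for bin_a in range(1, na + 1):
                row = raw[bin_a - 1]
                for bin_b in range(1, nb + 1):
                    count = row[bin_b - 1]
                    if count >= 1:
                        lines.append(
                            f"{(bin_a - 1) * bs} {(bin_b - 1) * bs} {_format_count(count)}"
                        )
            path.write_text("\n".join(lines) + "\n")
            contact_files[(ca, cb)] = path

    # --- genes ----------------------------------------------------------------
    rng_g = scenario.rng(3)
    gene_rows = []
    module_genes: dict[int, list[str]] = {i: [] for i in range(len(scenario.modules))}
    idx = 0
    for mod_idx, module in enumerate(scenario.modules):
        for chrom, label in module:
            idx += 1
            symbol = f"GUILTY{idx}"
            start, end = _gene_body(chrom, label, bs)
            gene_rows.append((f"G{idx:04d}", symbol, chrom, start, end, "+", 1))
            module_genes[mod_idx].append(symbol)
    isolated_genes = []
    for chrom, label in scenario.isolated_gene_bins:
        idx += 1
        symbol = f"LONER{idx}"
        start, end = _gene_body(chrom, label, bs)
        gene_rows.append((f"G{idx:04d}", symbol, chrom, start, end, "+", 1))
        isolated_genes.append({"symbol": symbol, "chrom": chrom, "bin": label})
    for k in range(scenario.n_background_genes):
        idx += 1
        chrom = chroms[int(rng_g.integers(len(chroms)))]
        start = int(rng_g.integers(1, layout.length_of(chrom) - 40_000))
        end = start + int(rng_g.integers(5_000, 30_000))
        gene_rows.append((f"G{idx:04d}", f"BG{k+1}", chrom, start, end, "+", 0))
    genes_path = out / "genes.tsv"
    genes_df = pd.DataFrame(
        gene_rows, columns=["gene_id", "symbol", "chrom", "start", "end", "strand", "guilty"]
    )
    genes_df.to_csv(genes_path, sep="\t", index=False)

    # --- capture Hi-C ---------------------------------------------------------
    guilty = genes_df[genes_df["guilty"] == 1]
    po_rows, pp_rows = [], []
    for row in guilty.itertuples(index=False):
        tss = int(row.start)
        bait1 = (tss - 2_000, tss + 500)
        bait2 = (tss - 500, tss + 2_500)
        bin_start = (pos_to_bin(tss, bs) - 1) * bs
        enh1 = (bin_start + 60_001, bin_start + 64_000)
        enh2 = (bin_start + 70_001, bin_start + 74_000)
        for bait, enh in ((bait1, enh1), (bait2, enh2)):
            po_rows.append(
                (row.chrom, bait[0], bait[1], row.symbol,
                 row.chrom, enh[0], enh[1], "", 6.0)
            )
    # promoter-promoter within modules, same chromosome (intra links)
    for mod_idx, module in enumerate(scenario.modules):
        by_chrom: dict[str, list[Bin]] = {}
        for b in module:
            by_chrom.setdefault(b[0], []).append(b)
        symbol_of_bin = {
            (b[0], b[1]): module_genes[mod_idx][j]
            for j, b in enumerate(module)
        }
        for chrom, bins in sorted(by_chrom.items()):
            bins = sorted(bins)
            for a, b in zip(bins, bins[1:]):
                sa, sb = symbol_of_bin[a], symbol_of_bin[b]
                ga = guilty[guilty["symbol"] == sa].iloc[0]
                gb = guilty[guilty["symbol"] == sb].iloc[0]
                pp_rows.append(
                    (chrom, int(ga.start) - 2_000, int(ga.start) + 2_500, sa,
                     chrom, int(gb.start) - 2_000, int(gb.start) + 2_500, sb, 5.0)
                )
    capture_cols = [
        "chrom_bait", "start_bait", "end_bait", "gene_bait",
        "chrom_other", "start_other", "end_other", "gene_other", "score",
    ]
    po_path = out / "capture_promoter_other.tsv"
    pp_path = out / "capture_promoter_promoter.tsv"
    pd.DataFrame(po_rows, columns=capture_cols).to_csv(po_path, sep="\t", index=False)
    pd.DataFrame(pp_rows, columns=capture_cols).to_csv(pp_path, sep="\t", index=False)

    # --- SNPs -----------------------------------------------------------------
    rng_s = scenario.rng(4)
    snp_rows = []
    module_bins = sorted(module_of)
    for k in range(scenario.n_significant_snps):
        chrom, label = module_bins[k % len(module_bins)]
        pos = (label - 1) * bs + int(rng_s.integers(1, bs))
        p = 10.0 ** rng_s.uniform(-9.5, -7.35)  # always < 5e-8
        snp_rows.append((f"rsSIG{k+1}", chrom, pos, p))
    for k in range(scenario.n_snps):
        chrom = chroms[int(rng_s.integers(len(chroms)))]
        pos = int(rng_s.integers(1, layout.length_of(chrom)))
        p = 10.0 ** rng_s.uniform(-6.3, -0.002)  # always > 5e-8
        snp_rows.append((f"rs{k+1}", chrom, pos, p))
    snps_path = out / "snps.tsv"
    pd.DataFrame(snp_rows, columns=["rsid", "chrom", "pos", "p_value"]).to_csv(
        snps_path, sep="\t", index=False
    )

    # --- eQTL table and per-cell-line intra contacts --------------------------
    rng_e = scenario.rng(5)
    eqtl_rows = []
    for k in range(scenario.n_eqtl_pairs):
        chrom = chroms[int(rng_e.integers(len(chroms)))]
        bucket = int(rng_e.integers(3))
        if bucket == 0:
            d = int(rng_e.integers(2_000, 90_000))
        elif bucket == 1:
            d = int(rng_e.integers(150_000, 900_000))
        else:
            d = int(rng_e.integers(1_100_000, 4_000_000))
        snp_pos = int(rng_e.integers(1, layout.length_of(chrom) - d))
        target_pos = snp_pos + d
        low = rng_e.random() < scenario.eqtl_low_p_fraction
        p = 10.0 ** rng_e.uniform(-12, -6.2) if low else 10.0 ** rng_e.uniform(-5.8, -0.05)
        eqtl_rows.append(
            (f"eqtl{k+1}", chrom, snp_pos, f"EQG{k+1}", chrom, target_pos, p, "aveALL")
        )
    eqtl_path = out / "eqtl.tsv"
    pd.DataFrame(
        eqtl_rows,
        columns=["snp_id", "snp_chrom", "snp_pos", "target_gene",
                 "target_chrom", "target_pos", "p_value", "tissue"],
    ).to_csv(eqtl_path, sep="\t", index=False)

    enrichment = dict(scenario.eqtl_enrichment)
    eqtl_contact_dirs: dict[str, Path] = {}
    for line_name in scenario.cell_lines:
        q = enrichment[line_name]
        line_dir = out / "eqtl_contacts" / line_name
        line_dir.mkdir(parents=True, exist_ok=True)
        eqtl_contact_dirs[line_name] = line_dir
        records: dict[tuple[str, int], dict[tuple[int, int], float]] = {}
        for _, chrom, snp_pos, _, _, target_pos, p, _ in eqtl_rows:
            scale = assign_scale(snp_pos, target_pos)
            lo, hi = sorted((pos_to_bin(snp_pos, scale), pos_to_bin(target_pos, scale)))
            if lo == hi:
                continue
            on_strong_p = q if p <= 1e-6 else scenario.eqtl_background_strong
            u = rng_e.random()
            if u < on_strong_p:
                norm = float(rng_e.uniform(70, 200))
            elif rng_e.random() < scenario.eqtl_nonzero_prob:
                norm = float(rng_e.uniform(1, 40))
            else:
                continue
            records.setdefault((chrom, scale), {})[(lo, hi)] = norm
        # background contact pairs filling the non-eQTL cells of the table
        for chrom in chroms:
            for scale in (10_000, 100_000, 1_000_000):
                n_bins = -(-layout.length_of(chrom) // scale)
                grid = records.setdefault((chrom, scale), {})
                for _ in range(30):
                    lo = int(rng_e.integers(1, n_bins))
                    hi = int(rng_e.integers(lo + 1, n_bins + 1))
                    grid.setdefault((lo, hi), float(rng_e.uniform(1, 40)))
                for _ in range(2):
                    lo = int(rng_e.integers(1, n_bins))
                    hi = int(rng_e.integers(lo + 1, n_bins + 1))
                    grid.setdefault((lo, hi), float(rng_e.uniform(70, 200)))
        for (chrom, scale), grid in sorted(records.items()):
            path = line_dir / f"{chrom}_{scale}.txt"
            lines = [
                f"{(lo - 1) * scale} {(hi - 1) * scale} {_format_count(v)}"
                for (lo, hi), v in sorted(grid.items())
            ]
            path.write_text("\n".join(lines) + "\n")

    manifest = {
        "seed": scenario.seed,
        "bin_size": bs,
        "threshold": scenario.threshold,
        "top_fraction": scenario.top_fraction,
        "chrom_names": list(chroms),
        "chrom_length": scenario.chrom_length,
        "modules": [
            [[chrom, label] for chrom, label in module] for module in scenario.modules
        ],
        "isolated_genes": isolated_genes,
        "hub_bins": [[chrom, label] for chrom, label in scenario.hub_bins],
        "best_cell_line": scenario.best_cell_line,
        "cell_lines": list(scenario.cell_lines),
        "significant_snps": [r[0] for r in snp_rows if r[0].startswith("rsSIG")],
        "module_within_prob": scenario.module_within_prob,
        "module_between_prob": scenario.module_between_prob,
        "promiscuity_fraction": scenario.promiscuity_fraction,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return SyntheticBundle(
        root=out,
        chrom_sizes=chrom_sizes,
        contact_files=contact_files,
        norm_files=norm_files,
        capture_promoter_other=po_path,
        capture_promoter_promoter=pp_path,
        genes=genes_path,
        snps=snps_path,
        eqtl=eqtl_path,
        eqtl_contact_dirs=eqtl_contact_dirs,
        manifest_path=manifest_path,
        manifest=manifest,
    )


def load_bundle_contacts(bundle: SyntheticBundle) -> ContactSet:
    """Read and KR-normalize the bundle's inter-chromosomal contacts."""
    manifest = bundle.manifest
    bs = manifest["bin_size"]
    frames = []
    for (ca, cb), path in sorted(bundle.contact_files.items()):
        frames.append(read_sparse_contacts(path, ca, cb, bs))
    df = pd.concat(frames, ignore_index=True)
    vectors = {
        chrom: read_norm_vector(path) for chrom, path in bundle.norm_files.items()
    }
    df = apply_normalization(df, vectors)
    return ContactSet(
        df,
        bs,
        threshold=manifest["threshold"],
        top_fraction=manifest["top_fraction"],
    )


def observed_strong_fraction(
    contacts: ContactSet, manifest: Mapping, exclude_hub: bool = True
) -> float:
    """Fraction of defined records at/above threshold, hub rows excluded.

    The planted hub emulates a promiscuous artifact region that an analyst
    removes from the dataset before analysis, so it is excluded from the
    tail-fraction check by default.
    """
    df = contacts.defined
    if exclude_hub:
        hub = {(c, b) for c, b in map(tuple, manifest["hub_bins"])}
        mask = df.apply(
            lambda r: (r["chrom_a"], r["bin_a"]) in hub
            or (r["chrom_b"], r["bin_b"]) in hub,
            axis=1,
        )
        df = df[~mask]
    if len(df) == 0:
        raise ConfigError("no defined records")
    return float((df["norm"] >= manifest["threshold"]).mean())


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well one pipeline run recovered the planted ground truth."""

    module_ari: float
    isolated_recall: float
    hub_detected: bool
    cell_line_correct: bool | None


def evaluate_recovery(
    extended_graph,
    partition,
    original_graph,
    promiscuous_nodes: Sequence[str],
    selected_cell_line: str | None,
    manifest: Mapping,
) -> RecoveryMetrics:
    """Compare pipeline outputs with the generator's ground-truth manifest.

    The module ARI is the adjusted Rand index between detected community
    labels and planted module labels, restricted to planted module bins
    present in the analysed graph.
    """
    from sklearn.metrics import adjusted_rand_score

    node_of_bin = {}
    for node, data in extended_graph.nodes(data=True):
        region = data["region"]
        for label in region.bins():
            node_of_bin[(region.chrom, label)] = node
    labels = partition.node_labels()
    truth, pred = [], []
    for mod_idx, module in enumerate(manifest["modules"]):
        for chrom, label in module:
            node = node_of_bin.get((chrom, label))
            if node is None or node not in labels:
                continue
            truth.append(mod_idx)
            pred.append(labels[node])
    ari = float(adjusted_rand_score(truth, pred)) if truth else 0.0

    orig_bin_owner = {}
    for node, data in original_graph.nodes(data=True):
        region = data["region"]
        for label in region.bins():
            orig_bin_owner[(region.chrom, label)] = node
    recalled = total = 0
    for entry in manifest["isolated_genes"]:
        total += 1
        node = orig_bin_owner.get((entry["chrom"], entry["bin"]))
        if node is not None and original_graph.nodes[node].get("isolated"):
            recalled += 1
    recall = recalled / total if total else 1.0

    hub_bins = {(c, b) for c, b in map(tuple, manifest["hub_bins"])}
    hub_node_bins = set()
    for node in promiscuous_nodes:
        if node in extended_graph:
            region = extended_graph.nodes[node]["region"]
            hub_node_bins |= {(region.chrom, label) for label in region.bins()}
    hub_detected = hub_bins <= hub_node_bins

    correct = (
        None
        if selected_cell_line is None
        else selected_cell_line == manifest["best_cell_line"]
    )
    return RecoveryMetrics(
        module_ari=ari,
        isolated_recall=recall,
        hub_detected=hub_detected,
        cell_line_correct=correct,
    )
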