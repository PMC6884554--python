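"""Extended gene regions (EGRs): gene bodies plus regulatory footprints.

Capture Hi-C interactions anchored at a gene's promoter define its
regulatory footprint: overlapping bait fragments merge into promoter
regions, overlapping other-end fragments merge into enhancer regions (and
interacting promoters of other genes contribute promoter-kind regions).
Gene bodies and footprints are then binned at 100 kb — an interval
partially covering a bin claims the whole bin — and adjacent claimed bins
are amalgamated into extended gene regions. A region housing at least one
"guilty" (phenotype-associated) gene is a guilty-EGR node; a gene-less
footprint becomes a regulatory node. Capture interactions between
non-overlapping, non-adjacent regions are preserved as intra-chromosomal
links.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .contacts import capture_fragment
from .genome import (
    BinnedRegion,
    CoordinateError,
    GenomeLayout,
    GenomicInterval,
    amalgamate,
    interval_to_bins,
    regions_adjacent_or_overlap,
)


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    guilty: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CoordinateError(f"gene {self.symbol}: start > end")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def tss(self) -> int:
        return self.start if self.strand != "-" else self.end


@dataclass(frozen=True)
class RegulatoryRegion:
    """A merged promoter or enhancer footprint linked to one gene."""

    kind: str  # "promoter" | "enhancer"
    interval: GenomicInterval
    linked_gene: str


@dataclass(frozen=True)
class ExtendedGeneRegion:
    region: BinnedRegion
    member_genes: frozenset[str]
    member_regulatory: tuple[RegulatoryRegion, ...]
    node_class: str  # "guilty-EGR" | "regulatory"

    @property
    def id(self) -> str:
        return self.region.label()


@dataclass(frozen=True)
class IntraLink:
    region_a: str
    region_b: str
    support: int


def read_gene_table(path: str | Path) -> list[GeneAnnotation]:
    """TSV with header gene_id/symbol/chrom/start/end[/strand][/guilty]."""
    table = pd.read_csv(path, sep="\t")
    genes = []
    for row in table.itertuples(index=False):
        genes.append(
            GeneAnnotation(
                gene_id=str(row.gene_id),
                symbol=str(row.symbol),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                strand=str(getattr(row, "strand", "+")),
                guilty=bool(int(getattr(row, "guilty", 0))),
            )
        )
    return genes


def _merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sweep-line merge of overlapping (not merely adjacent) intervals."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            merged[-1] = GenomicInterval(last.chrom, last.start, max(last.end, iv.end))
        else:
            merged.append(iv)
    return merged


def regulatory_boundaries(
    capture: pd.DataFrame, gene: str
) -> list[RegulatoryRegion]:
    """Merged promoter/enhancer regions of one gene from capture interactions.

    Bait fragments annotated to the gene merge into promoter regions.
    Other-end fragments of its promoter-other interactions merge per overlap
    cluster into enhancer regions; the far side of promoter-promoter
    interactions contributes promoter-kind regions (other genes' promoters
    that contact this gene's promoter). A gene absent from the tables yields
    an empty list with a warning.
    """
    promoter_frags: list[GenomicInterval] = []
    enhancer_frags: list[GenomicInterval] = []
    other_promoter_frags: list[GenomicInterval] = []
    for row in capture.itertuples(index=False):
        if row.kind == "promoter-other":
            if row.gene_a == gene:
                promoter_frags.append(capture_fragment(row, "a"))
                enhancer_frags.append(capture_fragment(row, "b"))
        else:  # promoter-promoter: either side may be the gene
            if row.gene_a == gene:
                promoter_frags.append(capture_fragment(row, "a"))
                other_promoter_frags.append(capture_fragment(row, "b"))
            elif row.gene_b == gene:
                promoter_frags.append(capture_fragment(row, "b"))
                other_promoter_frags.append(capture_fragment(row, "a"))
    if not (promoter_frags or enhancer_frags or other_promoter_frags):
        warnings.warn(f"gene {gene!r} absent from capture tables", stacklevel=2)
        return []
    regions = [
        RegulatoryRegion("promoter", iv, gene)
        for iv in _merge_intervals(promoter_frags)
    ]
    regions += [
        RegulatoryRegion("enhancer", iv, gene)
        for iv in _merge_intervals(enhancer_frags)
    ]
    regions += [
        RegulatoryRegion("promoter", iv, gene)
        for iv in _merge_intervals(other_promoter_frags)
    ]
    return regions


def build_egrs(
    genes: Sequence[GeneAnnotation],
    regulatory_regions: Sequence[RegulatoryRegion],
    bin_size: int = 100_000,
    layout: GenomeLayout | None = None,
) -> list[ExtendedGeneRegion]:
    """Bin genes and footprints at ``bin_size`` and amalgamate adjacent bins.

    Every gene and regulatory region claims every bin it touches. Each
    maximal run of claimed bins becomes one region; it is a guilty-EGR if it
    houses at least one guilty gene, otherwise a regulatory node. Output is
    sorted and invariant to input order.
    """
    claimed: set[tuple[str, int]] = set()
    for gene in genes:
        if layout is not None:
            layout.check_position(gene.chrom, gene.start)
            layout.check_position(gene.chrom, gene.end)
        for label in interval_to_bins(gene.interval, bin_size):
            claimed.add((gene.chrom, label))
    for reg in regulatory_regions:
        for label in interval_to_bins(reg.interval, bin_size):
            claimed.add((reg.interval.chrom, label))

    runs = amalgamate(claimed, bin_size)
    egrs: list[ExtendedGeneRegion] = []
    for run in runs:
        span = run.interval()
        members = frozenset(
            g.symbol for g in genes if g.guilty and g.interval.overlaps(span)
        )
        regs = tuple(
            sorted(
                (r for r in regulatory_regions if r.interval.overlaps(span)),
                key=lambda r: (r.interval, r.kind, r.linked_gene),
            )
        )
        node_class = "guilty-EGR" if members else "regulatory"
        egrs.append(ExtendedGeneRegion(run, members, regs, node_class))
    return egrs


def intra_links(
    egrs: Sequence[ExtendedGeneRegion], capture: pd.DataFrame
) -> list[IntraLink]:
    """Capture-supported links between non-overlapping, non-adjacent regions.

    A link exists iff at least one interaction places its two fragments in
    two distinct regions whose bin runs neither overlap nor touch; support
    counts the interactions behind each link.
    """
    if not egrs:
        return []
    bin_size = egrs[0].region.bin_size
    owner: dict[tuple[str, int], ExtendedGeneRegion] = {}
    for egr in egrs:
        for label in egr.region.bins():
            owner[(egr.region.chrom, label)] = egr

    def region_of(iv: GenomicInterval) -> ExtendedGeneRegion | None:
        for label in sorted(interval_to_bins(iv, bin_size)):
            hit = owner.get((iv.chrom, label))
            if hit is not None:
                return hit
        return None

    support: dict[tuple[str, str], int] = {}
    for row in capture.itertuples(index=False):
        ra = region_of(capture_fragment(row, "a"))
        rb = region_of(capture_fragment(row, "b"))
        if ra is None or rb is None or ra is rb:
            continue
        if regions_adjacent_or_overlap(ra.region, rb.region):
            continue
        key = tuple(sorted((ra.id, rb.id)))
        support[key] = support.get(key, 0) + 1
    return [
        IntraLink(a, b, n) for (a, b), n in sorted(support.items())
    ]
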