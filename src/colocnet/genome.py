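"""Genome coordinate conventions, fixed-size binning and region algebra.

All coordinates are 1-based and inclusive on both ends, matching the region
notation used throughout the package (e.g. ``chr22:38,800,001-43,700,000``).
BED input (0-based, half-open) is converted at the reader boundary.

Bins are fixed-size windows labelled by 1-based integers: position ``p``
falls in bin ``floor((p-1)/bin_size) + 1``, so bin ``k`` spans
``(k-1)*bin_size + 1 .. k*bin_size``. With 100 kb bins the region
chr22:38,800,001-43,700,000 is bins 389-437.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence


class CoordinateError(ValueError):
    """A genomic position, interval or bin label is invalid."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval on one chromosome (1-based, inclusive ends)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True, order=True)
class BinnedRegion:
    """A run of consecutive fixed-size bins on one chromosome.

    The bp-equivalent interval is ``(first_bin-1)*bin_size + 1`` through
    ``last_bin*bin_size``.
    """

    chrom: str
    first_bin: int
    last_bin: int
    bin_size: int

    def __post_init__(self) -> None:
        if self.first_bin < 1 or self.last_bin < self.first_bin:
            raise CoordinateError(
                f"invalid bin run {self.chrom}:{self.first_bin}-{self.last_bin}"
            )
        if self.bin_size < 1:
            raise CoordinateError(f"bin_size must be positive, got {self.bin_size}")

    @property
    def n_bins(self) -> int:
        return self.last_bin - self.first_bin + 1

    def bins(self) -> Iterator[int]:
        return iter(range(self.first_bin, self.last_bin + 1))

    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            (self.first_bin - 1) * self.bin_size + 1,
            self.last_bin * self.bin_size,
        )

    def span_bp(self) -> int:
        return self.n_bins * self.bin_size

    def label(self) -> str:
        """Compact node label, e.g. ``chr22:389-437`` (100 kb scale)."""
        return f"{self.chrom}:{self.first_bin}-{self.last_bin}"


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names, lengths (bp) and the working bin size."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int = 100_000

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise CoordinateError("chrom_names and chrom_lengths length mismatch")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise CoordinateError("duplicate chromosome names")
        if any(n <= 0 for n in self.chrom_lengths):
            raise CoordinateError("chromosome lengths must be positive")
        if self.bin_size <= 0:
            raise CoordinateError("bin_size must be positive")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str) -> int:
        return -(-self.length_of(chrom) // self.bin_size)  # ceil division

    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_names)

    def check_position(self, chrom: str, pos: int) -> None:
        length = self.length_of(chrom)
        if not 1 <= pos <= length:
            raise CoordinateError(f"position {chrom}:{pos} outside 1..{length}")


def pos_to_bin(pos: int, bin_size: int) -> int:
    """1-based bin label of a 1-based bp position."""
    if pos < 1:
        raise CoordinateError(f"position must be >= 1, got {pos}")
    if bin_size < 1:
        raise CoordinateError(f"bin_size must be positive, got {bin_size}")
    return (pos - 1) // bin_size + 1


def bin_to_interval(label: int, bin_size: int) -> tuple[int, int]:
    """bp span ``(start, end)`` of bin ``label``; inverse of :func:`pos_to_bin`."""
    if label < 1:
        raise CoordinateError(f"bin label must be >= 1, got {label}")
    if bin_size < 1:
        raise CoordinateError(f"bin_size must be positive, got {bin_size}")
    return (label - 1) * bin_size + 1, label * bin_size


def interval_to_bins(interval: GenomicInterval, bin_size: int) -> set[int]:
    """Bin labels an interval touches; partial coverage claims the whole bin."""
    return set(
        range(pos_to_bin(interval.start, bin_size), pos_to_bin(interval.end, bin_size) + 1)
    )


def amalgamate(
    bins: Iterable[tuple[str, int]], bin_size: int
) -> list[BinnedRegion]:
    """Merge a set of (chrom, bin label) into maximal runs of consecutive bins.

    Output regions are pairwise non-overlapping and non-adjacent, never cross
    chromosomes, and together cover exactly the input bin set. Empty input
    yields an empty list.
    """
    by_chrom: dict[str, set[int]] = {}
    for chrom, label in bins:
        if label < 1:
            raise CoordinateError(f"bin label must be >= 1, got {chrom}:{label}")
        by_chrom.setdefault(chrom, set()).add(label)
    regions: list[BinnedRegion] = []
    for chrom in sorted(by_chrom):
        labels = sorted(by_chrom[chrom])
        run_start = labels[0]
        prev = labels[0]
        for lab in labels[1:]:
            if lab > prev + 1:
                regions.append(BinnedRegion(chrom, run_start, prev, bin_size))
                run_start = lab
            prev = lab
        regions.append(BinnedRegion(chrom, run_start, prev, bin_size))
    return sorted(regions)


def regions_adjacent_or_overlap(a: BinnedRegion, b: BinnedRegion) -> bool:
    """True iff the two bin runs touch: overlap or sit in consecutive bins."""
    if a.bin_size != b.bin_size:
        raise CoordinateError(
            f"bin size mismatch: {a.bin_size} vs {b.bin_size}"
        )
    if a.chrom != b.chrom:
        return False
    return b.first_bin <= a.last_bin + 1 and a.first_bin <= b.last_bin + 1


# ---------------------------------------------------------------------------
# readers / writers


def read_chrom_sizes(path: str | Path, bin_size: int = 100_000) -> GenomeLayout:
    """Two-column TSV (chromosome name, length in bp) -> GenomeLayout."""
    names: list[str] = []
    lengths: list[int] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise CoordinateError(f"{path}:{lineno}: expected 2 columns")
        names.append(parts[0])
        lengths.append(int(parts[1]))
    return GenomeLayout(tuple(names), tuple(lengths), bin_size)


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """BED3+ reader; 0-based half-open converted to 1-based inclusive.

    Returns (interval, name) pairs; name is "" when the file is BED3.
    """
    out: list[tuple[GenomicInterval, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise CoordinateError(f"{path}:{lineno}: expected >= 3 BED columns")
        chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
        name = parts[3] if len(parts) > 3 else ""
        out.append((GenomicInterval(chrom, start0 + 1, end0), name))
    return out


def read_intervals_tsv(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """1-based inclusive interval TSV with header chrom/start/end[/name]."""
    import csv

    out: list[tuple[GenomicInterval, str]] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                (
                    GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
                    row.get("name", ""),
                )
            )
    return out
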