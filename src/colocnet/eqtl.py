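"""Cell-line selection by eQTL / chromatin-contact concordance.

cis-eQTL SNP-target pairs are binned at a distance-dependent scale (10 kb,
100 kb or 1 Mb), deduplicated, and intersected with intra-chromosomal Hi-C
contacts of each candidate cell line. The cell line whose strong contacts
(normalized count >= threshold) carry the highest proportion of strong
eQTL signals (p <= 1e-6) is selected as the best proxy for the tissue of
interest; a one-sided Fisher exact test, computed in log-space so that
astronomically small p-values remain meaningful, quantifies the enrichment.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .contacts import ConfigError, ContactSet
from .genome import pos_to_bin

#: distance-dependent binning scales (bp)
SCALES = (10_000, 100_000, 1_000_000)


class TransPairError(ValueError):
    """A trans (different-chromosome) pair entered a cis-only procedure."""


def assign_scale(snp_pos: int, target_pos: int) -> int:
    """Bin size for a cis pair from SNP-target distance.

    d < 100 kb -> 10 kb bins; 100 kb <= d < 1 Mb -> 100 kb; d >= 1 Mb -> 1 Mb.
    The boundary d == 1 Mb is assigned to the 1 Mb scale.
    """
    d = abs(snp_pos - target_pos)
    if d < 100_000:
        return 10_000
    if d < 1_000_000:
        return 100_000
    return 1_000_000


DEFAULT_EQTL_COLUMNS = {
    "snp_chrom": "snp_chrom",
    "snp_pos": "snp_pos",
    "target_gene": "target_gene",
    "target_chrom": "target_chrom",
    "target_pos": "target_pos",
    "p_value": "p_value",
    "tissue": "tissue",
}


def read_eqtl_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """TSV of eQTL pairs; target_pos is the gene anchor (TSS by convention)."""
    cmap = dict(DEFAULT_EQTL_COLUMNS if column_map is None else column_map)
    table = pd.read_csv(path, sep="\t")
    out = pd.DataFrame(
        {field: table[col] for field, col in cmap.items() if col in table.columns}
    )
    required = ("snp_chrom", "snp_pos", "target_gene", "target_pos", "p_value")
    missing = [f for f in required if f not in out.columns]
    if missing:
        raise ConfigError(f"{path}: missing eQTL columns {missing}")
    if "target_chrom" not in out.columns:
        out["target_chrom"] = out["snp_chrom"]
    if "tissue" not in out.columns:
        out["tissue"] = "aveALL"
    out["snp_pos"] = out["snp_pos"].astype(int)
    out["target_pos"] = out["target_pos"].astype(int)
    if ((out["p_value"] <= 0) | (out["p_value"] > 1)).any():
        raise ConfigError(f"{path}: p-values must lie in (0, 1]")
    return out


def bin_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Attach scale, snp_bin and target_bin columns to cis pairs."""
    if (pairs["snp_chrom"] != pairs["target_chrom"]).any():
        raise TransPairError("trans pair in cis-only binning procedure")
    scale = np.array(
        [assign_scale(s, t) for s, t in zip(pairs["snp_pos"], pairs["target_pos"])]
    )
    snp_bin = np.array(
        [pos_to_bin(p, s) for p, s in zip(pairs["snp_pos"], scale)]
    )
    target_bin = np.array(
        [pos_to_bin(p, s) for p, s in zip(pairs["target_pos"], scale)]
    )
    return pairs.assign(scale=scale, snp_bin=snp_bin, target_bin=target_bin)


def filter_and_dedupe(pairs: pd.DataFrame) -> pd.DataFrame:
    """Drop same-bin pairs at the 10 kb scale; keep minimum-p per (bin, gene).

    Among pairs sharing (scale, chromosome, snp_bin, target_gene) only the
    lowest-p pair survives; ties break deterministically on (target_bin,
    snp_pos) order.
    """
    df = pairs.copy()
    same_bin = (df["scale"] == 10_000) & (df["snp_bin"] == df["target_bin"])
    df = df[~same_bin]
    df = df.sort_values(
        ["scale", "snp_chrom", "snp_bin", "target_gene", "p_value", "target_bin", "snp_pos"],
        kind="mergesort",
    )
    df = df.drop_duplicates(
        subset=["scale", "snp_chrom", "snp_bin", "target_gene"], keep="first"
    )
    return df.reset_index(drop=True)


@dataclass
class ConcordanceTable:
    """2x2 contact-strength x eQTL-occupancy table plus summary fractions.

    Rows: contact >= threshold (strong) vs 0 < contact < threshold, over
    observed contact bin-pairs. Columns: bin-pair contains >= 1 eQTL pair
    vs not. ``strong_eqtl_fraction`` is the share of eQTL pairs sitting on
    strong contacts whose p <= ``strong_p_cut``; it is NaN (flagged
    undefined) when no eQTL pair sits on a strong contact.
    """

    a: int  # strong contact, contains eQTL pair
    b: int  # strong contact, no eQTL pair
    c: int  # weaker nonzero contact, contains eQTL pair
    d: int  # weaker nonzero contact, no eQTL pair
    strong_eqtl_fraction: float
    strong_p_cut: float
    n_pairs: int
    n_on_nonzero: int
    n_on_strong: int

    @property
    def fraction_nonzero(self) -> float:
        return self.n_on_nonzero / self.n_pairs if self.n_pairs else float("nan")

    @property
    def undefined(self) -> bool:
        return math.isnan(self.strong_eqtl_fraction)


def _contact_lookup(contacts: ContactSet) -> dict[tuple[str, int, int], float]:
    lut: dict[tuple[str, int, int], float] = {}
    for row in contacts.defined.itertuples(index=False):
        if row.chrom_a != row.chrom_b:
            continue
        lo, hi = sorted((int(row.bin_a), int(row.bin_b)))
        key = (row.chrom_a, lo, hi)
        lut[key] = max(lut.get(key, 0.0), float(row.norm))
    return lut


def concordance(
    pairs: pd.DataFrame,
    contacts: ContactSet | Mapping[int, ContactSet],
    threshold: float = 64.0,
    strong_p_cut: float = 1e-6,
) -> ConcordanceTable:
    """Cross binned, deduplicated cis-eQTL pairs with intra-chromosomal contacts.

    ``contacts`` is a single ContactSet or a mapping of scale (bp) to
    ContactSet when pairs span several scales.
    """
    if isinstance(contacts, ContactSet):
        contacts = {int(s): contacts for s in pairs["scale"].unique()}
    luts = {}
    for scale, cs in contacts.items():
        if len(cs) == 0:
            raise ConfigError("empty contact set")
        luts[int(scale)] = _contact_lookup(cs)

    occupied: dict[int, set[tuple[str, int, int]]] = {s: set() for s in luts}
    n_on_nonzero = n_on_strong = n_strong_low_p = 0
    for row in pairs.itertuples(index=False):
        scale = int(row.scale)
        lut = luts.get(scale)
        if lut is None:
            continue
        lo, hi = sorted((int(row.snp_bin), int(row.target_bin)))
        key = (row.snp_chrom, lo, hi)
        occupied[scale].add(key)
        norm = lut.get(key)
        if norm is None or norm <= 0:
            continue
        n_on_nonzero += 1
        if norm >= threshold:
            n_on_strong += 1
            if row.p_value <= strong_p_cut:
                n_strong_low_p += 1

    a = b = c = d = 0
    for scale, lut in luts.items():
        occ = occupied[scale]
        for key, norm in lut.items():
            if norm <= 0:
                continue
            strong = norm >= threshold
            has_pair = key in occ
            if strong and has_pair:
                a += 1
            elif strong:
                b += 1
            elif has_pair:
                c += 1
            else:
                d += 1

    frac = n_strong_low_p / n_on_strong if n_on_strong else float("nan")
    return ConcordanceTable(
        a=a,
        b=b,
        c=c,
        d=d,
        strong_eqtl_fraction=frac,
        strong_p_cut=strong_p_cut,
        n_pairs=len(pairs),
        n_on_nonzero=n_on_nonzero,
        n_on_strong=n_on_strong,
    )


def fisher_exact_one_sided(
    a: int, b: int, c: int, d: int, log: bool = False
) -> float:
    """Upper-tail Fisher exact probability P(X >= a) with fixed margins.

    Computed by log-space summation over the hypergeometric support, so
    extreme tables (p far below float underflow when exponentiated) can be
    reported via ``log=True`` (natural log of p).
    """
    counts = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in counts):
        raise ValueError(f"counts must be non-negative integers, got {counts}")
    a, b, c, d = (int(x) for x in counts)
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    row1 = a + b
    col1 = a + c
    hi = min(row1, col1)
    ks = np.arange(a, hi + 1)
    log_pmf = (
        gammaln(row1 + 1)
        - gammaln(ks + 1)
        - gammaln(row1 - ks + 1)
        + gammaln(n - row1 + 1)
        - gammaln(col1 - ks + 1)
        - gammaln(n - row1 - col1 + ks + 1)
        - (gammaln(n + 1) - gammaln(col1 + 1) - gammaln(n - col1 + 1))
    )
    log_p = float(logsumexp(log_pmf))
    log_p = min(log_p, 0.0)
    return log_p if log else math.exp(log_p)


@dataclass(frozen=True)
class CellLineScore:
    """Summary of one candidate cell line's eQTL-contact concordance."""

    cell_line: str
    fraction_nonzero: float
    strong_eqtl_fraction: float
    fisher_p: float
    log_fisher_p: float = float("nan")

    def __post_init__(self) -> None:
        for value in (self.fraction_nonzero, self.strong_eqtl_fraction):
            if not math.isnan(value) and not 0 <= value <= 1:
                raise ValueError(f"fraction outside [0, 1]: {value}")


def score_cell_line(
    cell_line: str,
    pairs: pd.DataFrame,
    contacts: ContactSet | Mapping[int, ContactSet],
    threshold: float = 64.0,
    strong_p_cut: float = 1e-6,
) -> CellLineScore:
    table = concordance(pairs, contacts, threshold, strong_p_cut)
    log_p = fisher_exact_one_sided(table.a, table.b, table.c, table.d, log=True)
    return CellLineScore(
        cell_line=cell_line,
        fraction_nonzero=table.fraction_nonzero,
        strong_eqtl_fraction=table.strong_eqtl_fraction,
        fisher_p=math.exp(log_p),
        log_fisher_p=log_p,
    )


def rank_cell_lines(scores: Sequence[CellLineScore]) -> list[CellLineScore]:
    """Descending by strong_eqtl_fraction; ties by Fisher p ascending, then label.

    The first element is the selected best cell line.
    """
    if not scores:
        raise ValueError("no cell-line scores to rank")

    def sort_key(s: CellLineScore):
        frac = -1.0 if math.isnan(s.strong_eqtl_fraction) else s.strong_eqtl_fraction
        log_p = s.log_fisher_p if not math.isnan(s.log_fisher_p) else math.log(
            max(s.fisher_p, 5e-324)
        )
        return (-frac, log_p, s.cell_line)

    return sorted(scores, key=sort_key)
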