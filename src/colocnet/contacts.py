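"""Hi-C sparse contact I/O, Knight-Ruiz normalization and thresholding.

Sparse inter-chromosomal dumps are three whitespace-delimited columns
``pos_a pos_b raw_count`` where positions are 0-based bin start coordinates
(one file per chromosome pair). Normalization vectors hold one balancing
factor per bin, ``NaN`` marking unmappable bins. Capture Hi-C significant
interactions arrive as tab-delimited tables with a header, split by kind
(promoter-other vs promoter-promoter) and pre-filtered for significance at
the source (one-sided cumulative binomial test, Benjamini-Hochberg FDR<0.05),
so no further significance filtering is applied here.

A normalized count is ``raw / (f_a * f_b)``; records touching an unmappable
bin (factor NaN or <= 0) are *excluded*, which is a state, not an error.
"Strong" contacts are those with normalized count >= a threshold (default 64,
roughly the top 0.05% of normalized inter-chromosomal counts in the datasets
this tool targets).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomicInterval

#: canonical column order of a contact table
CONTACT_COLUMNS = ["chrom_a", "bin_a", "chrom_b", "bin_b", "raw", "norm"]


class ContactParseError(ValueError):
    pass


class ConfigError(ValueError):
    pass


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Order each record so (chrom_a, bin_a) <= (chrom_b, bin_b) lexicographically."""
    df = df.copy()
    flip = (df["chrom_a"] > df["chrom_b"]) | (
        (df["chrom_a"] == df["chrom_b"]) & (df["bin_a"] > df["bin_b"])
    )
    for left, right in (("chrom_a", "chrom_b"), ("bin_a", "bin_b")):
        tmp = df.loc[flip, left].copy()
        df.loc[flip, left] = df.loc[flip, right]
        df.loc[flip, right] = tmp
    return df


@dataclass
class ContactSet:
    """Sparse normalized contacts plus the thresholding configuration.

    ``records`` is a DataFrame with columns :data:`CONTACT_COLUMNS`; ``norm``
    is NaN for excluded (unmappable-bin) records. Duplicate canonical pairs
    are summed on construction.
    """

    records: pd.DataFrame
    bin_size: int
    threshold: float = 64.0
    top_fraction: float = 0.0005

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ConfigError(f"threshold must be positive, got {self.threshold}")
        df = self.records
        missing = [c for c in CONTACT_COLUMNS if c not in df.columns and c != "norm"]
        if missing:
            raise ContactParseError(f"contact table missing columns {missing}")
        if "norm" not in df.columns:
            df = df.assign(norm=np.nan)
        df = _canonicalize(df)
        key = ["chrom_a", "bin_a", "chrom_b", "bin_b"]
        if df.duplicated(key).any():
            warnings.warn("duplicate contact pairs summed", stacklevel=2)
            df = df.groupby(key, as_index=False).agg(
                raw=("raw", "sum"), norm=("norm", "sum")
            )
        self.records = (
            df[CONTACT_COLUMNS].sort_values(key, kind="mergesort").reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def defined(self) -> pd.DataFrame:
        """Records with a defined (non-excluded) normalized count."""
        return self.records[self.records["norm"].notna()]

    def inter_chromosomal(self) -> "ContactSet":
        df = self.records[self.records["chrom_a"] != self.records["chrom_b"]]
        return replace(self, records=df.reset_index(drop=True))


def read_sparse_contacts(
    path: str | Path, chrom_a: str, chrom_b: str, bin_size: int
) -> pd.DataFrame:
    """Parse one sparse triplet dump (``pos_a pos_b count``) for a chromosome pair.

    Positions are 0-based bin starts and must be exact multiples of
    ``bin_size``; bin label = pos/bin_size + 1. Duplicate pairs are summed
    with a warning. Raises :class:`ContactParseError` with the offending line
    number on malformed input.
    """
    rows: list[tuple[str, int, str, int, float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ContactParseError(f"{path}:{lineno}: expected 3 fields")
        try:
            pos_a, pos_b = int(parts[0]), int(parts[1])
            count = float(parts[2])
        except ValueError:
            raise ContactParseError(f"{path}:{lineno}: non-numeric field") from None
        if count < 0:
            raise ContactParseError(f"{path}:{lineno}: negative count {count}")
        for pos in (pos_a, pos_b):
            if pos % bin_size != 0 or pos < 0:
                raise ContactParseError(
                    f"{path}:{lineno}: position {pos} not a multiple of {bin_size}"
                )
        rows.append((chrom_a, pos_a // bin_size + 1, chrom_b, pos_b // bin_size + 1, count))
    df = pd.DataFrame(rows, columns=["chrom_a", "bin_a", "chrom_b", "bin_b", "raw"])
    key = ["chrom_a", "bin_a", "chrom_b", "bin_b"]
    df = _canonicalize(df)
    if df.duplicated(key).any():
        warnings.warn(f"{path}: duplicate contact pairs summed", stacklevel=2)
        df = df.groupby(key, as_index=False)["raw"].sum()
    return df.sort_values(key, kind="mergesort").reset_index(drop=True)


def write_sparse_contacts(df: pd.DataFrame, path: str | Path, bin_size: int) -> None:
    """Inverse of :func:`read_sparse_contacts` (raw counts only)."""
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            raw = row.raw
            text = f"{int(raw)}" if float(raw).is_integer() else repr(float(raw))
            fh.write(
                f"{(row.bin_a - 1) * bin_size} {(row.bin_b - 1) * bin_size} {text}\n"
            )


def read_norm_vector(path: str | Path, n_bins: int | None = None) -> np.ndarray:
    """One balancing factor per line; ``NaN`` allowed for unmappable bins."""
    values = [
        float(line) for line in Path(path).read_text().splitlines() if line.strip()
    ]
    arr = np.asarray(values, dtype=float)
    if n_bins is not None and len(arr) != n_bins:
        raise ContactParseError(
            f"{path}: expected {n_bins} factors, found {len(arr)}"
        )
    return arr


def kr_normalize(raw, f_a, f_b):
    """Knight-Ruiz balanced count ``raw / (f_a * f_b)``; NaN where excluded.

    Accepts scalars or numpy arrays. A record with an undefined (NaN) or
    non-positive factor on either side is excluded (norm = NaN).
    """
    raw = np.asarray(raw, dtype=float)
    f_a = np.asarray(f_a, dtype=float)
    f_b = np.asarray(f_b, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(
            np.isnan(f_a) | np.isnan(f_b) | (f_a <= 0) | (f_b <= 0),
            np.nan,
            raw / (f_a * f_b),
        )
    if norm.ndim == 0:
        return float(norm)
    return norm


def apply_normalization(
    df: pd.DataFrame, norm_vectors: Mapping[str, np.ndarray]
) -> pd.DataFrame:
    """Attach a ``norm`` column using per-chromosome balancing vectors."""

    def factor(chroms: pd.Series, bins: pd.Series) -> np.ndarray:
        out = np.full(len(chroms), np.nan)
        for chrom, vec in norm_vectors.items():
            mask = (chroms == chrom).to_numpy()
            if mask.any():
                idx = bins.to_numpy()[mask] - 1
                valid = (idx >= 0) & (idx < len(vec))
                vals = np.full(mask.sum(), np.nan)
                vals[valid] = np.asarray(vec)[idx[valid]]
                out[mask] = vals
        return out

    f_a = factor(df["chrom_a"], df["bin_a"])
    f_b = factor(df["chrom_b"], df["bin_b"])
    return df.assign(norm=kr_normalize(df["raw"].to_numpy(), f_a, f_b))


def strong_contacts(contacts: ContactSet, threshold: float | None = None) -> ContactSet:
    """Retain records with defined normalized count >= threshold (inclusive)."""
    t = contacts.threshold if threshold is None else threshold
    if t <= 0:
        raise ConfigError(f"threshold must be positive, got {t}")
    df = contacts.records
    kept = df[df["norm"].notna() & (df["norm"] >= t)]
    return ContactSet(
        kept.reset_index(drop=True),
        contacts.bin_size,
        threshold=t,
        top_fraction=contacts.top_fraction,
    )


def threshold_from_quantile(
    contacts: ContactSet, top_fraction: float | None = None
) -> float:
    """Smallest value t for which <= top_fraction of records have norm >= t.

    Ties resolve toward fewer retained records. When even the records tied at
    the maximum exceed the allowance, a value just above the maximum is
    returned (retaining zero records).
    """
    q = contacts.top_fraction if top_fraction is None else top_fraction
    if not 0 < q < 1:
        raise ConfigError(f"top_fraction must be in (0, 1), got {q}")
    norm = contacts.records["norm"].dropna().to_numpy()
    if norm.size == 0:
        raise ConfigError("empty contact set: no defined normalized counts")
    n = norm.size
    allowed = int(math.floor(q * n))
    values, counts = np.unique(norm, return_counts=True)  # ascending
    ge_counts = counts[::-1].cumsum()[::-1]  # records >= values[i]
    ok = np.nonzero(ge_counts <= allowed)[0]
    if ok.size:
        return float(values[ok[0]])
    return float(np.nextafter(values[-1], np.inf))


# ---------------------------------------------------------------------------
# Capture Hi-C

#: logical fields a capture column map must cover
_CAPTURE_REQUIRED = (
    "chrom_a",
    "start_a",
    "end_a",
    "chrom_b",
    "start_b",
    "end_b",
)

DEFAULT_CAPTURE_COLUMNS: dict[str, str] = {
    "chrom_a": "chrom_bait",
    "start_a": "start_bait",
    "end_a": "end_bait",
    "gene_a": "gene_bait",
    "chrom_b": "chrom_other",
    "start_b": "start_other",
    "end_b": "end_other",
    "gene_b": "gene_other",
    "score": "score",
}


def read_capture_interactions(
    path: str | Path,
    kind: str,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a Capture Hi-C significant-interaction table.

    ``kind`` is ``promoter-other`` or ``promoter-promoter`` (fixed by the
    source file). ``column_map`` maps logical fields (chrom_a, start_a, ...)
    to header names; gene and score columns are optional. Fragment A is the
    bait (promoter) side of promoter-other interactions.
    """
    if kind not in ("promoter-other", "promoter-promoter"):
        raise ConfigError(f"unknown capture kind {kind!r}")
    cmap = dict(DEFAULT_CAPTURE_COLUMNS if column_map is None else column_map)
    table = pd.read_csv(path, sep="\t")
    missing = [
        cmap[f] for f in _CAPTURE_REQUIRED if cmap.get(f) not in table.columns
    ]
    if missing:
        raise ContactParseError(f"{path}: missing mapped columns {missing}")
    out = pd.DataFrame(
        {
            field: table[cmap[field]]
            for field in _CAPTURE_REQUIRED
            if cmap.get(field) in table.columns
        }
    )
    for optional in ("gene_a", "gene_b", "score"):
        col = cmap.get(optional)
        out[optional] = table[col] if col in table.columns else (
            np.nan if optional == "score" else ""
        )
    out["gene_a"] = out["gene_a"].fillna("").astype(str)
    out["gene_b"] = out["gene_b"].fillna("").astype(str)
    out["kind"] = kind
    for c in ("start_a", "end_a", "start_b", "end_b"):
        out[c] = out[c].astype(int)
    return out.reset_index(drop=True)


def capture_fragment(row, side: str) -> GenomicInterval:
    """GenomicInterval of the A or B fragment of a capture interaction row."""
    return GenomicInterval(
        getattr(row, f"chrom_{side}"),
        int(getattr(row, f"start_{side}")),
        int(getattr(row, f"end_{side}")),
    )
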