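"""Reading HiC-Pro style binned contact matrices and interaction-frequency
threshold logic.

The on-disk dialect is the plain-text HiC-Pro pair: an ``abs`` BED file
describing genome bins (chrom, start, end, 1-based global bin id) and a
three-column sparse matrix (idA, idB, IF).  Everything downstream works on
chromosome-local, 0-based bin indices and cis contacts only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 150_000


class ParseError(ValueError):
    """Raised when a bins/matrix file cannot be parsed."""


@dataclass
class GenomeBins:
    """Genome binning table, mirroring a HiC-Pro abs-BED file.

    ``table`` columns: chrom, start, end, global_id (1-based, as on disk),
    local_index (0-based, consecutive within each chromosome).
    """

    table: pd.DataFrame
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        t = self.table
        for chrom, sub in t.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(starts[1:] != ends[:-1]):
                raise ValueError(f"bins on {chrom} are not contiguous")
            if np.any(ends - starts > self.bin_size):
                raise ValueError(f"bin on {chrom} longer than bin size")

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def n_bins(self, chrom: str) -> int:
        n = int((self.table["chrom"] == chrom).sum())
        if n == 0:
            raise KeyError(
                f"unknown chromosome {chrom!r}; available: {self.chromosomes}"
            )
        return n

    def global_to_local(self) -> tuple[dict[int, str], dict[int, int]]:
        """Maps global bin id -> (chromosome, local 0-based index)."""
        chrom_of = dict(zip(self.table["global_id"], self.table["chrom"]))
        local_of = dict(zip(self.table["global_id"], self.table["local_index"]))
        return chrom_of, local_of


@dataclass
class CisMatrix:
    """One chromosome's cis contacts as an upper-triangle sparse list."""

    chrom: str
    n_bins: int
    i: np.ndarray  # 0-based local bin indices, i < j
    j: np.ndarray
    values: np.ndarray  # IF, strictly positive
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=np.int64)
        self.j = np.asarray(self.j, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.i) == len(self.j) == len(self.values)):
            raise ValueError("entry arrays must be congruent")
        if len(self.i):
            if np.any(self.i >= self.j):
                raise ValueError("entries must satisfy i < j")
            if np.any(self.j >= self.n_bins) or np.any(self.i < 0):
                raise ValueError("bin index out of range")
            if np.any(self.values <= 0):
                raise ValueError("IF values must be positive")
            pairs = set(zip(self.i.tolist(), self.j.tolist()))
            if len(pairs) != len(self.i):
                raise ValueError("duplicate (i, j) entries")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ThresholdSet:
    """Mean / median / percentile IF cutoffs plus strict-above fractions (%)."""

    mean: float
    median: float
    percentile: float
    q: float
    frac_above_mean: float
    frac_above_median: float
    frac_above_percentile: float


@dataclass
class ConstraintSet:
    """Contact pairs retained for modeling: IF strictly above the cutoff."""

    chrom: str
    threshold: float
    i: np.ndarray
    j: np.ndarray
    values: np.ndarray
    provenance: str = "mean"
    n_source: int = 0  # entries in the source matrix

    def __len__(self) -> int:
        return len(self.values)

    @property
    def percent_retained(self) -> float:
        return 100.0 * len(self) / self.n_source if self.n_source else float("nan")


def read_bins(bins_path) -> GenomeBins:
    """Read a HiC-Pro abs-BED bin table."""
    try:
        df = pd.read_csv(
            bins_path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "global_id"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64,
                   "global_id": np.int64},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"cannot parse bins file {bins_path}: {exc}") from exc
    widths = df["end"] - df["start"]
    bin_size = int(widths.max()) if len(df) else DEFAULT_BIN_SIZE
    df["local_index"] = df.groupby("chrom", sort=False).cumcount()
    return GenomeBins(df, bin_size=bin_size)


def read_hicpro(bins_path, matrix_path) -> tuple[GenomeBins, np.ndarray]:
    """Read the HiC-Pro (abs-BED, sparse matrix) pair.

    Returns the bin table and a structured entry array with fields
    ``id_a``, ``id_b`` (global, 1-based, id_a < id_b) and ``value``.
    Self-interactions are dropped; flipped pairs are canonicalized.
    """
    bins = read_bins(bins_path)
    known = set(bins.table["global_id"].tolist())
    ids_a, ids_b, vals = [], [], []
    with open(matrix_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{matrix_path}:{lineno}: expected 3 tab-separated fields"
                )
            try:
                a, b = int(parts[0]), int(parts[1])
                v = float(parts[2])
            except ValueError as exc:
                raise ParseError(f"{matrix_path}:{lineno}: {exc}") from exc
            if a not in known or b not in known:
                raise ParseError(
                    f"{matrix_path}:{lineno}: bin id not in bins file"
                )
            if a == b:
                continue  # self-interactions are never used
            if a > b:
                a, b = b, a
            ids_a.append(a)
            ids_b.append(b)
            vals.append(v)
    entries = np.zeros(
        len(vals),
        dtype=[("id_a", np.int64), ("id_b", np.int64), ("value", float)],
    )
    entries["id_a"] = ids_a
    entries["id_b"] = ids_b
    entries["value"] = vals
    return bins, entries


def extract_cis(bins: GenomeBins, entries: np.ndarray, chrom: str) -> CisMatrix:
    """Keep entries with both ends on ``chrom``, re-indexed locally."""
    n_bins = bins.n_bins(chrom)  # raises on unknown chromosome
    chrom_of, local_of = bins.global_to_local()
    keep_i, keep_j, keep_v = [], [], []
    for a, b, v in zip(entries["id_a"], entries["id_b"], entries["value"]):
        if chrom_of[a] == chrom and chrom_of[b] == chrom:
            keep_i.append(local_of[a])
            keep_j.append(local_of[b])
            keep_v.append(v)
    return CisMatrix(
        chrom=chrom,
        n_bins=n_bins,
        i=np.array(keep_i, dtype=np.int64),
        j=np.array(keep_j, dtype=np.int64),
        values=np.array(keep_v, dtype=float),
        bin_size=bins.bin_size,
    )


def _frac_strictly_above(values: np.ndarray, cutoff: float) -> float:
    return 100.0 * float(np.mean(values > cutoff))


def if_thresholds(cis: CisMatrix, q: float = 35.0) -> ThresholdSet:
    """Mean / median / q-th percentile of the nonzero IF values.

    Percentiles use linear interpolation between order statistics; the
    strict-above fractions mirror the constraint selection rule.
    """
    if len(cis) == 0:
        raise ValueError(f"no cis contacts on {cis.chrom}")
    v = cis.values
    mean = float(np.mean(v))
    median = float(np.median(v))
    pct = float(np.percentile(v, q))
    return ThresholdSet(
        mean=mean,
        median=median,
        percentile=pct,
        q=q,
        frac_above_mean=_frac_strictly_above(v, mean),
        frac_above_median=_frac_strictly_above(v, median),
        frac_above_percentile=_frac_strictly_above(v, pct),
    )


def select_constraints(
    cis: CisMatrix,
    mode: str = "mean",
    q: float = 35.0,
    explicit_list: np.ndarray | None = None,
) -> ConstraintSet:
    """Select modeling constraints: entries with IF strictly above the cutoff.

    ``mode`` is one of ``mean``, ``median``, ``percentile`` (uses ``q``) or
    ``explicit`` (consume a pre-filtered (i, j, IF) list as-is).
    """
    if mode == "explicit":
        if explicit_list is None:
            raise ValueError("explicit mode requires a pre-filtered list")
        arr = np.asarray(explicit_list, dtype=float)
        if arr.size and (arr[:, :2].max() >= cis.n_bins or arr[:, :2].min() < 0):
            raise ValueError("explicit list references unknown bins")
        return ConstraintSet(
            chrom=cis.chrom,
            threshold=float("nan"),
            i=arr[:, 0].astype(np.int64) if arr.size else np.array([], np.int64),
            j=arr[:, 1].astype(np.int64) if arr.size else np.array([], np.int64),
            values=arr[:, 2] if arr.size else np.array([]),
            provenance="explicit-list",
            n_source=len(cis),
        )

    ts = if_thresholds(cis, q=q)
    if mode == "mean":
        cutoff, prov = ts.mean, "mean"
    elif mode == "median":
        cutoff, prov = ts.median, "median"
    elif mode == "percentile":
        cutoff, prov = ts.percentile, f"percentile({q:g})"
    else:
        raise ValueError(f"unknown mode {mode!r}")

    mask = cis.values > cutoff
    if not mask.any():
        warnings.warn(
            f"threshold {cutoff:g} leaves no constraints on {cis.chrom}",
            stacklevel=2,
        )
    return ConstraintSet(
        chrom=cis.chrom,
        threshold=float(cutoff),
        i=cis.i[mask],
        j=cis.j[mask],
        values=cis.values[mask],
        provenance=prov,
        n_source=len(cis),
    )


def read_fithic_pairs(path, bins: GenomeBins, chrom: str) -> np.ndarray:
    """Map a FitHiC-style significant-pair file to local (i, j, IF) rows.

    Expected columns (tab-separated, optional header): chrom1, mid1,
    chrom2, mid2, and a contact-count/IF column.  Only cis pairs on
    ``chrom`` are returned; midpoints map to the containing bin.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 5:
        raise ParseError("FitHiC file needs >= 5 columns")
    df.columns = ["chrom1", "mid1", "chrom2", "mid2", "value"] + list(
        df.columns[5:]
    )
    sub = df[(df["chrom1"].astype(str) == chrom)
             & (df["chrom2"].astype(str) == chrom)]
    n_bins = bins.n_bins(chrom)
    rows = []
    for _, r in sub.iterrows():
        bi = int(r["mid1"]) // bins.bin_size
        bj = int(r["mid2"]) // bins.bin_size
        if bi == bj:
            continue
        if bi > bj:
            bi, bj = bj, bi
        if bj >= n_bins:
            raise ValueError(f"midpoint maps outside {chrom} ({bj} >= {n_bins})")
        rows.append((bi, bj, float(r["value"])))
    return np.array(rows, dtype=float).reshape(-1, 3)


def sequencing_depth(n_paired_reads: int, read_length: int, genome_size: int) -> float:
    """Fold coverage: (paired reads * 2 * read length) / genome size."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if n_paired_reads <= 0 or read_length <= 0:
        raise ValueError("reads and read length must be positive")
    return (n_paired_reads * 2 * read_length) / genome_size


def write_hicpro(bins: GenomeBins, entries: np.ndarray, bins_path, matrix_path) -> None:
    """Write the (abs-BED, sparse matrix) pair; inverse of :func:`read_hicpro`."""
    bins.table[["chrom", "start", "end", "global_id"]].to_csv(
        bins_path, sep="\t", header=False, index=False
    )
    with open(matrix_path, "w") as fh:
        for a, b, v in zip(entries["id_a"], entries["id_b"], entries["value"]):
            fh.write(f"{a}\t{b}\t{v:.17g}\n")
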