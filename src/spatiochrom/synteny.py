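"""Gene-to-bin mapping, ALG classification, microsynteny detection and
chromosome-homology testing.

Gene tables are BED-like data frames (chrom, start, end, gene_id, strand)
with 0-based half-open coordinates.  Orthology is a gene_id -> orthogroup
mapping; ALG labels mark genes that retained their ancestral chromosome
identity.

The microsynteny dialect implemented here is order- and strand-free: a
block is a maximal set of orthogroups shared by two species such that, in
both species, consecutive member genes (sorted by position) are separated
by at most ``max_intervening`` annotated non-member genes.  Blocks smaller
than ``min_genes`` orthogroups are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .hic_io import GenomeBins

ALG = "ALG"
NONALG = "nonALG"
UNANNOTATED = "unannotated"

GENE_COLUMNS = ["chrom", "start", "end", "gene_id", "strand"]


def make_gene_table(rows) -> pd.DataFrame:
    """Build and validate a gene table from (chrom, start, end, id, strand)."""
    df = pd.DataFrame(rows, columns=GENE_COLUMNS)
    if (df["start"] >= df["end"]).any():
        raise ValueError("gene start must be < end")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicated gene id {dup!r}")
    return df


@dataclass
class BinAnnotation:
    """Per-bin gene content, orthogroups and ALG/nonALG status."""

    chrom: str
    n_bins: int
    genes: list[list[str]]  # gene ids per bin
    orthogroups: list[set[str]]
    status: list[str]  # ALG / nonALG / unannotated

    def bins_of_genes(self, gene_ids) -> dict[str, int]:
        out = {}
        for b, ids in enumerate(self.genes):
            for g in ids:
                if g in gene_ids:
                    out[g] = b
        return out


@dataclass
class MicrosyntenyBlock:
    species_a: str
    species_b: str
    orthogroups: frozenset[str]
    genes_a: pd.DataFrame  # member genes of species A, sorted by position
    genes_b: pd.DataFrame
    chrom_a: str = ""
    chrom_b: str = ""

    def __post_init__(self) -> None:
        if not self.chrom_a:
            self.chrom_a = self.genes_a["chrom"].iloc[0]
        if not self.chrom_b:
            self.chrom_b = self.genes_b["chrom"].iloc[0]

    @property
    def size(self) -> int:
        return len(self.orthogroups)

    def span(self, which: str) -> tuple[int, int]:
        g = self.genes_a if which == "a" else self.genes_b
        return int(g["start"].min()), int(g["end"].max())


def map_genes_to_bins(
    genes: pd.DataFrame,
    bins: GenomeBins,
    chrom: str,
    orthology: dict[str, str] | None = None,
    alg_labels: dict[str, str] | None = None,
) -> BinAnnotation:
    """Assign each gene on ``chrom`` to the bin containing its midpoint.

    Genes whose midpoint falls past the binned chromosome end are assigned
    to the last bin with a warning.
    """
    import warnings

    n_bins = bins.n_bins(chrom)
    sub = genes[genes["chrom"] == chrom]
    per_bin_genes: list[list[str]] = [[] for _ in range(n_bins)]
    per_bin_ogs: list[set[str]] = [set() for _ in range(n_bins)]
    orthology = orthology or {}
    for _, row in sub.iterrows():
        mid = (int(row["start"]) + int(row["end"])) // 2
        b = mid // bins.bin_size
        if b >= n_bins:
            warnings.warn(
                f"gene {row['gene_id']} midpoint beyond binned {chrom}; "
                "assigned to last bin", stacklevel=2,
            )
            b = n_bins - 1
        per_bin_genes[b].append(row["gene_id"])
        og = orthology.get(row["gene_id"])
        if og is not None:
            per_bin_ogs[b].add(og)
    ann = BinAnnotation(chrom, n_bins, per_bin_genes, per_bin_ogs,
                        [UNANNOTATED] * n_bins)
    classify_alg_bins(ann, orthology or {}, alg_labels or {})
    return ann


def classify_alg_bins(ann: BinAnnotation, orthology: dict[str, str],
                      alg_labels: dict[str, str]) -> list[str]:
    """ALG if any gene in the bin carries an ALG label; nonALG if the bin has
    orthologous genes but no ALG gene; unannotated otherwise."""
    status = []
    for ids in ann.genes:
        has_alg = any(g in alg_labels for g in ids)
        has_ortho = any(g in orthology for g in ids)
        if has_alg:
            status.append(ALG)
        elif has_ortho:
            status.append(NONALG)
        else:
            status.append(UNANNOTATED)
    ann.status = status
    return status


def _rank_genes(genes: pd.DataFrame) -> pd.DataFrame:
    """Add a per-chromosome positional rank over all annotated genes."""
    g = genes.sort_values(["chrom", "start"], kind="mergesort").copy()
    g["rank"] = g.groupby("chrom", sort=False).cumcount()
    return g


def _split_by_gap(items: list, ranks: list[int], max_intervening: int):
    """Split rank-sorted items where the intervening-gene count exceeds the
    allowance (intervening = rank difference - 1)."""
    groups, current = [], [items[0]]
    for prev, cur, item in zip(ranks, ranks[1:], items[1:]):
        if cur - prev - 1 > max_intervening:
            groups.append(current)
            current = [item]
        else:
            current.append(item)
    groups.append(current)
    return groups


def detect_microsynteny(
    genes_a: pd.DataFrame,
    genes_b: pd.DataFrame,
    orthology: dict[str, str],
    min_genes: int = 3,
    max_intervening: int = 5,
    species_a: str = "A",
    species_b: str = "B",
) -> list[MicrosyntenyBlock]:
    """Detect order-free microsyntenic blocks between two species.

    For every chromosome pair, shared orthogroups are iteratively split at
    gaps of more than ``max_intervening`` intervening genes in either
    species until stable (a fixed point, since a split in one species can
    open a gap in the other); surviving clusters of at least ``min_genes``
    orthogroups are returned.
    """
    for df, name in ((genes_a, species_a), (genes_b, species_b)):
        if df["gene_id"].duplicated().any():
            raise ValueError(f"duplicated gene ids in species {name}")

    ra = _rank_genes(genes_a)
    rb = _rank_genes(genes_b)
    ra["og"] = ra["gene_id"].map(orthology)
    rb["og"] = rb["gene_id"].map(orthology)

    # One representative gene per (orthogroup, chromosome): the first by
    # position.  Multi-copy orthogroups are rare in the intended inputs.
    rep_a = ra.dropna(subset=["og"]).drop_duplicates(["og", "chrom"])
    rep_b = rb.dropna(subset=["og"]).drop_duplicates(["og", "chrom"])

    blocks: list[MicrosyntenyBlock] = []
    for (ca, sub_a) in rep_a.groupby("chrom", sort=False):
        ogs_a = set(sub_a["og"])
        for (cb, sub_b) in rep_b.groupby("chrom", sort=False):
            shared = ogs_a & set(sub_b["og"])
            if len(shared) < min_genes:
                continue
            clusters = [shared]
            stable = False
            while not stable:
                stable = True
                next_clusters = []
                for cl in clusters:
                    parts = [cl]
                    for sub in (sub_a, sub_b):
                        new_parts = []
                        for part in parts:
                            mem = sub[sub["og"].isin(part)].sort_values("rank")
                            ogs = mem["og"].tolist()
                            ranks = mem["rank"].tolist()
                            pieces = _split_by_gap(ogs, ranks, max_intervening)
                            new_parts.extend(set(p) for p in pieces)
                        parts = new_parts
                    if len(parts) > 1:
                        stable = False
                    next_clusters.extend(parts)
                clusters = [c for c in next_clusters if len(c) >= min_genes]
            for cl in clusters:
                mem_a = sub_a[sub_a["og"].isin(cl)].sort_values("start")
                mem_b = sub_b[sub_b["og"].isin(cl)].sort_values("start")
                blocks.append(MicrosyntenyBlock(
                    species_a=species_a, species_b=species_b,
                    orthogroups=frozenset(cl),
                    genes_a=mem_a.reset_index(drop=True),
                    genes_b=mem_b.reset_index(drop=True),
                    chrom_a=ca, chrom_b=cb,
                ))
    return blocks


def verify_block(block: MicrosyntenyBlock, genes_a: pd.DataFrame,
                 genes_b: pd.DataFrame, max_intervening: int = 5) -> bool:
    """Independent recount of the intervening-gene invariant."""
    for genes, members in ((genes_a, block.genes_a), (genes_b, block.genes_b)):
        chrom = members["chrom"].iloc[0]
        ordered = genes[genes["chrom"] == chrom].sort_values("start")
        ids = ordered["gene_id"].tolist()
        pos = sorted(ids.index(g) for g in members["gene_id"])
        for p, q in zip(pos, pos[1:]):
            if q - p - 1 > max_intervening:
                return False
    return True


def sample_random_blocks(
    block: MicrosyntenyBlock,
    genes: pd.DataFrame,
    orthology: dict[str, str],
    n: int = 100,
    mode: str = "genome",
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Size-matched random blocks: contiguous runs of orthologous genes.

    Each sample is a run of ``block.size`` consecutive orthologous genes
    starting at a uniformly drawn position; ``mode='chromosome'`` restricts
    starts to the chromosome bearing the observed block.
    """
    if mode not in ("genome", "chromosome"):
        raise ValueError("mode must be 'genome' or 'chromosome'")
    universe = genes[genes["gene_id"].isin(orthology)].copy()
    if mode == "chromosome":
        universe = universe[universe["chrom"] == block.chrom_a]
    universe = universe.sort_values(["chrom", "start"], kind="mergesort")
    size = block.size
    # valid starts keep the run within one chromosome
    starts = []
    offset = 0
    for _, sub in universe.groupby("chrom", sort=False):
        m = len(sub)
        if m >= size:
            starts.extend(range(offset, offset + m - size + 1))
        offset += m
    if not starts:
        raise ValueError(
            f"sampling universe too small for a block of {size} genes"
        )
    rng = np.random.default_rng(seed)
    rows = universe.reset_index(drop=True)
    out = []
    for s in rng.choice(len(starts), size=n, replace=True):
        lo = starts[s]
        out.append(rows.iloc[lo:lo + size].reset_index(drop=True))
    return out


@dataclass
class HomologyMatrix:
    """Chromosome-pair ortholog counts with Fisher enrichment tests."""

    table: pd.DataFrame  # chrom_a, chrom_b, count, p, q, homologous

    @property
    def calls(self) -> list[tuple[str, str]]:
        hit = self.table[self.table["homologous"]]
        return list(zip(hit["chrom_a"], hit["chrom_b"]))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, >= p)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    q = np.maximum(q, p)  # guard one-ulp rounding in p*m/rank
    q[order] = np.maximum.accumulate(q[order])
    return q


def chromosome_homology(
    orthologs: pd.DataFrame,
    alpha: float = 0.05,
) -> HomologyMatrix:
    """Fisher-exact chromosome homology from one-to-one ortholog placements.

    ``orthologs`` columns: orthogroup, chrom_a, chrom_b.  For each
    chromosome pair a 2x2 table (on-pair vs off-pair counts) is tested
    one-sided for enrichment against the gene-permutation null; BH
    correction across all pairs; calls at q < alpha.
    """
    if len(orthologs) == 0:
        raise ValueError("empty ortholog set")
    counts = (orthologs.groupby(["chrom_a", "chrom_b"]).size()
              .rename("count").reset_index())
    total = len(orthologs)
    n_a = orthologs.groupby("chrom_a").size()
    n_b = orthologs.groupby("chrom_b").size()
    rows = []
    chroms_a = sorted(orthologs["chrom_a"].unique())
    chroms_b = sorted(orthologs["chrom_b"].unique())
    lut = {(r.chrom_a, r.chrom_b): r.count for r in counts.itertuples()}
    for ca in chroms_a:
        for cb in chroms_b:
            k = int(lut.get((ca, cb), 0))
            a_tot = int(n_a[ca])
            b_tot = int(n_b[cb])
            table = [[k, a_tot - k], [b_tot - k, total - a_tot - b_tot + k]]
            _, p = fisher_exact(table, alternative="greater")
            rows.append((ca, cb, k, float(p)))
    df = pd.DataFrame(rows, columns=["chrom_a", "chrom_b", "count", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["homologous"] = df["q"] < alpha
    return HomologyMatrix(df)


def write_blocks_tsv(blocks: list[MicrosyntenyBlock], path) -> None:
    rows = []
    for k, b in enumerate(blocks):
        sa, ea = b.span("a")
        sb, eb = b.span("b")
        rows.append((k, b.species_a, b.chrom_a, sa, ea,
                     b.species_b, b.chrom_b, sb, eb, b.size,
                     ",".join(sorted(b.orthogroups))))
    pd.DataFrame(rows, columns=[
        "block_id", "species_a", "chrom_a", "start_a", "end_a",
        "species_b", "chrom_b", "start_b", "end_b", "n_orthogroups",
        "orthogroups",
    ]).to_csv(path, sep="\t", index=False)
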