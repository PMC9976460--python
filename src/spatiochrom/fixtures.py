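"""Seeded synthetic inputs for the whole pipeline.

Generates known 3D bead structures, distance-decay contact matrices in the
HiC-Pro text dialect, and a pair of pseudo-species genomes with a planted
one-to-one chromosome homology, ALG/nonALG gene partition and microsyntenic
blocks.  Every generator is deterministic given its seed and a truth
manifest records what was planted, so detection code can be scored against
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import synteny
from .hic_io import DEFAULT_BIN_SIZE, CisMatrix, GenomeBins, write_hicpro
from .reconstruct import Conformation, init_sarw
from .synteny import detect_microsynteny, make_gene_table


@dataclass
class DecayModel:
    """Power-law distance decay: IF = scale * (d / d_ref)^(-alpha)."""

    alpha: float = 1.0
    scale: float = 10.0
    d_ref: float = 50.0
    noise: str = "none"  # or "poisson"

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.scale <= 0 or self.d_ref <= 0:
            raise ValueError("decay parameters must be positive")
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")


def make_structure(n_beads: int, motif: str = "sarw", seed: int = 0,
                   step: float = 55.0, radius: float = 150.0,
                   pitch: float = 40.0) -> Conformation:
    """Deterministic test structures.

    ``helix`` and ``rosette`` have closed-form coordinates (analytic
    checks); ``sarw`` is a self-avoiding random walk.
    """
    if n_beads < 2:
        raise ValueError("need at least 2 beads")
    if motif == "sarw":
        return init_sarw(n_beads, step_length=step, exclusion=0.9 * step,
                         seed=seed)
    if motif == "helix":
        # constant angular step chosen so consecutive beads are `step` apart
        dz = pitch
        chord = np.sqrt(max(step**2 - dz**2, 1e-9))
        theta = 2.0 * np.arcsin(chord / (2.0 * radius))
        t = np.arange(n_beads)
        coords = np.column_stack([
            radius * np.cos(theta * t),
            radius * np.sin(theta * t),
            dz * t,
        ])
        return Conformation("chr", coords)
    if motif == "rosette":
        t = np.arange(n_beads, dtype=float)
        petal = radius * np.abs(np.cos(3.0 * t * 0.15))
        coords = np.column_stack([
            (petal + 20.0) * np.cos(t * 0.35),
            (petal + 20.0) * np.sin(t * 0.35),
            10.0 * np.sin(t * 0.05),
        ])
        return Conformation("chr", coords)
    raise ValueError(f"unknown motif {motif!r}")


def contacts_from_structure(conf: Conformation, model: DecayModel,
                            seed: int = 0, chrom: str | None = None,
                            bin_size: int = DEFAULT_BIN_SIZE) -> CisMatrix:
    """Contact matrix implied by a known structure under distance decay."""
    n = conf.n_beads
    iu, ju = np.triu_indices(n, k=1)
    d = np.linalg.norm(conf.coords[ju] - conf.coords[iu], axis=1)
    if np.any(d <= 0):
        raise ValueError("structure has non-positive pairwise distances")
    expected = model.scale * (d / model.d_ref) ** (-model.alpha)
    if model.noise == "poisson":
        rng = np.random.default_rng(seed)
        values = rng.poisson(expected).astype(float)
    else:
        values = expected
    keep = values > 0
    return CisMatrix(
        chrom=chrom or conf.chrom, n_bins=n,
        i=iu[keep], j=ju[keep], values=values[keep], bin_size=bin_size,
    )


@dataclass
class PlantedTruth:
    """Manifest of everything the genome generator planted."""

    seed: int
    n_chrom: int
    genes_per_chrom: int
    alg_fraction: float
    block_size: int
    homologous_pairs: list[tuple[str, str]]
    planted_blocks: list[dict]  # orthogroups + chrom per species

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class GenomePair:
    genes_a: pd.DataFrame
    genes_b: pd.DataFrame
    orthology: dict[str, str]  # gene_id -> orthogroup (both species)
    alg_a: dict[str, str]
    alg_b: dict[str, str]
    truth: PlantedTruth


def make_genomes(
    n_chrom: int = 3,
    genes_per_chrom: int = 120,
    alg_fraction: float = 0.8,
    n_blocks: int = 4,
    block_size: int = 4,
    seed: int = 0,
    gene_spacing: int = 25_000,
    gene_length: int = 10_000,
    ortholog_fraction: float = 0.25,
    max_shuffle_tries: int = 20,
) -> GenomePair:
    """Two pseudo-species genomes with planted homology, ALGs and blocks.

    Species A and B have ``n_chrom`` chromosomes each with a planted
    one-to-one homology (A_chr<k> ~ B_chr<k>).  A fraction of orthologous
    genes keep their homologous chromosome (ALG genes); the rest move to a
    different chromosome (nonALG).  ``n_blocks`` microsyntenic blocks of
    ``block_size`` adjacent orthologs are planted on homologous chromosome
    pairs; all other B-side gene positions are shuffled, with rejection of
    shuffles that create accidental blocks so noise-free detection recovers
    exactly the planted truth.
    """
    total = n_chrom * genes_per_chrom
    if n_blocks * block_size > genes_per_chrom // 2:
        raise ValueError("infeasible packing: too many planted block genes")
    rng = np.random.default_rng(seed)

    # --- species A: genes laid out sequentially per chromosome
    rows_a = []
    for c in range(n_chrom):
        chrom = f"A_chr{c}"
        for g in range(genes_per_chrom):
            start = g * gene_spacing
            rows_a.append((chrom, start, start + gene_length,
                           f"A_g{c}_{g:04d}", "+"))
    genes_a = make_gene_table(rows_a)

    # orthologous subset of A genes
    orthology: dict[str, str] = {}
    og_counter = 0
    a_ortho_mask = rng.random(total) < ortholog_fraction
    a_ids = genes_a["gene_id"].tolist()
    a_chrom_of = dict(zip(genes_a["gene_id"], genes_a["chrom"]))
    og_of_a: dict[str, str] = {}
    for gid, is_ortho in zip(a_ids, a_ortho_mask):
        if is_ortho:
            og = f"OG{og_counter:05d}"
            og_counter += 1
            orthology[gid] = og
            og_of_a[gid] = og

    # --- plant blocks: runs of block_size consecutive A genes, forced
    # orthologous, with a 6-gene buffer so neighbouring diagonal orthologs
    # cannot chain onto a planted block (the gap allowance is 5).
    buffer_width = 6
    planted: list[dict] = []
    block_ogs_by_chrom: dict[int, list[list[str]]] = {c: [] for c in range(n_chrom)}
    block_slots: dict[int, set[int]] = {c: set() for c in range(n_chrom)}
    reserved: dict[int, set[int]] = {c: set() for c in range(n_chrom)}
    buffer_genes: set[str] = set()
    for b in range(n_blocks):
        c = b % n_chrom
        for _ in range(200):
            start_g = int(rng.integers(0, genes_per_chrom - block_size))
            span = set(range(start_g, start_g + block_size))
            halo = set(range(start_g - buffer_width,
                             start_g + block_size + buffer_width))
            if halo & reserved[c]:
                continue
            gids = [f"A_g{c}_{g:04d}" for g in sorted(span)]
            for g in gids:  # planting overrides the random orthology mask
                if g not in og_of_a:
                    og = f"OG{og_counter:05d}"
                    og_counter += 1
                    orthology[g] = og
                    og_of_a[g] = og
            block_slots[c] |= span
            reserved[c] |= halo
            for s in halo - span:
                if 0 <= s < genes_per_chrom:
                    buffer_genes.add(f"A_g{c}_{s:04d}")
            ogs = [og_of_a[g] for g in gids]
            block_ogs_by_chrom[c].append(ogs)
            planted.append({
                "orthogroups": sorted(ogs),
                "chrom_a": f"A_chr{c}", "chrom_b": f"B_chr{c}",
            })
            break
        else:
            raise ValueError("infeasible packing: could not place a block")

    # ALG / nonALG split of the remaining (non-block) orthologous genes.
    # Buffer genes are forced nonALG so they leave the homologous
    # chromosome, and the per-chromosome ALG count is capped below the
    # order-free chaining threshold (one shared gene per 7 positions).
    block_genes = {g for c in block_slots for s in block_slots[c]
                   for g in [f"A_g{c}_{s:04d}"]}
    chain_cap = max(genes_per_chrom // 7 - 1, 1)
    alg_a: dict[str, str] = {}
    is_alg: dict[str, bool] = {}
    for c in range(n_chrom):
        free_c = [g for g in og_of_a
                  if g not in block_genes and g not in buffer_genes
                  and a_chrom_of[g] == f"A_chr{c}"]
        n_alg = min(int(round(alg_fraction * len(free_c))), chain_cap)
        chosen = set(rng.choice(len(free_c), size=n_alg, replace=False)
                     ) if n_alg else set()
        for k, gid in enumerate(free_c):
            keep = k in chosen
            is_alg[gid] = keep
            if keep:
                alg_a[gid] = f"ALG{c}"
    for gid in buffer_genes & set(og_of_a):
        is_alg[gid] = False
    for gid in block_genes:  # planted blocks sit on homologous chromosomes
        is_alg[gid] = True
        c = int(a_chrom_of[gid].rsplit("chr", 1)[1])
        alg_a[gid] = f"ALG{c}"

    # --- species B layout, with rejection of accidental blocks
    for attempt in range(max_shuffle_tries):
        genes_b, alg_b, ortho_b = _layout_species_b(
            n_chrom, genes_per_chrom, gene_spacing, gene_length,
            og_of_a, a_chrom_of, is_alg, block_ogs_by_chrom, rng,
        )
        full_orthology = {**orthology, **ortho_b}
        found = detect_microsynteny(genes_a, genes_b, full_orthology)
        found_sets = {frozenset(b.orthogroups) for b in found}
        want_sets = {frozenset(p["orthogroups"]) for p in planted}
        if found_sets == want_sets:
            orthology = full_orthology
            break
    else:
        raise RuntimeError(
            "could not produce a shuffle free of accidental blocks"
        )

    truth = PlantedTruth(
        seed=seed, n_chrom=n_chrom, genes_per_chrom=genes_per_chrom,
        alg_fraction=alg_fraction, block_size=block_size,
        homologous_pairs=[(f"A_chr{c}", f"B_chr{c}") for c in range(n_chrom)],
        planted_blocks=planted,
    )
    return GenomePair(genes_a=genes_a, genes_b=genes_b, orthology=orthology,
                      alg_a=alg_a, alg_b=alg_b, truth=truth)


def _stride_factor(m: int, rng) -> int:
    """Multiplier u (coprime with m) maximizing the minimal circular
    distance of u*d mod m over small d, so genes adjacent in one species
    land far apart in the other."""
    import math

    best_u, best_score = 1, -1
    for u in range(2, m - 1):
        if math.gcd(u, m) != 1:
            continue
        score = min(min((u * d) % m, m - (u * d) % m) for d in range(1, 7))
        if score > best_score:
            best_u, best_score = u, score
    return best_u


def _interleave(items: list, members: list) -> list:
    """Insert ``members`` into ``items`` at evenly spaced final positions."""
    if not members:
        return list(items)
    n_total = len(items) + len(members)
    slots = np.linspace(0, n_total - 1, len(members)).round().astype(int)
    slots = np.unique(slots)
    out: list = [None] * n_total
    mi, bi = 0, 0
    marker = object()
    for slot in range(n_total):
        if mi < len(slots) and slot == slots[mi]:
            out[slot] = (members[mi], marker)
            mi += 1
    for slot in range(n_total):
        if out[slot] is None:
            if bi < len(items):
                out[slot] = items[bi]
                bi += 1
            elif mi < len(members):
                out[slot] = (members[mi], marker)
                mi += 1
    return [x[0] if isinstance(x, tuple) and len(x) == 2 and x[1] is marker
            else x for x in out]


def _layout_species_b(n_chrom, genes_per_chrom, gene_spacing, gene_length,
                      og_of_a, a_chrom_of, is_alg, block_ogs_by_chrom,
                      rng) -> tuple[pd.DataFrame, dict[str, str], dict[str, str]]:
    """Place B-side genes.

    Planted blocks stay contiguous on the homologous chromosome.  Background
    ALG orthologs stay on the homologous chromosome but in stride-permuted
    order: genes genomically close in species A end up far apart in species
    B, which prevents the dense ALG complement from chaining into accidental
    order-free blocks.  nonALG orthologs move to a random other chromosome;
    non-orthologous filler pads every chromosome.
    """
    a_order: dict[str, int] = {}
    for gid in og_of_a:  # insertion order follows the A layout
        a_order[og_of_a[gid]] = len(a_order)
    # per target chromosome, orthologs grouped by their source chromosome;
    # each group is strided independently so no two A-close genes of the
    # same chromosome pair end up B-close
    groups_for_chrom: dict[int, dict[int, list[str]]] = {
        c: {} for c in range(n_chrom)
    }
    block_ogs = {og for c in block_ogs_by_chrom
                 for blk in block_ogs_by_chrom[c] for og in blk}
    for gid, og in og_of_a.items():
        if og in block_ogs:
            continue
        c_home = int(a_chrom_of[gid].rsplit("chr", 1)[1])
        if is_alg[gid]:
            target = c_home
        else:
            choices = [c for c in range(n_chrom) if c != c_home] or [c_home]
            target = int(rng.choice(choices))
        groups_for_chrom[target].setdefault(c_home, []).append(og)

    rows_b = []
    alg_b: dict[str, str] = {}
    ortho_b: dict[str, str] = {}
    og_is_alg = {og_of_a[g]: is_alg.get(g, False) for g in og_of_a}
    og_home = {og_of_a[g]: int(a_chrom_of[g].rsplit("chr", 1)[1])
               for g in og_of_a}
    gid_counter = 0
    for c in range(n_chrom):
        groups = groups_for_chrom[c]
        n_group_genes = sum(len(g) for g in groups.values())
        n_filler = (genes_per_chrom - n_group_genes
                    - sum(len(b) for b in block_ogs_by_chrom[c]))
        items: list[object] = [None] * max(n_filler, 0)
        # insert each source-chromosome group at even slots in stride order;
        # later insertions only stretch earlier groups' gaps
        for home in sorted(groups, key=lambda h: len(groups[h])):
            members = sorted(groups[home], key=lambda og: a_order[og])
            m = len(members)
            if m >= 7:
                u = _stride_factor(m, rng)
                strided: list[str] = [None] * m  # type: ignore[list-item]
                for jj, og in enumerate(members):
                    strided[(u * jj) % m] = og
                members = strided
            items = _interleave(items, members)
        # splice planted blocks in as contiguous runs at random offsets
        for blk in block_ogs_by_chrom[c]:
            pos = int(rng.integers(0, len(items) + 1))
            items = items[:pos] + list(blk) + items[pos:]
        for slot, item in enumerate(items):
            start = slot * gene_spacing
            gid = f"B_g{gid_counter:05d}"
            gid_counter += 1
            rows_b.append((f"B_chr{c}", start, start + gene_length, gid, "+"))
            if item is not None:
                ortho_b[gid] = item
                # B-side ALG labels mirror retained chromosome identity
                if og_is_alg.get(item, False) and og_home[item] == c:
                    alg_b[gid] = f"ALG{c}"
    return make_gene_table(rows_b), alg_b, ortho_b


def genome_bins_for(genes: pd.DataFrame, bin_size: int = DEFAULT_BIN_SIZE,
                    first_global_id: int = 1) -> GenomeBins:
    """abs-BED-style bin table covering each chromosome's gene extent."""
    rows = []
    gid = first_global_id
    for chrom, sub in genes.groupby("chrom", sort=False):
        length = int(sub["end"].max())
        n_bins = max(1, -(-length // bin_size))
        for k in range(n_bins):
            start = k * bin_size
            end = min(start + bin_size, n_bins * bin_size)
            rows.append((chrom, start, end, gid, k))
            gid += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "global_id",
                                     "local_index"])
    return GenomeBins(df, bin_size=bin_size)


def cis_to_entries(cis: CisMatrix, bins: GenomeBins) -> np.ndarray:
    """Map a local cis matrix back to global-id entries for serialization."""
    sub = bins.table[bins.table["chrom"] == cis.chrom]
    local_to_global = dict(zip(sub["local_index"], sub["global_id"]))
    entries = np.zeros(len(cis), dtype=[("id_a", np.int64),
                                        ("id_b", np.int64), ("value", float)])
    entries["id_a"] = [local_to_global[int(x)] for x in cis.i]
    entries["id_b"] = [local_to_global[int(x)] for x in cis.j]
    entries["value"] = cis.values
    return entries


def write_fixture_bundle(
    out_dir,
    seed: int = 0,
    n_chrom: int = 3,
    genes_per_chrom: int = 120,
    n_beads: int | None = None,
    alpha: float = 1.0,
    n_blocks: int = 4,
    block_size: int = 4,
    bin_size: int = DEFAULT_BIN_SIZE,
    gene_spacing: int = 25_000,
) -> dict:
    """Emit a complete plain-text input bundle into ``out_dir``.

    Contents: HiC-Pro bins+matrix per species (contacts derived from known
    SARW structures under distance decay), gene BEDs, orthology and ALG
    TSVs, true structure xyz tables, and a JSON manifest with seeds,
    parameters and the planted truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pair = make_genomes(n_chrom=n_chrom, genes_per_chrom=genes_per_chrom,
                        n_blocks=n_blocks, block_size=block_size, seed=seed,
                        gene_spacing=gene_spacing)
    paths: dict[str, str] = {}
    decay = DecayModel(alpha=alpha)
    for label, genes in (("A", pair.genes_a), ("B", pair.genes_b)):
        bins = genome_bins_for(genes, bin_size=bin_size)
        all_entries = []
        for c, chrom in enumerate(bins.chromosomes):
            nb = n_beads or bins.n_bins(chrom)
            struct = make_structure(nb, "sarw",
                                    seed=seed * 1000 + c + (0 if label == "A"
                                                            else 500))
            struct.chrom = chrom
            cis = contacts_from_structure(struct, decay, chrom=chrom,
                                          bin_size=bin_size)
            # clip to the binned chromosome if n_beads was overridden
            if cis.n_bins != bins.n_bins(chrom):
                keep = (cis.i < bins.n_bins(chrom)) & (cis.j < bins.n_bins(chrom))
                cis = CisMatrix(chrom, bins.n_bins(chrom), cis.i[keep],
                                cis.j[keep], cis.values[keep], bin_size)
            all_entries.append(cis_to_entries(cis, bins))
            xyz_path = out / f"structure_{label}_{chrom}.tsv"
            from .model_io import write_xyz
            write_xyz(struct, xyz_path)
            paths[f"structure_{label}_{chrom}"] = str(xyz_path)
        entries = np.concatenate(all_entries)
        bins_path = out / f"bins_{label}.bed"
        matrix_path = out / f"matrix_{label}.tsv"
        write_hicpro(bins, entries, bins_path, matrix_path)
        paths[f"bins_{label}"] = str(bins_path)
        paths[f"matrix_{label}"] = str(matrix_path)
        genes_path = out / f"genes_{label}.bed"
        genes.assign(score=0)[["chrom", "start", "end", "gene_id", "score",
                               "strand"]].to_csv(genes_path, sep="\t",
                                                 header=False, index=False)
        paths[f"genes_{label}"] = str(genes_path)

    ortho_path = out / "orthology.tsv"
    with open(ortho_path, "w") as fh:
        for gid in sorted(pair.orthology):
            fh.write(f"{gid}\t{pair.orthology[gid]}\n")
    paths["orthology"] = str(ortho_path)
    for label, table in (("A", pair.alg_a), ("B", pair.alg_b)):
        p = out / f"alg_{label}.tsv"
        with open(p, "w") as fh:
            for gid in sorted(table):
                fh.write(f"{gid}\t{table[gid]}\n")
        paths[f"alg_{label}"] = str(p)

    manifest = {
        "seed": seed, "n_chrom": n_chrom, "genes_per_chrom": genes_per_chrom,
        "alpha": alpha, "n_blocks": n_blocks, "block_size": block_size,
        "bin_size": bin_size, "paths": paths,
        "truth": json.loads(pair.truth.to_json()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = str(out / "manifest.json")
    return manifest


def read_gene_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene_id", "score",
                            "strand"])
    return df[["chrom", "start", "end", "gene_id", "strand"]]


def read_two_column_tsv(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                k, v = line.rstrip("\n").split("\t")
                out[k] = v
    return out
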