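"""Serialization of chromosome models as pseudo-atom PDB and xyz tables.

Each bead becomes one CA pseudo-atom (one residue per bead, sequential
residue numbers, one chain per chromosome); CONECT records link consecutive
beads.  Coordinates in nm are divided by a scale factor so they fit the
fixed 8.3 PDB columns; the scale, chromosome id and bin size ride along in
REMARK lines so a read-back recovers nm coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .reconstruct import Conformation

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_MAX_RESIDUES_PER_CHAIN = 9999  # PDB residue-number column limit


@dataclass
class PdbScale:
    """nm-per-PDB-unit divisor applied before writing coordinates."""

    divisor: float = 10.0

    def __post_init__(self) -> None:
        if self.divisor <= 0:
            raise ValueError("divisor must be positive")


def write_pdb(conf: Conformation, path, scale: PdbScale | None = None,
              bin_size: int | None = None) -> None:
    if scale is None:
        scale = PdbScale()
    xyz = conf.coords / scale.divisor
    if np.any(np.abs(xyz) >= 10_000):
        raise ValueError(
            "scaled coordinate overflows the 8.3 PDB column; "
            "increase the scale divisor"
        )
    lines = [
        f"REMARK 250 CHROMOSOME {conf.chrom}",
        f"REMARK 250 SCALE_NM_PER_UNIT {scale.divisor:g}",
    ]
    if bin_size is not None:
        lines.append(f"REMARK 250 BIN_SIZE_BP {bin_size}")
    serial = 0
    for k in range(conf.n_beads):
        serial += 1
        chain = _CHAIN_IDS[k // _MAX_RESIDUES_PER_CHAIN]
        resseq = k % _MAX_RESIDUES_PER_CHAIN + 1
        x, y, z = xyz[k]
        lines.append(
            f"ATOM  {serial:5d}  CA  BED {chain}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    for k in range(conf.n_beads - 1):
        lines.append(f"CONECT{k + 1:5d}{k + 2:5d}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_pdb(path) -> tuple[Conformation, dict]:
    """Read a bead-per-residue CA-trace PDB written by :func:`write_pdb`.

    Also accepts a standard single-chain CA trace; without a REMARK scale
    line the scale defaults to 1 (with a warning).
    """
    meta: dict = {}
    coords = []
    chains = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("REMARK 250 CHROMOSOME"):
                meta["chrom"] = line.split()[-1]
            elif line.startswith("REMARK 250 SCALE_NM_PER_UNIT"):
                meta["scale"] = float(line.split()[-1])
            elif line.startswith("REMARK 250 BIN_SIZE_BP"):
                meta["bin_size"] = int(line.split()[-1])
            elif line.startswith("ATOM") or line.startswith("HETATM"):
                name = line[12:16].strip()
                if name != "CA":
                    continue
                chains.add(line[21])
                coords.append(
                    (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                )
    if not coords:
        raise ValueError(f"{path}: no CA atoms found")
    # Sequential chains from the >9999-residue rollover are one chromosome;
    # anything else is ambiguous.
    if len(chains) > 1 and sorted(chains) != list(
        _CHAIN_IDS[: len(chains)]
    ):
        raise ValueError("multiple unrelated chains: one chromosome per model")
    if "scale" not in meta:
        warnings.warn("no REMARK scale found; assuming 1 nm per PDB unit",
                      stacklevel=2)
        meta["scale"] = 1.0
    xyz = np.array(coords) * meta["scale"]
    return Conformation(meta.get("chrom", "chr"), xyz), meta


def write_xyz(conf: Conformation, path) -> None:
    """Plain TSV: bead_index, x_nm, y_nm, z_nm."""
    with open(path, "w") as fh:
        fh.write("bead_index\tx_nm\ty_nm\tz_nm\n")
        for k, (x, y, z) in enumerate(conf.coords):
            fh.write(f"{k}\t{x:.17g}\t{y:.17g}\t{z:.17g}\n")


def read_xyz(path, chrom: str = "chr") -> Conformation:
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    order = np.argsort(data[:, 0])
    return Conformation(chrom, data[order, 1:4])
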