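import numpy as np
import pytest

from spatiochrom.fixtures import (
    DecayModel,
    contacts_from_structure,
    make_genomes,
    make_structure,
)
from spatiochrom.hic_io import GenomeBins
import pandas as pd


@pytest.fixture(scope="session")
def genome_pair():
    """Default two-species synthetic genome pair (seed 1)."""
    return make_genomes(seed=1)


@pytest.fixture(scope="session")
def truth50():
    """Known 50-bead SARW structure used as reconstruction ground truth."""
    return make_structure(50, "sarw", seed=3)


@pytest.fixture(scope="session")
def cis50(truth50):
    """Noise-free distance-decay contacts of the 50-bead truth structure."""
    return contacts_from_structure(truth50, DecayModel(alpha=1.0))


@pytest.fixture
def tiny_bins_file(tmp_path):
    """3-bin single-chromosome abs-BED file."""
    p = tmp_path / "bins.bed"
    p.write_text(
        "chrA\t0\t150000\t1\n"
        "chrA\t150000\t300000\t2\n"
        "chrA\t300000\t450000\t3\n"
    )
    return p


@pytest.fixture
def two_chrom_bins():
    rows = []
    gid = 1
    for chrom, n in (("chrA", 4), ("chrB", 3)):
        for k in range(n):
            rows.append((chrom, k * 150000, (k + 1) * 150000, gid, k))
            gid += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "global_id",
                                     "local_index"])
    return GenomeBins(df, bin_size=150000)


def write_matrix(path, rows):
    path.write_text("".join(f"{a}\t{b}\t{v}\n" for a, b, v in rows))
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(42)
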