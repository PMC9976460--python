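"""Comparative spatial-synteny statistics.

Distances and nm/Mb spatial ratios over bin pairs, randomized-orthology
nulls, a permutation-calibrated two-dimensional two-sample
(Fasano-Franceschini) test, ALG/nonALG contact-class counting inside
interaction spheres, microsynteny contact-density comparisons, and
conserved spatial-neighbour discovery between two species' models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .intsph import IntSphProfile
from .reconstruct import Conformation
from .synteny import UNANNOTATED, BinAnnotation


@dataclass
class DistancePairs:
    """Per bin pair: Euclidean (nm), genomic (Mb) distance, nm/Mb ratio."""

    table: pd.DataFrame  # columns i, j, euclid_nm, genomic_mb, ratio
    n_dropped_same_bin: int = 0


def pair_distances(conf: Conformation, pairs, bin_size: int = 150_000) -> DistancePairs:
    """Euclidean and genomic distances for bin pairs on one model.

    Same-bin pairs are dropped (zero genomic distance) and counted;
    genomic distance is |i - j| * bin_size in Mb.
    """
    pairs = np.asarray(list(pairs), dtype=np.int64).reshape(-1, 2)
    if pairs.size and (pairs.max() >= conf.n_beads or pairs.min() < 0):
        raise ValueError("bin index out of range for model")
    same = pairs[:, 0] == pairs[:, 1]
    kept = pairs[~same]
    d_nm = np.linalg.norm(conf.coords[kept[:, 1]] - conf.coords[kept[:, 0]],
                          axis=1)
    d_mb = np.abs(kept[:, 1] - kept[:, 0]) * bin_size / 1e6
    df = pd.DataFrame({
        "i": kept[:, 0], "j": kept[:, 1],
        "euclid_nm": d_nm, "genomic_mb": d_mb, "ratio": d_nm / d_mb,
    })
    return DistancePairs(df, n_dropped_same_bin=int(same.sum()))


def randomized_orthology_null(
    pairs: pd.DataFrame,
    statistic,
    n_runs: int = 10,
    seed: int = 0,
):
    """Randomized-orthology null: permute the partner column per run.

    ``pairs`` has columns ``gene_a`` and ``gene_b``; ``statistic`` maps a
    permuted pairing table to a number (or array).  Returns (per-run
    results, median across runs).
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 gene pairs")
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_runs):
        perm = pairs.copy()
        perm["gene_b"] = rng.permutation(perm["gene_b"].to_numpy())
        results.append(statistic(perm))
    return results, np.median(np.asarray(results, dtype=float), axis=0)


def bonferroni(p: float, n_comparisons: int) -> float:
    return min(1.0, p * n_comparisons)


@dataclass
class FFTestResult:
    statistic: float  # D
    p_value: float
    n_perm: int
    seed: int


def _quadrant_membership(points: np.ndarray, origins: np.ndarray) -> np.ndarray:
    """Boolean (4, n_origins, n_points): quadrant k of point relative to origin.

    Quadrants partition the plane (strict/non-strict splits so each point
    lands in exactly one quadrant per origin).
    """
    x = points[:, 0][None, :] > origins[:, 0][:, None]
    y = points[:, 1][None, :] > origins[:, 1][:, None]
    return np.stack([x & y, x & ~y, ~x & y, ~x & ~y])


def _ff_statistic_batched(q_mem: np.ndarray, labels: np.ndarray,
                          n1: int, n2: int) -> np.ndarray:
    """FF D for a batch of labelings.

    ``q_mem`` is the (4, n_origins, n_points) membership tensor for all
    points against all origins; ``labels`` is (n_points, n_batch) boolean
    (True = sample A).  Returns D per batch column, where D averages the
    two max-over-origin quadrant discrepancies (origins in A; origins in B).
    """
    labels = labels.astype(np.float64)
    n_batch = labels.shape[1]
    d_max = np.zeros((q_mem.shape[1], n_batch))
    for k in range(4):
        ca = q_mem[k] @ labels  # (n_origins, n_batch) counts in A
        ct = q_mem[k].sum(axis=1, keepdims=True)  # total counts
        diff = np.abs(ca / n1 - (ct - ca) / n2)
        np.maximum(d_max, diff, out=d_max)
    # origins 0..n1+n2-1 are all points; but which origins belong to A
    # varies per batch labeling.
    d1 = np.where(labels.astype(bool), d_max, 0.0).max(axis=0)
    d2 = np.where(~labels.astype(bool), d_max, 0.0).max(axis=0)
    return 0.5 * (d1 + d2)


def ff_test(sample_a: np.ndarray, sample_b: np.ndarray,
            n_perm: int = 999, seed: int = 0) -> FFTestResult:
    """Two-sample 2D Kolmogorov-Smirnov test (Fasano-Franceschini variant).

    For every data point taken as origin, the four quadrant fractions of
    each sample are compared; D averages the maximal discrepancy over
    sample-A origins and over sample-B origins.  The p-value comes from
    label permutations and has resolution 1/(n_perm + 1).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or b.ndim != 2 or b.shape[1] != 2:
        raise ValueError("samples must be (n, 2) arrays")
    if len(a) < 5 or len(b) < 5:
        raise ValueError("each sample needs at least 5 points")
    pts = np.vstack([a, b])
    if np.allclose(pts, pts[0]):
        raise ValueError("degenerate samples: all points identical")
    n1, n2 = len(a), len(b)
    n = n1 + n2
    q_mem = _quadrant_membership(pts, pts).astype(np.float64)

    obs_labels = np.zeros((n, 1), dtype=bool)
    obs_labels[:n1, 0] = True
    d_obs = float(_ff_statistic_batched(q_mem, obs_labels, n1, n2)[0])

    rng = np.random.default_rng(seed)
    perm_labels = np.zeros((n, n_perm), dtype=bool)
    for c in range(n_perm):
        idx = rng.choice(n, size=n1, replace=False)
        perm_labels[idx, c] = True
    d_perm = _ff_statistic_batched(q_mem, perm_labels, n1, n2)
    p = (1.0 + np.sum(d_perm >= d_obs - 1e-12)) / (n_perm + 1.0)
    return FFTestResult(statistic=d_obs, p_value=float(p),
                        n_perm=n_perm, seed=seed)


@dataclass
class ContactClassCounts:
    chrom: str
    alg_alg: int
    alg_nonalg: int
    nonalg_nonalg: int

    @property
    def total(self) -> int:
        return self.alg_alg + self.alg_nonalg + self.nonalg_nonalg


def alg_contact_counts(profile: IntSphProfile,
                       statuses: list[str]) -> ContactClassCounts:
    """Classify IntSph centre-member pairs by ALG status.

    Each unordered bead pair (centre, member) is counted once; pairs
    involving unannotated beads are excluded.
    """
    if len(statuses) != profile.n_beads:
        raise ValueError("statuses must cover all beads")
    seen: set[tuple[int, int]] = set()
    counts = {("ALG", "ALG"): 0, ("ALG", "nonALG"): 0, ("nonALG", "nonALG"): 0}
    for i in range(profile.n_beads):
        if statuses[i] == UNANNOTATED:
            continue
        for j in profile.members(i):
            j = int(j)
            if statuses[j] == UNANNOTATED:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            pair = tuple(sorted((statuses[i], statuses[j])))
            counts[pair] += 1
    return ContactClassCounts(
        chrom=profile.chrom,
        alg_alg=counts[("ALG", "ALG")],
        alg_nonalg=counts[("ALG", "nonALG")],
        nonalg_nonalg=counts[("nonALG", "nonALG")],
    )


def rank_sum_test(x, y) -> float:
    """Two-sided rank-sum p: exact enumeration for small tie-free samples,
    normal approximation with tie correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and len(x) <= 12 and len(y) <= 12:
        method = "exact"
    else:
        method = "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided",
                              method=method).pvalue)


@dataclass
class DensityTestResult:
    observed_mean: float
    observed_median: float
    random_mean: float
    random_median: float
    p_value: float
    n_observed: int
    n_random: int


def microsynteny_density_test(
    profile: IntSphProfile,
    observed_bins,
    random_bins,
) -> DensityTestResult:
    """Compare contact density of microsynteny-bearing IntSphs vs random.

    The observed sample is the density of spheres centred on bins holding
    at least one observed-block gene; the random sample likewise for the
    size-matched random blocks.  Two-sided rank-sum test.
    """
    obs_idx = sorted(set(int(b) for b in observed_bins))
    rnd_idx = sorted(set(int(b) for b in random_bins))
    if not obs_idx or not rnd_idx:
        raise ValueError("empty observed or random bin sample")
    obs = profile.density[obs_idx].astype(float)
    rnd = profile.density[rnd_idx].astype(float)
    if np.array_equal(np.sort(obs), np.sort(rnd)):
        p = 1.0
    else:
        p = rank_sum_test(obs, rnd)
    return DensityTestResult(
        observed_mean=float(obs.mean()),
        observed_median=float(np.median(obs)),
        random_mean=float(rnd.mean()),
        random_median=float(np.median(rnd)),
        p_value=p,
        n_observed=len(obs),
        n_random=len(rnd),
    )


def shared_spatial_neighbors(
    model_a: Conformation,
    model_b: Conformation,
    query_orthogroups: set[str],
    ann_a: BinAnnotation,
    ann_b: BinAnnotation,
    r: float = 50.0,
) -> set[str]:
    """Orthogroups spatially near the query genes in BOTH species.

    An orthogroup qualifies iff in each species at least one of its bins
    lies within the closed ball of radius ``r`` around some query-gene bin.
    Query orthogroups are excluded from the result.
    """
    import logging
    logger = logging.getLogger(__name__)

    def near_set(model: Conformation, ann: BinAnnotation) -> set[str]:
        query_bins = [b for b, ogs in enumerate(ann.orthogroups)
                      if ogs & query_orthogroups]
        if not query_bins:
            logger.warning("query orthogroups absent on %s", ann.chrom)
            return set()
        q = model.coords[query_bins]
        out: set[str] = set()
        for b, ogs in enumerate(ann.orthogroups):
            if not ogs:
                continue
            d = np.linalg.norm(q - model.coords[b], axis=1)
            if np.any(d <= r):
                out |= ogs
        return out

    if not query_orthogroups:
        return set()
    hits = near_set(model_a, ann_a) & near_set(model_b, ann_b)
    return hits - set(query_orthogroups)
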