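"""Interaction-sphere (IntSph) contact-density profiling.

A sphere of fixed physical radius is centred on every bead; the contact
density of a bead is the number of other beads inside the closed ball.
A radius scan plus a four-parameter logistic fit of mean density against
radius yields a recommended working radius (a fraction of the inflection
point).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .reconstruct import Conformation


@dataclass
class IntSphProfile:
    """Per-bead neighbour counts at one radius; member lists on demand."""

    chrom: str
    radius: float
    density: np.ndarray  # int counts, center excluded
    _members: list[np.ndarray] | None = None

    @property
    def n_beads(self) -> int:
        return len(self.density)

    def members(self, bead: int) -> np.ndarray:
        """Sorted indices of beads inside the sphere centred on ``bead``."""
        if self._members is None:
            raise ValueError("profile built without member sets")
        return self._members[bead]


@dataclass
class SigmoidFit:
    bottom: float
    top: float
    x0: float  # inflection radius, nm
    slope: float
    rss: float

    def predict(self, r: np.ndarray) -> np.ndarray:
        return _logistic4(np.asarray(r, float), self.bottom, self.top,
                          self.x0, self.slope)


def contact_density(conf: Conformation, r: float,
                    keep_members: bool = True,
                    exclude_genomic: int = 0) -> IntSphProfile:
    """Exact closed-ball neighbour counts per bead (KD-tree accelerated).

    Genomic neighbours count by default; ``exclude_genomic=k`` drops beads
    within k chain positions of the centre (sensitivity analyses only).
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    tree = cKDTree(conf.coords)
    neighbor_lists = tree.query_ball_point(conf.coords, r)
    members: list[np.ndarray] = []
    density = np.zeros(conf.n_beads, dtype=np.int64)
    for i, lst in enumerate(neighbor_lists):
        idx = np.array(sorted(lst), dtype=np.int64)
        idx = idx[idx != i]
        if exclude_genomic:
            idx = idx[np.abs(idx - i) > exclude_genomic]
        density[i] = len(idx)
        if keep_members:
            members.append(idx)
    return IntSphProfile(conf.chrom, float(r), density,
                         members if keep_members else None)


def radius_scan(conf: Conformation, radii) -> pd.DataFrame:
    """Mean and median contact density over a sorted list of radii."""
    radii = np.asarray(list(radii), dtype=float)
    if np.any(np.diff(radii) < 0):
        raise ValueError("radii must be sorted ascending")
    rows = []
    for r in radii:
        prof = contact_density(conf, r, keep_members=False)
        rows.append((r, float(prof.density.mean()),
                     float(np.median(prof.density))))
    return pd.DataFrame(rows, columns=["radius", "mean_density",
                                       "median_density"])


def _logistic4(x, bottom, top, x0, slope):
    return bottom + (top - bottom) / (1.0 + np.exp(-(x - x0) / slope))


def fit_sigmoid(scan: pd.DataFrame, column: str = "mean_density",
                misfit_threshold: float = 0.05) -> SigmoidFit:
    """Least-squares 4-parameter logistic fit of density against radius.

    Multi-start from quartile-based initial guesses; deterministic.  Raises
    if no start converges or if the residual exceeds ``misfit_threshold``
    of the data variance (poor sigmoidal shape, e.g. linear data).
    """
    x = scan["radius"].to_numpy(dtype=float)
    y = scan[column].to_numpy(dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 scan points spanning rise and plateau")
    span = x.max() - x.min()
    rng_y = y.max() - y.min()
    x0_starts = np.quantile(x, [0.25, 0.5, 0.75])
    slope_starts = [span / 20.0, span / 8.0, span / 4.0]
    # Bounding bottom/top near the data range and the slope scale away from
    # the large-slope limit keeps the fit genuinely sigmoidal: a straight
    # line is a logistic's limit as slope -> inf, which must stay rejectable.
    lower = [y.min() - 0.1 * rng_y, y.min() - 0.1 * rng_y, x.min(), 1e-9]
    upper = [y.max() + 0.1 * rng_y, y.max() + 0.1 * rng_y, x.max(), span / 4.0]
    best = None
    for x0_0 in x0_starts:
        for s0 in slope_starts:
            p0 = [y.min(), y.max(), x0_0, min(s0, span / 4.0)]
            try:
                popt, _ = curve_fit(
                    _logistic4, x, y, p0=p0, maxfev=20_000,
                    bounds=(lower, upper),
                )
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((_logistic4(x, *popt) - y) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
    if best is None:
        raise RuntimeError("sigmoid fit did not converge from any start")
    popt, rss = best
    bottom, top, x0, slope = (float(v) for v in popt)
    if bottom > top:
        bottom, top = top, bottom
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss > 0 and rss / tss > misfit_threshold:
        raise RuntimeError(
            f"poor sigmoidal fit (relative residual {rss / tss:.3f} > "
            f"{misfit_threshold}); density curve may not be sigmoidal"
        )
    # A sigmoid must flatten inside the scanned range; the fitted logistic's
    # normalized derivative at the largest radius detects scans (or straight
    # lines) that never reach a plateau.
    pe = 1.0 / (1.0 + np.exp(-(x.max() - x0) / slope))
    if 4.0 * pe * (1.0 - pe) > 0.2:
        raise RuntimeError(
            "no plateau within the scanned radius range; extend the scan "
            "or the data is not sigmoidal"
        )
    return SigmoidFit(bottom=bottom, top=top, x0=x0, slope=slope, rss=rss)


def recommend_radius(fit: SigmoidFit, fraction: float = 0.75) -> float:
    """Working radius: ``fraction`` times the inflection point.

    The admissible band for ``fraction`` is [0.5, 1.0].
    """
    if not 0.5 <= fraction <= 1.0:
        raise ValueError("fraction must be within [0.5, 1.0]")
    return fraction * fit.x0
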