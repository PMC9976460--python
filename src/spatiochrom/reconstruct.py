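"""Coarse-grained chromosome reconstruction engine.

A chromosome is a chain of beads (one per genomic bin).  Starting from a
self-avoiding random walk, beads move under damped Newtonian dynamics with
three linear-spring force terms:

* volume exclusion between overlapping beads (active only below the rest
  length ``d_rep0 = 2 * r_bead``),
* chain tension between genomic neighbours (rest length ``c2``),
* contact restraints between bin pairs whose interaction frequency exceeds
  the chosen cutoff (rest length ``d_hic0``).

Trajectories are integrated with classic (position) Verlet; the velocity in
the drag term is estimated from successive positions.  Convergence is
monitored through a pseudo-energy (kinetic plus spring potential) and the
superposition RMSD of recorded snapshots against the final structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .hic_io import CisMatrix, ConstraintSet, select_constraints

logger = logging.getLogger(__name__)


@dataclass
class SimulationParams:
    """Physical constants and integration settings.

    Force constants are not physically parametrized; defaults are chosen for
    overdamped numerical stability and exposed for configuration.  The bead
    radius (default 25 nm for a 150 kb bin) sets the length scale.
    """

    m: float = 1.0
    gamma: float = 0.5
    k_rep: float = 1.0
    k_ten: float = 1.0
    k_hic: float = 0.3
    r_bead: float = 25.0
    c2: float = 50.0
    d_hic0: float = 50.0
    dt: float = 0.01
    n_steps: int = 10_000
    n_replicates: int = 3
    seeds: tuple[int, ...] = ()
    record_interval: int = 100
    sarw_step: float | None = None  # default 2*r_bead
    sarw_exclusion: float | None = None  # default 2*r_bead

    def __post_init__(self) -> None:
        for name in ("m", "gamma", "k_rep", "k_ten", "k_hic", "r_bead",
                     "c2", "d_hic0", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.seeds:
            self.seeds = tuple(range(1, self.n_replicates + 1))
        if len(self.seeds) != self.n_replicates:
            raise ValueError("need one seed per replicate")

    @property
    def d_rep0(self) -> float:
        """Repulsion rest length: two bead radii (beads touching)."""
        return 2.0 * self.r_bead

    @property
    def step_length(self) -> float:
        return self.sarw_step if self.sarw_step is not None else 2.0 * self.r_bead

    @property
    def exclusion(self) -> float:
        return (self.sarw_exclusion if self.sarw_exclusion is not None
                else 2.0 * self.r_bead)


@dataclass
class Conformation:
    """Ordered 3D bead coordinates (nm) of one chromosome model."""

    chrom: str
    coords: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("need at least one bead")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def distance_matrix(self) -> np.ndarray:
        return squareform(pdist(self.coords))


@dataclass
class SimState:
    positions: np.ndarray
    prev_positions: np.ndarray
    step: int = 0
    chrom: str = "chr"

    def velocities(self, dt: float) -> np.ndarray:
        """Finite-difference velocity estimate used by the drag term."""
        return (self.positions - self.prev_positions) / dt


@dataclass
class TrajectoryMetrics:
    steps: np.ndarray
    energy: np.ndarray
    rmsd_to_final: np.ndarray

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("step\tenergy\trmsd_to_final\n")
            for s, e, r in zip(self.steps, self.energy, self.rmsd_to_final):
                fh.write(f"{s}\t{e:.9g}\t{r:.9g}\n")


def init_sarw(
    n_beads: int,
    step_length: float,
    exclusion: float,
    seed: int,
    max_restarts: int = 50,
) -> Conformation:
    """Self-avoiding random walk initialization.

    Consecutive beads are exactly ``step_length`` apart; every non-consecutive
    pair is at least ``exclusion`` apart.  Deterministic given ``seed``.
    """
    if step_length <= 0:
        raise ValueError("step_length must be positive")
    if exclusion > step_length:
        raise ValueError("exclusion must not exceed step_length")
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        coords = np.zeros((n_beads, 3))
        ok = True
        for k in range(1, n_beads):
            placed = False
            for _ in range(200):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                cand = coords[k - 1] + step_length * u
                if k < 2:
                    placed = True
                else:
                    d = np.linalg.norm(coords[: k - 1] - cand, axis=1)
                    placed = bool(np.all(d >= exclusion))
                if placed:
                    coords[k] = cand
                    break
            if not placed:
                ok = False
                break
        if ok:
            return Conformation("chr", coords[:n_beads])
    raise RuntimeError(
        f"SARW placement failed after {max_restarts} restarts; "
        "try a smaller exclusion distance"
    )


def _pairwise_spring(coords: np.ndarray, i: np.ndarray, j: np.ndarray,
                     k: float, rest: float,
                     only_below_rest: bool = False,
                     rng: np.random.Generator | None = None,
                     jitter: float = 1e-6) -> np.ndarray:
    """Accumulate linear-spring forces K*(d - d0) along the i->j unit vector.

    A positive displacement (d > d0) pulls the pair together, a negative one
    pushes it apart; Newton's third law holds pairwise by construction.
    """
    n = coords.shape[0]
    forces = np.zeros((n, 3))
    if len(i) == 0:
        return forces
    delta = coords[j] - coords[i]  # i -> j
    d = np.linalg.norm(delta, axis=1)
    zero = d == 0.0
    if np.any(zero):
        # Coincident beads leave the unit vector undefined; split them with a
        # seeded infinitesimal offset.
        if rng is None:
            rng = np.random.default_rng(0)
        logger.warning("coincident beads encountered; applying jitter")
        eps = rng.normal(size=(int(zero.sum()), 3))
        eps *= jitter / np.linalg.norm(eps, axis=1, keepdims=True)
        delta[zero] = eps
        d[zero] = jitter
    if only_below_rest:
        active = d < rest
        if not np.any(active):
            return forces
        i, j, delta, d = i[active], j[active], delta[active], d[active]
    u = delta / d[:, None]
    f = k * (d - rest)  # per-pair scalar; >0 attracts, <0 repels
    fv = f[:, None] * u
    np.add.at(forces, i, fv)
    np.add.at(forces, j, -fv)
    return forces


def force_repulsion(conf: Conformation, p: SimulationParams,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Volume exclusion: springs active only for pairs closer than d_rep0."""
    coords = conf.coords
    n = conf.n_beads
    if n < 2:
        return np.zeros((n, 3))
    d = squareform(pdist(coords))
    iu, ju = np.triu_indices(n, k=1)
    close = d[iu, ju] < p.d_rep0
    return _pairwise_spring(coords, iu[close], ju[close], p.k_rep, p.d_rep0,
                            rng=rng)


def force_tension(conf: Conformation, p: SimulationParams,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Chain tension between genomic neighbours, rest length c2."""
    n = conf.n_beads
    if n < 2:
        raise ValueError("tension needs at least 2 beads")
    i = np.arange(n - 1)
    return _pairwise_spring(conf.coords, i, i + 1, p.k_ten, p.c2, rng=rng)


def force_hic(conf: Conformation, constraints: ConstraintSet,
              p: SimulationParams,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """Contact restraints: one spring per retained bin pair."""
    n = conf.n_beads
    if len(constraints) == 0:
        return np.zeros((n, 3))
    if constraints.j.max() >= n or constraints.i.min() < 0:
        raise ValueError("constraint index out of range for conformation")
    return _pairwise_spring(conf.coords, constraints.i, constraints.j,
                            p.k_hic, p.d_hic0, rng=rng)


def total_force(conf: Conformation, constraints: ConstraintSet | None,
                p: SimulationParams,
                rng: np.random.Generator | None = None) -> np.ndarray:
    f = force_repulsion(conf, p, rng=rng)
    if conf.n_beads >= 2:
        f += force_tension(conf, p, rng=rng)
    if constraints is not None and len(constraints):
        f += force_hic(conf, constraints, p, rng=rng)
    return f


def step_verlet(state: SimState, constraints: ConstraintSet | None,
                p: SimulationParams,
                extra_force: np.ndarray | None = None,
                rng: np.random.Generator | None = None) -> SimState:
    """One classic-Verlet step of m*a = -gamma*v + F_rep + F_ten + F_hic.

    The drag velocity is the finite difference (x_t - x_{t-dt}) / dt.
    """
    x = state.positions
    conf = Conformation(state.chrom, x)
    f = total_force(conf, constraints, p, rng=rng)
    if extra_force is not None:
        f = f + extra_force
    v = (x - state.prev_positions) / p.dt
    a = (f - p.gamma * v) / p.m
    new_x = 2.0 * x - state.prev_positions + a * p.dt**2
    if not np.all(np.isfinite(new_x)):
        raise FloatingPointError(
            f"non-finite coordinates at step {state.step + 1}; "
            "try a smaller dt or weaker spring constants"
        )
    return SimState(positions=new_x, prev_positions=x,
                    step=state.step + 1, chrom=state.chrom)


def pseudo_energy(state: SimState, constraints: ConstraintSet | None,
                  p: SimulationParams) -> float:
    """Kinetic plus spring potential energy; zero at rest."""
    x = state.positions
    v = (x - state.prev_positions) / p.dt
    e = 0.5 * p.m * float(np.sum(v * v))
    n = x.shape[0]
    if n >= 2:
        d = np.linalg.norm(np.diff(x, axis=0), axis=1)
        e += 0.5 * p.k_ten * float(np.sum((d - p.c2) ** 2))
        dm = pdist(x)
        iu, ju = np.triu_indices(n, k=1)
        overlap = dm < p.d_rep0
        # repulsion potential only on the active (overlapping) branch
        e += 0.5 * p.k_rep * float(np.sum((dm[overlap] - p.d_rep0) ** 2))
        if constraints is not None and len(constraints):
            dc = np.linalg.norm(x[constraints.j] - x[constraints.i], axis=1)
            e += 0.5 * p.k_hic * float(np.sum((dc - p.d_hic0) ** 2))
    return e


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Optimal-superposition RMSD after removing translation and rotation."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    r = vt.T @ d @ u.T
    diff = ac @ r.T - bc
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def rmsd(a: Conformation, b: Conformation) -> float:
    return kabsch_rmsd(a.coords, b.coords)


@dataclass
class ReplicateResult:
    conformation: Conformation
    metrics: TrajectoryMetrics
    seed: int
    error: str | None = None


def run_simulation(
    n_beads: int,
    constraints: ConstraintSet | None,
    p: SimulationParams,
    seed: int,
    chrom: str = "chr",
) -> ReplicateResult:
    """Run one replicate: SARW init then fixed-step Verlet integration."""
    conf0 = init_sarw(n_beads, p.step_length, p.exclusion, seed=seed)
    rng = np.random.default_rng(seed + 10_000_019)
    state = SimState(positions=conf0.coords.copy(),
                     prev_positions=conf0.coords.copy(), chrom=chrom)
    rec_steps, rec_energy, snapshots = [0], [pseudo_energy(state, constraints, p)], [
        state.positions.copy()
    ]
    for _ in range(p.n_steps):
        state = step_verlet(state, constraints, p, rng=rng)
        if state.step % p.record_interval == 0 or state.step == p.n_steps:
            rec_steps.append(state.step)
            rec_energy.append(pseudo_energy(state, constraints, p))
            snapshots.append(state.positions.copy())
    final = snapshots[-1]
    rmsds = np.array([kabsch_rmsd(s, final) for s in snapshots])
    metrics = TrajectoryMetrics(
        steps=np.array(rec_steps), energy=np.array(rec_energy),
        rmsd_to_final=rmsds,
    )
    return ReplicateResult(
        conformation=Conformation(chrom, final), metrics=metrics, seed=seed
    )


def reconstruct(
    source: CisMatrix | ConstraintSet,
    p: SimulationParams,
    cutoff_mode: str = "mean",
    n_beads: int | None = None,
) -> list[ReplicateResult]:
    """Reconstruct one chromosome with ``p.n_replicates`` independent runs.

    ``source`` is either a cis matrix (thresholded with ``cutoff_mode``) or an
    already-selected constraint set.  Failed replicates are reported with
    their error; successful ones are returned regardless.
    """
    if isinstance(source, CisMatrix):
        constraints = select_constraints(source, mode=cutoff_mode)
        n = source.n_bins
        chrom = source.chrom
    else:
        constraints = source
        n = n_beads if n_beads is not None else int(constraints.j.max()) + 1
        chrom = constraints.chrom
    if n < 2:
        raise ValueError("need at least 2 beads")
    results: list[ReplicateResult] = []
    for seed in p.seeds:
        try:
            results.append(run_simulation(n, constraints, p, seed, chrom=chrom))
        except FloatingPointError as exc:
            logger.error("replicate seed=%d failed: %s", seed, exc)
            results.append(ReplicateResult(
                conformation=Conformation(chrom, np.zeros((1, 3))),
                metrics=TrajectoryMetrics(np.array([]), np.array([]),
                                          np.array([])),
                seed=seed, error=str(exc),
            ))
    if all(r.error for r in results):
        raise RuntimeError("all replicates failed")
    return results


def validate_model(conf: Conformation,
                   constraints: ConstraintSet) -> tuple[float, float]:
    """(Spearman, cosine) agreement between IF and model distances.

    Spearman correlates IF with Euclidean distance over the constrained
    pairs (negative for good models).  Cosine compares the max-normalized IF
    vector with the max-normalized inverse-distance vector.
    """
    if len(constraints) < 3:
        raise ValueError("need at least 3 constraints to validate")
    d = np.linalg.norm(
        conf.coords[constraints.j] - conf.coords[constraints.i], axis=1
    )
    rho = float(spearmanr(constraints.values, d).statistic)
    v_if = constraints.values / constraints.values.max()
    inv = 1.0 / np.maximum(d, 1e-12)
    v_inv = inv / inv.max()
    cosine = float(
        np.dot(v_if, v_inv) / (np.linalg.norm(v_if) * np.linalg.norm(v_inv))
    )
    return rho, cosine
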