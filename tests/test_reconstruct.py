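import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

from spatiochrom.hic_io import ConstraintSet, select_constraints
from spatiochrom.reconstruct import (
    Conformation,
    SimState,
    SimulationParams,
    force_hic,
    force_repulsion,
    force_tension,
    init_sarw,
    kabsch_rmsd,
    pseudo_energy,
    reconstruct,
    rmsd,
    run_simulation,
    step_verlet,
    validate_model,
)


def constraints_of(pairs, chrom="chr"):
    pairs = np.asarray(pairs, dtype=float).reshape(-1, 3)
    return ConstraintSet(chrom=chrom, threshold=0.0,
                         i=pairs[:, 0].astype(np.int64),
                         j=pairs[:, 1].astype(np.int64),
                         values=pairs[:, 2], n_source=len(pairs))


class TestSarw:
    def test_single_bead_at_origin(self):
        conf = init_sarw(1, 50.0, 50.0, seed=0)
        assert conf.n_beads == 1
        assert np.allclose(conf.coords, 0.0)

    def test_invariants(self):
        conf = init_sarw(50, 55.0, 50.0, seed=7)
        steps = np.linalg.norm(np.diff(conf.coords, axis=0), axis=1)
        assert np.allclose(steps, 55.0, atol=1e-9)
        d = pdist(conf.coords)
        n = conf.n_beads
        mask = np.ones(len(d), dtype=bool)
        # drop consecutive pairs from the condensed distance vector
        idx = 0
        for a in range(n - 1):
            for b in range(a + 1, n):
                if b == a + 1:
                    mask[idx] = False
                idx += 1
        assert np.min(d[mask]) >= 50.0

    def test_determinism(self):
        a = init_sarw(30, 55.0, 50.0, seed=11)
        b = init_sarw(30, 55.0, 50.0, seed=11)
        assert np.array_equal(a.coords, b.coords)

    def test_exclusion_exceeds_step(self):
        with pytest.raises(ValueError):
            init_sarw(10, 50.0, 60.0, seed=0)


class TestForces:
    def params(self, **kw):
        return SimulationParams(**kw)

    def test_repulsion_boundary_zero(self):
        p = self.params(r_bead=1.0)  # d_rep0 = 2
        conf = Conformation("c", [[0, 0, 0], [2.0, 0, 0]])
        f = force_repulsion(conf, p)
        assert np.allclose(f, 0.0)

    def test_repulsion_magnitude(self):
        p = self.params(k_rep=10.0, r_bead=1.0)  # d_rep0 = 2, d = 1
        conf = Conformation("c", [[0, 0, 0], [1.0, 0, 0]])
        f = force_repulsion(conf, p)
        # K*(d - d0) = 10*(1-2) = -10 along +x for bead 0 => pushed to -x
        assert f[0, 0] == pytest.approx(-10.0)
        assert f[1, 0] == pytest.approx(10.0)

    def test_repulsion_sums_to_zero(self, rng):
        p = self.params(r_bead=30.0)
        conf = Conformation("c", rng.uniform(-50, 50, size=(40, 3)))
        f = force_repulsion(conf, p)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-9)

    def test_tension_rest_zero(self):
        p = self.params(c2=50.0)
        coords = np.column_stack([np.arange(5) * 50.0,
                                  np.zeros(5), np.zeros(5)])
        f = force_tension(Conformation("c", coords), p)
        assert np.allclose(f, 0.0)

    def test_tension_two_beads(self):
        p = self.params(k_ten=5.0, c2=2.0)
        conf = Conformation("c", [[0, 0, 0], [3.0, 0, 0]])
        f = force_tension(conf, p)
        # stretched by 1 -> magnitude 5 pulling together
        assert f[0, 0] == pytest.approx(5.0)
        assert f[1, 0] == pytest.approx(-5.0)

    def test_tension_symmetric_middle(self):
        p = self.params(c2=2.0)
        conf = Conformation("c", [[0, 0, 0], [3.0, 0, 0], [6.0, 0, 0]])
        f = force_tension(conf, p)
        assert np.allclose(f[1], 0.0, atol=1e-12)

    def test_hic_empty(self):
        p = self.params()
        conf = Conformation("c", np.zeros((4, 3)) + np.arange(4)[:, None])
        f = force_hic(conf, constraints_of(np.empty((0, 3))), p)
        assert np.allclose(f, 0.0)

    def test_hic_magnitude(self):
        p = self.params(k_hic=2.0, d_hic0=100.0)
        conf = Conformation("c", [[0, 0, 0], [500.0, 0, 0]])
        f = force_hic(conf, constraints_of([[0, 1, 1.0]]), p)
        # K*(500-100) = 800 pulling together
        assert f[0, 0] == pytest.approx(800.0)
        assert f[1, 0] == pytest.approx(-800.0)

    def test_hic_rest_length_zero(self):
        p = self.params(k_hic=2.0, d_hic0=100.0)
        conf = Conformation("c", [[0, 0, 0], [100.0, 0, 0]])
        f = force_hic(conf, constraints_of([[0, 1, 1.0]]), p)
        assert np.allclose(f, 0.0)

    def test_hic_out_of_range(self):
        p = self.params()
        conf = Conformation("c", [[0, 0, 0], [100.0, 0, 0]])
        with pytest.raises(ValueError, match="out of range"):
            force_hic(conf, constraints_of([[0, 5, 1.0]]), p)

    def test_total_force_zero_random(self, rng):
        p = self.params()
        coords = rng.uniform(-100, 100, size=(30, 3))
        conf = Conformation("c", coords)
        cons = constraints_of([[0, 10, 1.0], [5, 25, 2.0]])
        from spatiochrom.reconstruct import total_force
        f = total_force(conf, cons, p)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-9)


class TestVerlet:
    def test_no_force_no_motion(self):
        p = SimulationParams()
        x = np.array([[1.0, 2.0, 3.0]])
        st = SimState(positions=x.copy(), prev_positions=x.copy())
        st2 = step_verlet(st, None, p)
        assert np.allclose(st2.positions, x)

    def test_terminal_velocity(self):
        p = SimulationParams(gamma=0.5, dt=0.01)
        st = SimState(positions=np.zeros((1, 3)),
                      prev_positions=np.zeros((1, 3)))
        force = np.array([[3.0, 0.0, 0.0]])
        for _ in range(3000):
            st = step_verlet(st, None, p, extra_force=force)
        v = st.velocities(p.dt)
        assert v[0, 0] == pytest.approx(3.0 / 0.5, rel=1e-2)

    def test_two_bead_spring_equilibrates(self):
        p = SimulationParams()
        x = np.array([[0.0, 0, 0], [80.0, 0, 0]])
        st = SimState(positions=x.copy(), prev_positions=x.copy())
        for _ in range(5000):
            st = step_verlet(st, None, p)
        d = np.linalg.norm(st.positions[1] - st.positions[0])
        assert d == pytest.approx(p.c2, abs=1e-3)

    def test_nonfinite_abort(self):
        p = SimulationParams(dt=0.01)
        x = np.array([[0.0, 0, 0], [80.0, 0, 0]])
        st = SimState(positions=x.copy(), prev_positions=x.copy())
        with pytest.raises(FloatingPointError, match="dt"):
            step_verlet(st, None, p, extra_force=np.full((2, 3), np.inf))


class TestPseudoEnergy:
    def test_rest_configuration_zero(self):
        p = SimulationParams()
        coords = np.column_stack([np.arange(4) * p.c2, np.zeros(4),
                                  np.zeros(4)])
        st = SimState(positions=coords, prev_positions=coords.copy())
        assert pseudo_energy(st, None, p) == pytest.approx(0.0)

    def test_single_stretched_spring(self):
        p = SimulationParams(k_ten=5.0, c2=2.0, r_bead=0.5)  # d_rep0=1 < d
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        st = SimState(positions=coords, prev_positions=coords.copy())
        assert pseudo_energy(st, None, p) == pytest.approx(2.5)

    def test_non_increasing_late(self, cis50):
        p = SimulationParams(n_steps=4000, n_replicates=1)
        cons = select_constraints(cis50, mode="mean")
        res = run_simulation(50, cons, p, seed=5)
        e = res.metrics.energy
        late = e[len(e) // 2:]
        assert np.all(np.diff(late) <= 1e-6 * e[0])


class TestRmsd:
    def test_identical_zero(self, truth50):
        assert rmsd(truth50, truth50) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_zero(self, truth50, rng):
        from scipy.spatial.transform import Rotation
        r = Rotation.random(rng=42).as_matrix()
        moved = truth50.coords @ r.T + np.array([10.0, -5.0, 3.0])
        assert kabsch_rmsd(truth50.coords, moved) == pytest.approx(
            0.0, abs=1e-9)

    def test_symmetry(self, truth50, rng):
        other = Conformation("c", truth50.coords
                             + rng.normal(0, 5, truth50.coords.shape))
        assert rmsd(truth50, other) == pytest.approx(rmsd(other, truth50))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_grid_search_oracle(self):
        # brute-force rotation search must not beat Kabsch, and must come
        # close to it on a small toy problem
        a = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 1]])
        b = np.array([[0.1, 0, 0], [1, 0.2, 0], [0.9, 1, 0.1], [0, 1.1, 0.8]])
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        from scipy.spatial.transform import Rotation

        def grid_best(center, width, steps):
            axes = [np.linspace(c - width, c + width, steps)
                    for c in center]
            euler = np.array(np.meshgrid(*axes)).reshape(3, -1).T
            mats = Rotation.from_euler("zyz", euler).as_matrix()
            rotated = np.einsum("rij,nj->rni", mats, ac)
            v = np.sqrt(np.mean(np.sum((rotated - bc) ** 2, axis=2), axis=1))
            k = int(np.argmin(v))
            return euler[k], float(v[k])

        center, best = grid_best([np.pi, np.pi / 2, np.pi], np.pi, 25)
        width = 0.45
        for _ in range(8):  # geometric local refinement
            center, best = grid_best(center, width, 13)
            width *= 0.45
        k = kabsch_rmsd(a, b)
        assert k <= best + 1e-12
        assert k == pytest.approx(best, rel=1e-6)


class TestReconstruct:
    def test_relaxed_chain(self):
        p = SimulationParams(n_steps=4000, n_replicates=1, sarw_step=70.0)
        res = reconstruct(constraints_of(np.empty((0, 3))), p, n_beads=20)
        conf = res[0].conformation
        d = np.linalg.norm(np.diff(conf.coords, axis=0), axis=1)
        assert np.allclose(d, p.c2, atol=0.5)

    def test_determinism(self, cis50):
        p = SimulationParams(n_steps=300, n_replicates=2)
        r1 = reconstruct(cis50, p)
        r2 = reconstruct(cis50, p)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.conformation.coords,
                                  b.conformation.coords)

    def test_replicates_differ(self, cis50):
        p = SimulationParams(n_steps=300, n_replicates=2)
        res = reconstruct(cis50, p)
        assert not np.allclose(res[0].conformation.coords,
                               res[1].conformation.coords)

    def test_rmsd_to_final_is_zero_at_end(self, cis50):
        p = SimulationParams(n_steps=500, n_replicates=1)
        res = reconstruct(cis50, p)
        assert res[0].metrics.rmsd_to_final[-1] == pytest.approx(0.0,
                                                                 abs=1e-9)

    @pytest.mark.slow
    def test_parameter_recovery(self, truth50, cis50):
        p = SimulationParams(n_steps=10_000, n_replicates=3)
        res = reconstruct(cis50, p)
        true_d = pdist(truth50.coords)
        best = max(
            spearmanr(pdist(r.conformation.coords), true_d).statistic
            for r in res if r.error is None
        )
        assert best >= 0.8


class TestValidateModel:
    def test_perfect_monotone(self):
        coords = np.column_stack([np.arange(6) * 10.0, np.zeros(6),
                                  np.zeros(6)])
        conf = Conformation("c", coords)
        # larger IF exactly where distance is smaller
        cons = constraints_of([[0, 1, 9.0], [0, 2, 5.0], [0, 3, 2.0]])
        rho, _ = validate_model(conf, cons)
        assert rho == pytest.approx(-1.0)

    def test_cosine_proportional(self):
        coords = np.column_stack([np.arange(4) * 10.0, np.zeros(4),
                                  np.zeros(4)])
        conf = Conformation("c", coords)
        d = [10.0, 20.0, 30.0]
        cons = constraints_of([[0, 1, 100.0 / d[0]], [0, 2, 100.0 / d[1]],
                               [0, 3, 100.0 / d[2]]])
        _, cos = validate_model(conf, cons)
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_null_uncorrelated(self, rng):
        coords = rng.uniform(0, 1000, size=(100, 3))
        conf = Conformation("c", coords)
        pairs = []
        seen = set()
        while len(pairs) < 1000:
            i, j = rng.integers(0, 100, size=2)
            if i < j and (i, j) not in seen:
                seen.add((i, j))
                pairs.append([i, j, rng.exponential(2.0)])
        rho, _ = validate_model(conf, constraints_of(pairs))
        assert abs(rho) < 0.1

    def test_too_few_constraints(self):
        conf = Conformation("c", np.zeros((3, 3)) + np.arange(3)[:, None])
        with pytest.raises(ValueError, match="3 constraints"):
            validate_model(conf, constraints_of([[0, 1, 1.0]]))
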