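"""DPD forces, cell list, thermostat and integrator."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import solve_ivp

import dpdmc
from dpdmc import _kernels
from dpdmc.builder import Configuration, Topology
from dpdmc.engine import (
    IntegrationError,
    IntegratorSettings,
    build_cell_list,
    kinetic_temperature,
    pair_forces,
    run,
    spring_forces,
)
from dpdmc.interactions import InteractionTable

from conftest import brute_force_pairs


def two_beads(r, box=10.0, v1=(0, 0, 0), v2=(0, 0, 0)):
    """Two beads separated by r along x, centered in the box."""
    pos = np.array([[box / 2 - r / 2, box / 2, box / 2],
                    [box / 2 + r / 2, box / 2, box / 2]])
    vel = np.array([v1, v2], dtype=float)
    return Configuration(positions=pos, velocities=vel,
                         types=np.zeros(2, np.int8), box_edge=box)


def free_topology(n):
    return Topology(n_beads=n, mol_species=np.zeros(n, np.int8),
                    mol_id=np.arange(n, dtype=np.int32),
                    bonds=np.empty((0, 2), np.int64),
                    bead_types=np.zeros(n, np.int8), chain_counts={})


def uniform_table(a=25.0, gamma=4.5):
    sigma = np.sqrt(2.0 * gamma)
    return InteractionTable(a=np.full((3, 3), a), gamma=gamma, sigma=sigma)


class TestPairForces:
    def test_conservative_magnitude_at_half_cutoff(self):
        cfg = two_beads(0.5)
        f = pair_forces(cfg, uniform_table(gamma=0.0), with_noise=False)
        # a (1 - r/Rc) = 25 * 0.5 = 12.5, repulsive along x
        np.testing.assert_allclose(f[0], [-12.5, 0, 0], atol=1e-4)
        np.testing.assert_allclose(f[1], [12.5, 0, 0], atol=1e-4)

    @pytest.mark.parametrize("r", [1.0, 1.3, 4.0])
    def test_zero_beyond_cutoff(self, r):
        cfg = two_beads(r)
        f = pair_forces(cfg, uniform_table(), with_noise=False)
        np.testing.assert_array_equal(f, np.zeros((2, 3)))

    def test_perpendicular_velocity_gives_no_drag(self):
        cfg_perp = two_beads(0.5, v1=(0, 1, 0), v2=(0, -1, 0))
        cfg_rest = two_beads(0.5)
        f_perp = pair_forces(cfg_perp, uniform_table(), with_noise=False)
        f_rest = pair_forces(cfg_rest, uniform_table(), with_noise=False)
        np.testing.assert_allclose(f_perp, f_rest, atol=1e-5)

    def test_head_on_velocity_is_damped(self):
        cfg = two_beads(0.5, v1=(1, 0, 0), v2=(-1, 0, 0))
        f = pair_forces(cfg, uniform_table(gamma=4.5), with_noise=False)
        # drag opposes the approach: -gamma w^2 |v12| on top of repulsion
        np.testing.assert_allclose(f[0, 0], -12.5 - 4.5 * 0.25 * 2.0,
                                   atol=1e-4)

    def test_coincident_beads_give_zero_force(self):
        cfg = two_beads(0.0)
        f = pair_forces(cfg, uniform_table(), with_noise=False)
        assert np.isfinite(f).all()
        np.testing.assert_array_equal(f, np.zeros((2, 3)))

    def test_forces_sum_to_zero(self):
        rng = np.random.default_rng(0)
        n = 120
        cfg = Configuration(positions=rng.uniform(0, 6, (n, 3)),
                            velocities=rng.normal(size=(n, 3)),
                            types=rng.integers(0, 3, n).astype(np.int8),
                            box_edge=6.0)
        f = pair_forces(cfg, dpdmc.InteractionTable.reference(), seed=4)
        np.testing.assert_allclose(f.sum(axis=0), np.zeros(3), atol=1e-9)

    def test_noise_amplitude_from_fluctuation_dissipation(self):
        assert uniform_table(gamma=4.5).sigma == pytest.approx(3.0)


class TestGaussianNoise:
    def test_ziggurat_samples_standard_normal(self):
        out = np.empty(200_000)
        _kernels.gauss_fill(out, _kernels.rng_state(123))
        assert out.mean() == pytest.approx(0.0, abs=0.01)
        assert out.std() == pytest.approx(1.0, abs=0.01)
        assert stats.skew(out) == pytest.approx(0.0, abs=0.03)
        assert stats.kurtosis(out) == pytest.approx(0.0, abs=0.06)
        # distributional agreement, not just moments
        ks = stats.kstest(out[:20000], "norm")
        assert ks.pvalue > 0.01


class TestSpringForces:
    def test_magnitude_proportional_to_length(self):
        cfg = two_beads(0.3)
        topo = free_topology(2)
        topo.bonds = np.array([[0, 1]], dtype=np.int64)
        f = spring_forces(cfg, topo, spring_c=4.0)
        np.testing.assert_allclose(f[0], [1.2, 0, 0], atol=1e-12)
        np.testing.assert_allclose(f[1], [-1.2, 0, 0], atol=1e-12)

    def test_zero_length_bond_gives_zero_force(self):
        cfg = two_beads(0.0)
        topo = free_topology(2)
        topo.bonds = np.array([[0, 1]], dtype=np.int64)
        np.testing.assert_array_equal(spring_forces(cfg, topo),
                                      np.zeros((2, 3)))

    def test_interior_bead_feels_both_bonds(self):
        # 3-bead chain oracle: direct summation of the two bond forces
        pos = np.array([[5.0, 5.0, 5.0], [5.6, 5.0, 5.0], [5.6, 5.8, 5.0]])
        cfg = Configuration(positions=pos, velocities=np.zeros((3, 3)),
                            types=np.zeros(3, np.int8), box_edge=10.0)
        topo = free_topology(3)
        topo.bonds = np.array([[0, 1], [1, 2]], dtype=np.int64)
        f = spring_forces(cfg, topo, spring_c=4.0)
        expected_mid = -4.0 * (pos[1] - pos[0]) - 4.0 * (pos[1] - pos[2])
        np.testing.assert_allclose(f[1], expected_mid, atol=1e-12)
        np.testing.assert_allclose(f.sum(axis=0), np.zeros(3), atol=1e-12)

    def test_bond_across_minimum_image_uses_nearest_copy(self):
        pos = np.array([[0.2, 3.0, 3.0], [5.8, 3.0, 3.0]])  # 0.4 via wrap
        cfg = Configuration(positions=pos, velocities=np.zeros((2, 3)),
                            types=np.zeros(2, np.int8), box_edge=6.0)
        topo = free_topology(2)
        topo.bonds = np.array([[0, 1]], dtype=np.int64)
        f = spring_forces(cfg, topo, spring_c=4.0)
        np.testing.assert_allclose(f[0], [-1.6, 0, 0], atol=1e-12)

    def test_overlong_bond_raises_ambiguity_error(self):
        pos = np.array([[0.2, 0.2, 0.2], [2.8, 2.8, 2.8]])
        cfg = Configuration(positions=pos, velocities=np.zeros((2, 3)),
                            types=np.zeros(2, np.int8), box_edge=6.0)
        topo = free_topology(2)
        topo.bonds = np.array([[0, 1]], dtype=np.int64)
        with pytest.raises(IntegrationError, match="half the box"):
            spring_forces(cfg, topo)


class TestCellList:
    @pytest.mark.parametrize("n, box", [(50, 6.0), (200, 6.0), (200, 4.5)])
    def test_matches_brute_force(self, n, box):
        rng = np.random.default_rng(n)
        cfg = Configuration(positions=rng.uniform(0, box, (n, 3)),
                            velocities=np.zeros((n, 3)),
                            types=np.zeros(n, np.int8), box_edge=box)
        pairs = {tuple(p) for p in build_cell_list(cfg, 1.5)}
        assert pairs == brute_force_pairs(cfg.positions, box, 1.5)

    def test_pair_across_periodic_face(self):
        pos = np.array([[0.1, 2.0, 2.0], [5.6, 2.0, 2.0]])
        cfg = Configuration(positions=pos, velocities=np.zeros((2, 3)),
                            types=np.zeros(2, np.int8), box_edge=6.0)
        assert build_cell_list(cfg, 1.0).tolist() == [[0, 1]]

    def test_small_box_falls_back_to_all_pairs(self):
        rng = np.random.default_rng(1)
        cfg = Configuration(positions=rng.uniform(0, 2.5, (30, 3)),
                            velocities=np.zeros((30, 3)),
                            types=np.zeros(30, np.int8), box_edge=2.5)
        pairs = {tuple(p) for p in build_cell_list(cfg, 1.0)}
        assert pairs == brute_force_pairs(cfg.positions, 2.5, 1.0)

    def test_empty_configuration(self):
        cfg = Configuration(positions=np.empty((0, 3)),
                            velocities=np.empty((0, 3)),
                            types=np.empty(0, np.int8), box_edge=6.0)
        assert len(build_cell_list(cfg, 1.5)) == 0

    def test_isolated_bead_feels_no_force(self):
        # cutoff locality: a bead farther than Rc from all others
        pos = np.array([[1.0, 1.0, 1.0], [1.5, 1.0, 1.0], [4.0, 4.0, 4.0]])
        cfg = Configuration(positions=pos, velocities=np.zeros((3, 3)),
                            types=np.zeros(3, np.int8), box_edge=8.0)
        f = pair_forces(cfg, uniform_table(), with_noise=False)
        np.testing.assert_array_equal(f[2], np.zeros(3))


class TestIntegrator:
    def test_single_bead_moves_ballistically(self):
        cfg = Configuration(positions=np.array([[2.0, 2.0, 2.0]]),
                            velocities=np.array([[0.5, -0.25, 0.1]]),
                            types=np.zeros(1, np.int8), box_edge=8.0)
        traj = run(cfg, free_topology(1), uniform_table(),
                   IntegratorSettings(n_steps=10, snapshot_interval=10))
        np.testing.assert_allclose(
            traj.final.positions[0],
            [2.0 + 0.5 * 0.5, 2.0 - 0.25 * 0.5, 2.0 + 0.1 * 0.5],
            atol=1e-12)
        np.testing.assert_allclose(traj.final.velocities[0],
                                   [0.5, -0.25, 0.1], atol=1e-12)

    def test_zero_steps_returns_initial_frame_only(self, small_system):
        _, topo, cfg = small_system
        traj = run(cfg, topo, dpdmc.InteractionTable.reference(),
                   IntegratorSettings(n_steps=0))
        assert traj.n_frames == 1
        np.testing.assert_array_equal(traj.frames[0], cfg.positions)

    def test_same_seed_bitwise_identical(self, small_system):
        _, topo, cfg = small_system
        table = dpdmc.InteractionTable.reference()
        s = IntegratorSettings(n_steps=200, seed=42, snapshot_interval=50)
        t1 = run(cfg, topo, table, s)
        t2 = run(cfg, topo, table, s)
        for f1, f2 in zip(t1.frames, t2.frames):
            np.testing.assert_array_equal(f1, f2)
        np.testing.assert_array_equal(t1.final.velocities,
                                      t2.final.velocities)

    def test_different_seed_diverges(self, small_system):
        _, topo, cfg = small_system
        table = dpdmc.InteractionTable.reference()
        t1 = run(cfg, topo, table, IntegratorSettings(n_steps=50, seed=1))
        t2 = run(cfg, topo, table, IntegratorSettings(n_steps=50, seed=2))
        assert not np.array_equal(t1.final.positions, t2.final.positions)

    def test_momentum_conserved_during_dynamics(self, small_system):
        _, topo, cfg = small_system
        traj = run(cfg, topo, dpdmc.InteractionTable.reference(),
                   IntegratorSettings(n_steps=2000, seed=9))
        p = traj.log[["px", "py", "pz"]].to_numpy()
        assert np.abs(p).max() < 1e-9

    def test_thermostat_holds_unit_temperature(self, small_system):
        _, topo, cfg = small_system
        traj = run(cfg, topo, dpdmc.InteractionTable.reference(),
                   IntegratorSettings(n_steps=3000, seed=3))
        late = traj.log.temperature.iloc[2:]
        assert late.mean() == pytest.approx(1.0, abs=0.05)

    def test_initial_overlong_bond_raises(self):
        pos = np.array([[0.2, 0.2, 0.2], [2.9, 2.9, 2.9]])
        cfg = Configuration(positions=pos, velocities=np.zeros((2, 3)),
                            types=np.zeros(2, np.int8), box_edge=6.0)
        topo = free_topology(2)
        topo.bonds = np.array([[0, 1]], dtype=np.int64)
        with pytest.raises(IntegrationError):
            run(cfg, topo, uniform_table(),
                IntegratorSettings(n_steps=10))

    def test_kinetic_temperature_definition(self):
        v = np.array([[1.0, 0, 0], [0, -1.0, 0]])
        assert kinetic_temperature(v) == pytest.approx(1.0 / 3.0)


class TestFineStepOracle:
    """Bonded pair, conservative + spring only, against a high-accuracy
    integration of the same equations of motion."""

    @staticmethod
    def _rhs(t, y, a, c):
        r1, r2, v1, v2 = y[:3], y[3:6], y[6:9], y[9:12]
        d = r1 - r2
        r = np.linalg.norm(d)
        e = d / r
        f_cons = a * (1 - r) * e if r < 1.0 else np.zeros(3)
        f_spring = -c * d
        f1 = f_cons + f_spring
        return np.concatenate([v1, v2, f1, -f1])

    def test_trajectory_matches_reference_integration(self):
        box = 12.0
        pos = np.array([[5.7, 6.0, 6.0], [6.3, 6.0, 6.0]])
        vel = np.array([[0.3, 0.1, 0.0], [-0.3, -0.1, 0.0]])
        cfg = Configuration(positions=pos.copy(), velocities=vel.copy(),
                            types=np.zeros(2, np.int8), box_edge=box)
        topo = free_topology(2)
        topo.bonds = np.array([[0, 1]], dtype=np.int64)
        table = InteractionTable(a=np.full((3, 3), 25.0), gamma=0.0,
                                 sigma=0.0)
        t_end = 1.0
        dt = 0.001
        traj = run(cfg, topo, table,
                   IntegratorSettings(dt=dt, n_steps=int(t_end / dt),
                                      snapshot_interval=int(t_end / dt)))
        sol = solve_ivp(self._rhs, (0, t_end),
                        np.concatenate([pos[0], pos[1], vel[0], vel[1]]),
                        args=(25.0, 4.0), rtol=1e-10, atol=1e-12,
                        dense_output=True)
        ref = sol.y[:, -1]
        np.testing.assert_allclose(traj.final.positions[0], ref[:3],
                                   atol=1e-5)
        np.testing.assert_allclose(traj.final.positions[1], ref[3:6],
                                   atol=1e-5)
        np.testing.assert_allclose(traj.final.velocities.ravel(), ref[6:],
                                   atol=1e-4)


class TestIntegrateStep:
    def test_single_step_ballistic(self):
        cfg = Configuration(positions=np.array([[2.0, 2.0, 2.0]]),
                            velocities=np.array([[0.4, 0.0, -0.2]]),
                            types=np.zeros(1, np.int8), box_edge=8.0)
        from dpdmc.engine import integrate_step
        new, frc = integrate_step(cfg, free_topology(1), uniform_table(),
                                  IntegratorSettings(n_steps=1))
        np.testing.assert_allclose(new.positions[0],
                                   [2.02, 2.0, 2.0 - 0.01], atol=1e-12)
        np.testing.assert_array_equal(frc, np.zeros((1, 3)))

    def test_momentum_conserved_each_step(self, small_system):
        _, topo, cfg = small_system
        from dpdmc.engine import integrate_step
        table = dpdmc.InteractionTable.reference()
        state, frc = cfg, None
        for _ in range(3):
            state, frc = integrate_step(state, topo, table,
                                        IntegratorSettings(seed=5), frc)
            np.testing.assert_allclose(state.velocities.sum(axis=0),
                                       np.zeros(3), atol=1e-10)
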