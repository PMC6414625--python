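"""DPD simulator: setup arithmetic, forces, bonds, shape analysis."""

import math

import numpy as np
import pytest

from laminachrom import polymer as pm
from laminachrom.polymer import (
    INACTIVE,
    SURFACE,
    PolymerSystem,
    SimParams,
    block_summary,
    bond_update,
    dpd_step,
    ensemble_distance_map,
    gyration_eigenvalues,
    init_system,
    kinetic_temperature,
)


class TestSetup:
    def test_production_particle_count(self):
        # density 3 in a 50^3 box: 375,000 particles, 64 blocks of 500+50
        p = SimParams()
        assert p.n_total == 375_000
        assert p.chain_length == 64 * 550
        assert p.noise_sigma**2 == pytest.approx(2 * p.friction_gamma * p.kT)

    def test_desk_scale_counts(self):
        p = SimParams(
            box=(16.0, 16.0, 16.0), n_blocks=8,
            inactive_per_block=55, active_per_block=5, seed=1,
        )
        system = init_system(p, np.random.default_rng(1))
        assert p.chain_length == 480
        assert len(system.positions) == p.n_total == 3 * 16**3
        assert (system.types == INACTIVE).sum() == 8 * 55
        assert system.backbone.shape == (479, 2)

    def test_zero_solvent_config(self):
        p = SimParams(
            box=(12.0, 12.0, 12.0), n_blocks=2, inactive_per_block=10,
            active_per_block=2, with_solvent=False, seed=1,
        )
        system = init_system(p, np.random.default_rng(1))
        n_wall = (system.types == SURFACE).sum()
        assert len(system.positions) == p.chain_length + n_wall

    def test_box_too_small_raises(self):
        p = SimParams(box=(4.0, 4.0, 4.0), seed=1)  # 192 particles < chain
        with pytest.raises(ValueError, match="too small"):
            init_system(p, np.random.default_rng(0))

    def test_wall_immobile_and_on_face(self):
        p = SimParams(
            box=(10.0, 10.0, 10.0), n_blocks=1, inactive_per_block=10,
            active_per_block=2, n_steps=0, seed=3,
        )
        system = init_system(p, np.random.default_rng(3))
        wall = system.types == SURFACE
        assert (system.positions[wall, 2] == 0).all()
        before = system.positions[wall].copy()
        dpd_step(system, 5)
        np.testing.assert_array_equal(system.positions[wall], before)


class TestForces:
    def _two_particle_system(self, r, a=25.0):
        p = SimParams(
            box=(10.0, 10.0, 10.0), n_blocks=0, with_wall=False,
            with_solvent=False, a_ij=a, friction_gamma=0.0, kT=0.0, seed=1,
        )
        pos = np.array([[5.0, 5.0, 5.0], [5.0 + r, 5.0, 5.0]])
        system = PolymerSystem(
            positions=pos,
            velocities=np.zeros((2, 3)),
            types=np.zeros(2, dtype=np.int8),
            block_id=np.full(2, -1, dtype=np.int32),
            backbone=np.empty((0, 2), dtype=np.int64),
            rev_partner=np.full(2, -1, dtype=np.int64),
            params=p,
        )
        return system

    def test_no_force_beyond_cutoff(self):
        system = self._two_particle_system(1.5)
        dpd_step(system, 1)
        assert np.allclose(system.forces, 0.0)

    def test_conservative_force_magnitude_at_half_cutoff(self):
        # soft repulsion a*(1 - r/rc): a=25 at r=0.5 gives |F| = 12.5
        system = self._two_particle_system(0.5)
        dpd_step(system, 1)
        f = system.forces
        assert f[0, 0] == pytest.approx(-12.5, rel=1e-6)
        assert f[1, 0] == pytest.approx(12.5, rel=1e-6)
        assert np.allclose(f[:, 1:], 0.0, atol=1e-9)

    def test_momentum_conserved_in_periodic_solvent(self):
        p = SimParams(
            box=(6.0, 6.0, 6.0), n_blocks=0, with_wall=False, seed=4, n_steps=0
        )
        system = init_system(p, np.random.default_rng(4))
        before = system.velocities.sum(axis=0)
        dpd_step(system, 50)
        after = system.velocities.sum(axis=0)
        assert np.abs(after - before).max() < 1e-10

    def test_instability_detected(self):
        system = self._two_particle_system(0.5)
        system.velocities[0] = [100.0, 0.0, 0.0]
        with pytest.raises(RuntimeError, match="reduce dt"):
            dpd_step(system, 1)

    def test_particles_stay_inside_slab(self):
        p = SimParams(
            box=(8.0, 8.0, 8.0), n_blocks=1, inactive_per_block=20,
            active_per_block=2, seed=5, n_steps=0,
        )
        system = init_system(p, np.random.default_rng(5))
        dpd_step(system, 200)
        z = system.positions[system.mobile, 2]
        assert (z >= 0).all() and (z <= 8).all()


class TestBonds:
    def _pair_system(self, p_pp=0.001, p_break=0.01):
        p = SimParams(
            box=(10.0, 10.0, 10.0), n_blocks=0, with_wall=False,
            with_solvent=False, p_bond_pp=p_pp, p_break=p_break, seed=1,
        )
        system = PolymerSystem(
            positions=np.array([[5.0, 5.0, 5.0], [5.5, 5.0, 5.0]]),
            velocities=np.zeros((2, 3)),
            types=np.full(2, INACTIVE, dtype=np.int8),
            block_id=np.zeros(2, dtype=np.int32),
            backbone=np.empty((0, 2), dtype=np.int64),
            rev_partner=np.full(2, -1, dtype=np.int64),
            params=p,
        )
        return system

    def test_two_particle_stationary_bonded_fraction(self):
        # two-state chain: bonded fraction -> p_on / (p_on + p_off) = 1/11
        system = self._pair_system()
        rng = np.random.default_rng(123)
        bonded = 0
        checks = 30_000
        for _ in range(checks):
            bond_update(system, rng)
            bonded += system.rev_partner[0] >= 0
        frac = bonded / checks
        expected = 0.001 / 0.011
        # ~3 sigma Monte-Carlo band for an AR(1) occupancy chain
        assert frac == pytest.approx(expected, abs=0.025)

    def test_saturation_never_violated(self):
        p = SimParams(
            box=(6.0, 6.0, 6.0), n_blocks=1, inactive_per_block=30,
            active_per_block=2, p_bond_pp=0.5, p_break=0.1, seed=6, n_steps=0,
        )
        system = init_system(p, np.random.default_rng(6))
        rng = np.random.default_rng(7)
        for _ in range(20):
            dpd_step(system, 20)
            bond_update(system, rng)
            system.assert_saturation()
        assert (system.rev_partner >= 0).sum() > 0  # bonds actually formed

    def test_bonded_particle_skips_creation(self):
        system = self._pair_system(p_pp=1.0, p_break=0.0)
        rng = np.random.default_rng(1)
        bond_update(system, rng)
        assert system.rev_partner[0] == 1 and system.rev_partner[1] == 0
        bond_update(system, rng)  # no change, already saturated
        system.assert_saturation()

    def test_surface_bond_probability(self):
        # inactive bead with only the wall in reach bonds at p_bond_ps per check
        p = SimParams(
            box=(6.0, 6.0, 6.0), n_blocks=0, with_solvent=False,
            p_bond_ps=0.007, p_break=0.0, seed=8,
        )
        system = init_system(p, np.random.default_rng(8))
        n_wall = len(system.positions)
        pos = np.vstack([system.positions, [[3.0, 3.0, 0.5]]])
        types = np.concatenate([system.types, [INACTIVE]]).astype(np.int8)
        system = PolymerSystem(
            positions=pos,
            velocities=np.zeros_like(pos),
            types=types,
            block_id=np.full(len(pos), -1, dtype=np.int32),
            backbone=np.empty((0, 2), dtype=np.int64),
            rev_partner=np.full(len(pos), -1, dtype=np.int64),
            params=p,
        )
        rng = np.random.default_rng(9)
        formed = 0
        trials = 20_000
        for _ in range(trials):
            bond_update(system, rng)
            if system.rev_partner[n_wall] >= 0:
                formed += 1
                system.rev_partner[n_wall] = -1
        assert formed / trials == pytest.approx(0.007, abs=0.002)


class TestDeterminism:
    def test_identical_seed_identical_trajectory(self):
        p = SimParams(
            box=(6.0, 6.0, 6.0), n_blocks=1, inactive_per_block=10,
            active_per_block=2, n_steps=400, snapshot_interval=200,
            check_interval=100, n_runs=1, seed=77,
        )
        a = pm.run_simulation(p)
        b = pm.run_simulation(p)
        np.testing.assert_array_equal(a[0]["snapshots"][-1], b[0]["snapshots"][-1])

    def test_zero_steps_initial_snapshot_only(self):
        p = SimParams(
            box=(6.0, 6.0, 6.0), n_blocks=1, inactive_per_block=10,
            active_per_block=2, n_steps=0, n_runs=1, seed=1,
        )
        runs = pm.run_simulation(p)
        assert len(runs[0]["snapshots"]) == 1

    def test_runs_have_distinct_seeds(self):
        p = SimParams(
            box=(6.0, 6.0, 6.0), n_blocks=1, inactive_per_block=10,
            active_per_block=2, n_steps=0, n_runs=3, seed=1,
        )
        runs = pm.run_simulation(p)
        assert len({r["seed"] for r in runs}) == 3


class TestBlockAnalysis:
    def test_tetrahedron_gyration_isotropic(self):
        verts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        lam = gyration_eigenvalues(verts)
        assert lam == pytest.approx([1.0, 1.0, 1.0])

    def test_surface_contact_rule(self):
        p = SimParams(
            box=(8.0, 8.0, 8.0), n_blocks=2, inactive_per_block=4,
            active_per_block=1, with_solvent=False, seed=1,
        )
        system = init_system(p, np.random.default_rng(1))
        pos = system.positions.copy()
        chain = system.chain_index
        # block 0 high above the wall, block 1 with exactly one touching bead
        pos[chain[:5], 2] = 5.0
        pos[chain[5:10], 2] = 5.0
        pos[chain[5], 2] = 0.5
        for k, i in enumerate(chain):
            pos[i, 0] = 1.0 + 0.4 * k
            pos[i, 1] = 4.0
        summaries = block_summary(pos, system)
        assert summaries[0].n_surface_contacts == 0
        assert not summaries[0].is_lad
        assert summaries[1].n_surface_contacts == 1
        assert summaries[1].is_lad

    def test_oblateness_low_for_flat_cloud(self, rng):
        flat = np.column_stack(
            [rng.uniform(0, 5, 200), rng.uniform(0, 5, 200), rng.uniform(0, 0.2, 200)]
        )
        lam = gyration_eigenvalues(flat)
        assert lam[2] / math.sqrt(lam[0] * lam[1]) < 0.1

    def test_distance_map_straight_line(self):
        p = SimParams(
            box=(100.0, 100.0, 100.0), n_blocks=2, inactive_per_block=8,
            active_per_block=2, with_solvent=False, with_wall=False, seed=1,
        )
        system = init_system(p, np.random.default_rng(1))
        pos = system.positions.copy()
        chain = system.chain_index
        for k, i in enumerate(chain):
            pos[i] = [10.0 + 0.5 * k, 50.0, 50.0]
        run = {"snapshots": [pos], "steps": [0]}
        dmap = ensemble_distance_map([run], system, coarse_grain=5, discard_fraction=0.0)
        # straight chain: distances proportional to |i - j|
        assert dmap[0, 1] == pytest.approx(2.5)
        assert dmap[0, 3] == pytest.approx(7.5)
        np.testing.assert_allclose(dmap, dmap.T)
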