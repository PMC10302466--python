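"""Unit and property tests for the Lennard-Jones MD engine."""

from __future__ import annotations

import numpy as np
import pytest

from pointrdf.datatypes import (
    CapacityError,
    Condition,
    LJParams,
    OverlapError,
    Snapshot,
)
from pointrdf.md_engine import (
    compute_forces,
    draw_velocities,
    generate_grid,
    init_configuration,
    kinetic_temperature,
    run_condition,
    step_nvt,
)
from pointrdf.rdf_core import RadialGrid, trajectory_rdfset


def min_image_min_distance(positions, box):
    """All-pairs minimum-image minimum distance, explicit double loop."""
    n = len(positions)
    dmin = np.inf
    for i in range(n):
        for j in range(i + 1, n):
            d = positions[i] - positions[j]
            d -= box * np.round(d / box)
            dmin = min(dmin, float(np.sqrt(np.sum(d * d))))
    return dmin


class TestInitConfiguration:
    def test_two_atoms_single_species(self, lj_params):
        snap = init_configuration(2, (20.0, 20.0, 20.0), [1.0], seed=3)
        assert snap.n_atoms == 2
        assert set(snap.species) == {0}
        assert min_image_min_distance(snap.positions, snap.box) >= 0.85

    def test_same_seed_bitwise_identical(self, lj_params):
        a = init_configuration(64, (8.0, 8.0, 8.0), [1.0], seed=11)
        b = init_configuration(64, (8.0, 8.0, 8.0), [1.0], seed=11)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)
        assert np.array_equal(a.species, b.species)

    def test_binary_counts_and_min_distance(self, binary_params):
        snap = init_configuration(
            500, (7.5, 7.5, 7.5), [0.5, 0.5], seed=5, params=binary_params
        )
        counts = np.bincount(snap.species, minlength=2)
        assert abs(counts[0] - 250) <= 1 and counts.sum() == 500
        assert min_image_min_distance(snap.positions, snap.box) >= 0.85

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            init_configuration(500, (3.0, 3.0, 3.0), [1.0], seed=0)


class TestDrawVelocities:
    def test_momentum_removed_and_temperature_exact(self):
        v = draw_velocities(50, 1.3, 1.0, seed=2)
        masses = np.ones(50)
        assert np.allclose(np.sum(v, axis=0), 0.0, atol=1e-12)
        assert kinetic_temperature(v, masses) == pytest.approx(1.3, rel=1e-12)

    def test_component_variance_matches_maxwell_boltzmann(self):
        # n = 10000: empirical per-component variance within 3% of kT/m
        v = draw_velocities(10000, 1.0, 2.0, seed=9)
        assert np.allclose(v.var(axis=0), 1.0 / 2.0, rtol=0.03)


class TestForces:
    def test_zero_force_at_lj_minimum(self, lj_params):
        d = 2.0 ** (1.0 / 6.0)
        snap = Snapshot(
            positions=np.array([[1.0, 1.0, 1.0], [1.0 + d, 1.0, 1.0]]),
            velocities=np.zeros((2, 3)),
            species=np.zeros(2, int),
            box=np.array([10.0, 10.0, 10.0]),
        )
        forces, _ = compute_forces(snap, lj_params)
        assert np.allclose(forces, 0.0, atol=1e-12)

    def test_newtons_third_law(self, liquid_trajectory, lj_params):
        forces, _ = compute_forces(liquid_trajectory[0], lj_params)
        assert np.allclose(forces.sum(axis=0), 0.0, atol=1e-9)

    def test_matches_finite_difference_gradient(self, lj_params):
        snap = init_configuration(50, (6.0, 6.0, 6.0), [1.0], seed=21)
        forces, _ = compute_forces(snap, lj_params)
        rng = np.random.default_rng(0)
        h = 1e-6
        # probe 12 random coordinates against central differences
        for _ in range(12):
            i = int(rng.integers(snap.n_atoms))
            ax = int(rng.integers(3))
            up, dn = snap.copy(), snap.copy()
            up.positions[i, ax] += h
            dn.positions[i, ax] -= h
            _, e_up = compute_forces(up, lj_params)
            _, e_dn = compute_forces(dn, lj_params)
            fd = -(e_up - e_dn) / (2 * h)
            scale = max(1.0, abs(forces[i, ax]))
            assert forces[i, ax] == pytest.approx(fd, abs=1e-5 * scale)

    def test_overlap_raises(self, lj_params):
        snap = Snapshot(
            positions=np.array([[1.0, 1.0, 1.0], [1.3, 1.0, 1.0]]),
            velocities=np.zeros((2, 3)),
            species=np.zeros(2, int),
            box=np.array([10.0, 10.0, 10.0]),
        )
        with pytest.raises(OverlapError):
            compute_forces(snap, lj_params)

    def test_cutoff_must_fit_box(self, lj_params):
        snap = Snapshot(
            positions=np.array([[0.5, 0.5, 0.5], [2.0, 2.0, 2.0]]),
            velocities=np.zeros((2, 3)),
            species=np.zeros(2, int),
            box=np.array([4.0, 4.0, 4.0]),
        )
        with pytest.raises(ValueError, match="cutoff"):
            compute_forces(snap, lj_params)


class TestIntegration:
    def test_zero_force_fixed_point(self, lj_params):
        d = 2.0 ** (1.0 / 6.0)
        snap = Snapshot(
            positions=np.array([[1.0, 1.0, 1.0], [1.0 + d, 1.0, 1.0]]),
            velocities=np.zeros((2, 3)),
            species=np.zeros(2, int),
            box=np.array([10.0, 10.0, 10.0]),
        )
        out = step_nvt(snap, lj_params, dt=0.002, thermostat_coupling=0.0)
        assert np.allclose(out.positions, snap.positions, atol=1e-12)

    def test_nve_energy_and_momentum_conservation(
        self, liquid_trajectory, lj_params
    ):
        snap = liquid_trajectory[10].copy()
        masses = lj_params.atom_masses(snap.species)

        def total_energy(s):
            _, pot = compute_forces(s, lj_params)
            return pot + 0.5 * float(np.sum(masses[:, None] * s.velocities**2))

        e0 = total_energy(snap)
        p0 = np.sum(masses[:, None] * snap.velocities, axis=0)
        for _ in range(1000):
            snap = step_nvt(snap, lj_params, dt=0.002, thermostat_coupling=0.0)
        e1 = total_energy(snap)
        p1 = np.sum(masses[:, None] * snap.velocities, axis=0)
        assert abs(e1 - e0) / abs(e0) < 1e-3
        assert np.allclose(p1, p0, atol=1e-9)

    def test_nvt_temperature_within_two_percent(
        self, liquid_trajectory, lj_params, liquid_condition
    ):
        temps = [
            kinetic_temperature(s.velocities, lj_params.atom_masses(s.species))
            for s in liquid_trajectory
        ]
        assert np.mean(temps) == pytest.approx(
            liquid_condition.temperature, rel=0.02
        )


class TestRunCondition:
    def test_snapshot_count_and_labels(self, lj_params):
        cond = Condition(1.0, 0.8, "c")
        traj = run_condition(
            cond, lj_params, 200, 2000, 100, seed=1, n_atoms=150, dt=0.004
        )
        assert len(traj) == 20
        assert all(s.condition is cond for s in traj)

    def test_determinism(self, lj_params):
        cond = Condition(1.0, 0.8, "c")
        kw = dict(n_atoms=150, dt=0.004)
        a = run_condition(cond, lj_params, 100, 200, 50, seed=4, **kw)
        b = run_condition(cond, lj_params, 100, 200, 50, seed=4, **kw)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.positions, sb.positions)
            assert np.array_equal(sa.velocities, sb.velocities)

    def test_interval_must_divide(self, lj_params):
        with pytest.raises(ValueError):
            run_condition(Condition(1.0, 0.8, "c"), lj_params, 10, 100, 33, 0)

    def test_liquid_structure_sanity(self, liquid_trajectory):
        box = liquid_trajectory[0].box
        grid = RadialGrid.for_box(box)
        g = trajectory_rdfset(liquid_trajectory, grid)[(0, 0)].g
        assert g.max() > 1.0
        tail = g[3 * grid.n_bins // 4:]
        assert abs(tail.mean() - 1.0) < 0.05


class TestIdealGasLimit:
    def test_epsilon_zero_gives_flat_rdf(self):
        params = LJParams(
            epsilon=np.array([[0.0]]),
            sigma=np.array([[1.0]]),
            mass=np.array([1.0]),
            cutoff=2.5,
        )
        cond = Condition(1.0, 0.5, "ideal")
        # free flight decorrelates pair distances only once the relative
        # displacement between samples exceeds a bin width; sample sparsely
        traj = run_condition(
            cond, params, 100, 1200, 150, seed=13, n_atoms=300, dt=0.004
        )
        grid = RadialGrid.for_box(traj[0].box, r_max=3.0, n_bins=40)
        g = trajectory_rdfset(traj, grid)[(0, 0)].g
        n = traj[0].n_atoms
        v_box = float(np.prod(traj[0].box))
        # expected unordered pair count per bin over all frames
        expected = len(traj) * (n * (n - 1) / 2) * grid.shell_volumes / v_box
        assert np.all(np.abs(g - 1.0) <= 3.0 / np.sqrt(expected))


class TestGenerateGrid:
    def test_counts_ids_and_temperature_monotonicity(self, lj_params):
        conds = [
            Condition(t, 0.8, f"T{t:.2f}") for t in np.linspace(0.85, 1.35, 5)
        ]
        trajs = generate_grid(
            conds,
            lj_params,
            seed=3,
            n_equil_steps=800,
            n_prod_steps=600,
            sample_interval=20,
            n_atoms=150,
            dt=0.004,
        )
        assert sorted(trajs) == sorted(c.condition_id for c in conds)
        grid = RadialGrid.for_box(trajs["T0.85"][0].box)
        peaks = {
            cid: trajectory_rdfset(t, grid)[(0, 0)].g.max()
            for cid, t in trajs.items()
        }
        # hotter liquid at the same density has a lower first peak
        assert peaks["T0.85"] > peaks["T1.35"]

    def test_needs_five_conditions(self, lj_params):
        with pytest.raises(ValueError):
            generate_grid([Condition(1.0, 0.8, "a")], lj_params, seed=0)
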