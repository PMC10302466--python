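"""A compact Lennard-Jones molecular dynamics engine.

Generates equilibrated liquid trajectories of one- and two-species LJ
systems under periodic boundary conditions, the labelled-data source for
the RDF surrogate.  Design: velocity-Verlet integration, Berendsen
velocity-rescaling thermostat, constant volume (density is the second
state variable of a condition), reduced units throughout.

Everything is deterministic given its seed: the same (inputs, seed) give
bitwise-identical trajectories on one platform.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

from ._kernels import lj_forces_energy
from .datatypes import (
    CapacityError,
    Condition,
    InstabilityError,
    LJParams,
    OverlapError,
    Snapshot,
    Trajectory,
    wrap_positions,
)

__all__ = [
    "init_configuration",
    "draw_velocities",
    "compute_forces",
    "kinetic_temperature",
    "step_nvt",
    "run_condition",
    "generate_grid",
]

#: default integration time step in reduced LJ time units
DEFAULT_DT = 0.002
#: hard-core floor (in units of the smallest sigma) below which the
#: potential is considered numerically unsafe
OVERLAP_FLOOR = 0.5
#: minimum initial pair separation in units of sigma
MIN_INIT_SEPARATION = 0.85


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Instantaneous kinetic temperature with the centre-of-mass momentum
    constraint accounted for: T = sum(m v^2) / (3 (N - 1) k_B), k_B = 1."""
    n = velocities.shape[0]
    ke2 = float(np.sum(masses[:, None] * velocities**2))
    return ke2 / (3.0 * (n - 1))


def draw_velocities(
    n_atoms: int,
    temperature: float,
    masses: np.ndarray | float,
    seed: int,
) -> np.ndarray:
    """Maxwell-Boltzmann velocities at ``temperature``.

    Each component is drawn Gaussian with variance kT/m, the aggregate
    linear momentum is removed, and the instantaneous kinetic temperature
    is rescaled exactly to the target.
    """
    if not temperature > 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    masses = np.broadcast_to(np.atleast_1d(np.asarray(masses, float)), (n_atoms,))
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_atoms, 3)) * np.sqrt(temperature / masses)[:, None]
    # remove aggregate linear momentum
    v -= np.sum(masses[:, None] * v, axis=0) / np.sum(masses)
    t_now = kinetic_temperature(v, masses)
    return v * math.sqrt(temperature / t_now)


def init_configuration(
    n_atoms: int,
    box: Sequence[float],
    species_fractions: Sequence[float],
    seed: int,
    *,
    params: LJParams | None = None,
    temperature: float = 1.0,
    condition: Condition | None = None,
) -> Snapshot:
    """Place atoms on a jittered cubic lattice with no pair closer than
    0.85 sigma under minimum image, assign species by the given fractions,
    and draw thermal velocities.

    Raises :class:`CapacityError` when the box cannot host ``n_atoms`` at
    the minimum spacing.
    """
    if n_atoms < 2:
        raise ValueError("need at least 2 atoms")
    fractions = np.asarray(species_fractions, float)
    if fractions.ndim != 1 or not math.isclose(fractions.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("species fractions must sum to 1")
    params = params or LJParams.monatomic()
    if len(fractions) != params.n_species:
        raise ValueError("fractions length must equal the number of species")
    box = np.asarray(box, float)
    sigma_max = float(params.sigma.max())

    # lattice of m^3 sites; the jitter amplitude is capped so the worst-case
    # nearest-neighbour distance stays >= 0.85 sigma
    m = max(2, math.ceil(n_atoms ** (1.0 / 3.0)))
    spacing = box / m
    a_min = float(spacing.min())
    jitter = min(0.05 * a_min, 0.5 * (a_min - MIN_INIT_SEPARATION * sigma_max))
    if jitter < 0:
        raise CapacityError(
            f"box {box} too small for {n_atoms} atoms at spacing "
            f">= {MIN_INIT_SEPARATION} sigma (lattice constant {a_min:.3f})"
        )

    rng = np.random.default_rng(seed)
    sites = np.stack(
        np.meshgrid(*[(np.arange(m) + 0.5) for _ in range(3)], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3) * spacing
    chosen = rng.permutation(m**3)[:n_atoms]
    positions = sites[chosen] + rng.uniform(-jitter, jitter, size=(n_atoms, 3))
    positions = wrap_positions(positions, box)

    # largest-remainder apportionment of species counts, then shuffle
    raw = fractions * n_atoms
    counts = np.floor(raw).astype(int)
    remainder = n_atoms - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    species = np.repeat(np.arange(len(fractions)), counts)
    rng.shuffle(species)

    vel_seed = int(np.random.SeedSequence(seed).generate_state(2)[1] % (2**31))
    velocities = draw_velocities(
        n_atoms, temperature, params.atom_masses(species), vel_seed
    )
    return Snapshot(
        positions=positions,
        velocities=velocities,
        species=species,
        box=box,
        time=0.0,
        condition=condition,
    ).validate()


def _check_cutoff(params: LJParams, box: np.ndarray) -> None:
    if not params.cutoff < 0.5 * float(np.min(box)):
        raise ValueError(
            f"cutoff {params.cutoff} must be < half the smallest box edge "
            f"({0.5 * float(np.min(box)):.4f})"
        )


def compute_forces(
    snapshot: Snapshot, params: LJParams
) -> tuple[np.ndarray, float]:
    """Forces (exact negative gradient of the truncated-and-shifted pair
    energy under minimum image) and the potential energy."""
    _check_cutoff(params, snapshot.box)
    forces, potential, min_r2 = lj_forces_energy(
        snapshot.positions,
        snapshot.species,
        snapshot.box,
        params.epsilon,
        params.sigma,
        params.energy_shift,
        params.cutoff,
    )
    floor = OVERLAP_FLOOR * float(params.sigma.min())
    # overlaps are only numerically dangerous when the potential acts
    if float(params.epsilon.max()) > 0 and min_r2 < floor * floor:
        raise OverlapError(
            f"atom pair at distance {math.sqrt(min_r2):.4f} below the hard "
            f"floor {floor:.4f}"
        )
    return forces, potential


def _verlet_steps(
    positions: np.ndarray,
    velocities: np.ndarray,
    species: np.ndarray,
    box: np.ndarray,
    params: LJParams,
    dt: float,
    n_steps: int,
    thermostat_coupling: float,
    target_temperature: float,
    step_offset: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """In-place velocity-Verlet loop with optional Berendsen rescaling.

    ``thermostat_coupling`` is the dimensionless dt/tau of the Berendsen
    scheme; 0 disables the thermostat (NVE).
    """
    masses = params.atom_masses(species)[:, None]
    eps, sig, shift, rc = (
        params.epsilon,
        params.sigma,
        params.energy_shift,
        params.cutoff,
    )
    floor2 = (OVERLAP_FLOOR * float(params.sigma.min())) ** 2
    if float(eps.max()) == 0.0:
        floor2 = -1.0  # free particles: overlaps are harmless
    forces, _, min_r2 = lj_forces_energy(positions, species, box, eps, sig, shift, rc)
    if min_r2 < floor2:
        raise OverlapError("overlapping atoms in the starting configuration")
    for k in range(n_steps):
        velocities += (0.5 * dt) * forces / masses
        positions += dt * velocities
        positions -= np.floor(positions / box) * box
        forces, _, min_r2 = lj_forces_energy(
            positions, species, box, eps, sig, shift, rc
        )
        velocities += (0.5 * dt) * forces / masses
        if min_r2 < floor2:
            raise OverlapError(f"overlap at step {step_offset + k}")
        if not np.all(np.isfinite(positions)):
            raise InstabilityError(
                f"non-finite coordinates at step {step_offset + k}"
            )
        if thermostat_coupling > 0.0:
            t_now = kinetic_temperature(velocities, masses[:, 0])
            lam = math.sqrt(
                1.0 + thermostat_coupling * (target_temperature / t_now - 1.0)
            )
            velocities *= lam
    return positions, velocities


def step_nvt(
    snapshot: Snapshot,
    params: LJParams,
    dt: float = DEFAULT_DT,
    thermostat_coupling: float = 0.1,
    target_temperature: float | None = None,
) -> Snapshot:
    """One velocity-Verlet step followed by a Berendsen velocity-rescaling
    update; positions re-wrapped into the box.  Coupling 0 gives NVE."""
    if not dt > 0:
        raise ValueError("dt must be > 0")
    _check_cutoff(params, snapshot.box)
    if target_temperature is None:
        if thermostat_coupling > 0 and snapshot.condition is None:
            raise ValueError("thermostat needs a target temperature")
        target_temperature = (
            snapshot.condition.temperature if snapshot.condition else 1.0
        )
    out = snapshot.copy()
    out.positions, out.velocities = _verlet_steps(
        out.positions,
        out.velocities,
        out.species,
        out.box,
        params,
        dt,
        1,
        thermostat_coupling,
        target_temperature,
    )
    out.positions = wrap_positions(out.positions, out.box)
    out.time = snapshot.time + dt
    return out


def run_condition(
    condition: Condition,
    params: LJParams,
    n_equil_steps: int,
    n_prod_steps: int,
    sample_interval: int,
    seed: int,
    *,
    n_atoms: int = 400,
    species_fractions: Sequence[float] | None = None,
    dt: float = DEFAULT_DT,
    thermostat_coupling: float = 0.1,
) -> Trajectory:
    """Equilibrate then sample a constant-volume trajectory of one condition.

    The box edge follows from the condition's number density
    (``pressure_or_density``); equilibration frames are discarded and
    ``n_prod_steps / sample_interval`` production snapshots are returned,
    all labelled with the condition.
    """
    if n_prod_steps % sample_interval != 0:
        raise ValueError("sample_interval must divide n_prod_steps")
    if species_fractions is None:
        species_fractions = [1.0 / params.n_species] * params.n_species
    density = condition.pressure_or_density
    if not density > 0:
        raise ValueError("condition density must be > 0 for the NVT engine")
    edge = (n_atoms / density) ** (1.0 / 3.0)
    box = np.array([edge, edge, edge])
    snap = init_configuration(
        n_atoms,
        box,
        species_fractions,
        seed,
        params=params,
        temperature=condition.temperature,
        condition=condition,
    )
    pos, vel = snap.positions, snap.velocities
    try:
        pos, vel = _verlet_steps(
            pos, vel, snap.species, box, params, dt, n_equil_steps,
            thermostat_coupling, condition.temperature,
        )
        snapshots: list[Snapshot] = []
        for k in range(n_prod_steps // sample_interval):
            pos, vel = _verlet_steps(
                pos, vel, snap.species, box, params, dt, sample_interval,
                thermostat_coupling, condition.temperature,
                step_offset=n_equil_steps + k * sample_interval,
            )
            snapshots.append(
                Snapshot(
                    positions=wrap_positions(pos.copy(), box),
                    velocities=vel.copy(),
                    species=snap.species.copy(),
                    box=box.copy(),
                    time=(n_equil_steps + (k + 1) * sample_interval) * dt,
                    condition=condition,
                )
            )
    except (InstabilityError, OverlapError) as err:
        raise type(err)(f"condition {condition.condition_id}: {err}") from err
    return Trajectory(
        condition=condition,
        snapshots=snapshots,
        sample_interval=sample_interval * dt,
    ).validate()


def generate_grid(
    conditions: Sequence[Condition],
    params: LJParams,
    seed: int,
    *,
    n_equil_steps: int = 2000,
    n_prod_steps: int = 3000,
    sample_interval: int = 20,
    n_atoms: int = 400,
    species_fractions: Sequence[float] | None = None,
    dt: float = DEFAULT_DT,
    thermostat_coupling: float = 0.1,
) -> Mapping[str, Trajectory]:
    """One trajectory per condition; per-condition seeds are forked
    deterministically from the master seed."""
    if len(conditions) < 5:
        raise ValueError("need at least 5 conditions for a non-degenerate split")
    ids = [c.condition_id for c in conditions]
    if len(set(ids)) != len(ids):
        raise ValueError("condition_ids must be unique")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(conditions))
    out: dict[str, Trajectory] = {}
    for cond, child in zip(conditions, child_seeds):
        out[cond.condition_id] = run_condition(
            cond,
            params,
            n_equil_steps,
            n_prod_steps,
            sample_interval,
            int(child % (2**31)),
            n_atoms=n_atoms,
            species_fractions=species_fractions,
            dt=dt,
            thermostat_coupling=thermostat_coupling,
        )
    return out
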