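"""Core data containers shared by the simulation engine, the RDF machinery
and the surrogate model.

All quantities default to reduced Lennard-Jones units (``sigma = epsilon =
mass = k_B = 1``); a unit tag travels with trajectories read from external
files so physical-unit data are never silently mixed with reduced-unit data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Condition",
    "Snapshot",
    "Trajectory",
    "LJParams",
    "wrap_positions",
]


class CapacityError(ValueError):
    """A box is too small to host the requested atoms at minimum spacing."""


class OverlapError(ValueError):
    """Two atoms are closer than the hard-core floor of the potential."""


class InstabilityError(RuntimeError):
    """The integrator produced non-finite coordinates."""


def wrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into the primary periodic cell ``[0, L)``."""
    box = np.asarray(box, dtype=float)
    wrapped = np.mod(positions, box)
    # mod of a tiny negative value can round to exactly L; fold to 0
    return np.where(wrapped >= box, 0.0, wrapped)


@dataclass(frozen=True)
class Condition:
    """One thermodynamic state labelling a simulation.

    ``pressure_or_density`` is the second state variable next to temperature.
    The bundled engine runs at constant volume, so for internally generated
    data it holds the number density; externally labelled data may carry a
    pressure instead.  The surrogate consumes the pair as two scalars either
    way.
    """

    temperature: float
    pressure_or_density: float
    condition_id: str

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")

    @property
    def state_scalars(self) -> np.ndarray:
        """(pressure-or-density, temperature) as a 2-vector."""
        return np.array([self.pressure_or_density, self.temperature], float)


@dataclass
class Snapshot:
    """One molecular configuration: positions, velocities, species, box.

    Invariants (checked by :meth:`validate`): positions wrapped to
    ``[0, L)``; positions/velocities/species share length ``N >= 2``;
    box edges strictly positive.
    """

    positions: np.ndarray  # (N, 3)
    velocities: np.ndarray  # (N, 3)
    species: np.ndarray  # (N,) small dense integers
    box: np.ndarray  # (3,) orthorhombic edge lengths
    time: float = 0.0
    condition: Condition | None = None
    has_velocities: bool = True  # False when read from a velocity-free file
    units: str = "reduced"

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.species = np.ascontiguousarray(self.species, dtype=np.int64)
        self.box = np.asarray(self.box, dtype=np.float64)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def n_species(self) -> int:
        return int(self.species.max()) + 1 if self.species.size else 0

    def validate(self) -> "Snapshot":
        n = self.n_atoms
        if n < 2:
            raise ValueError(f"need at least 2 atoms, got {n}")
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError("positions and velocities must both be (N, 3)")
        if self.species.shape != (n,):
            raise ValueError("species must be length N")
        if not np.all(self.box > 0):
            raise ValueError(f"box edges must be positive, got {self.box}")
        if np.any(self.positions < 0) or np.any(self.positions >= self.box):
            raise ValueError("positions must be wrapped into [0, box)")
        if not np.all(np.isfinite(self.positions)) or not np.all(
            np.isfinite(self.velocities)
        ):
            raise ValueError("non-finite coordinates or velocities")
        return self

    def copy(self) -> "Snapshot":
        return Snapshot(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            species=self.species.copy(),
            box=self.box.copy(),
            time=self.time,
            condition=self.condition,
            has_velocities=self.has_velocities,
            units=self.units,
        )


@dataclass
class Trajectory:
    """Time-ordered snapshots of one condition at constant N, V and species."""

    condition: Condition | None
    snapshots: list[Snapshot]
    sample_interval: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)

    def __getitem__(self, idx):
        return self.snapshots[idx]

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    def validate(self) -> "Trajectory":
        if not self.snapshots:
            raise ValueError("trajectory holds no snapshots")
        first = self.snapshots[0].validate()
        times = self.times
        if np.any(np.diff(times) <= 0):
            raise ValueError("snapshot times must be strictly increasing")
        for snap in self.snapshots[1:]:
            snap.validate()
            if snap.n_atoms != first.n_atoms:
                raise ValueError("atom count varies across frames")
            if not np.array_equal(snap.species, first.species):
                raise ValueError("species vary across frames")
            if not np.allclose(snap.box, first.box):
                raise ValueError("box varies across frames")
        return self


@dataclass
class LJParams:
    """Pairwise Lennard-Jones parameters for up to a handful of species.

    ``epsilon`` and ``sigma`` are (S, S) symmetric matrices over species
    pairs, ``mass`` per-species.  The pair potential is truncated and
    shifted at ``cutoff`` so the energy is continuous there.
    """

    epsilon: np.ndarray  # (S, S)
    sigma: np.ndarray  # (S, S)
    mass: np.ndarray  # (S,)
    cutoff: float = 2.5

    def __post_init__(self) -> None:
        self.epsilon = np.atleast_2d(np.asarray(self.epsilon, float))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, float))
        self.mass = np.atleast_1d(np.asarray(self.mass, float))
        if self.epsilon.shape != self.sigma.shape:
            raise ValueError("epsilon and sigma shapes differ")
        s = self.epsilon.shape[0]
        if self.epsilon.shape != (s, s) or self.mass.shape != (s,):
            raise ValueError("epsilon/sigma must be (S, S) and mass (S,)")
        if np.any(self.epsilon < 0) or np.any(self.sigma <= 0):
            raise ValueError("epsilon must be >= 0 and sigma > 0")
        if np.any(self.mass <= 0) or not self.cutoff > 0:
            raise ValueError("mass and cutoff must be > 0")
        if not np.allclose(self.epsilon, self.epsilon.T) or not np.allclose(
            self.sigma, self.sigma.T
        ):
            raise ValueError("epsilon and sigma must be symmetric")

    @property
    def n_species(self) -> int:
        return self.epsilon.shape[0]

    @property
    def energy_shift(self) -> np.ndarray:
        """Pair energy at the cutoff, subtracted to make U continuous."""
        sr6 = (self.sigma / self.cutoff) ** 6
        return 4.0 * self.epsilon * (sr6 * sr6 - sr6)

    def atom_masses(self, species: np.ndarray) -> np.ndarray:
        return self.mass[np.asarray(species, int)]

    @classmethod
    def monatomic(
        cls, epsilon: float = 1.0, sigma: float = 1.0, mass: float = 1.0,
        cutoff: float = 2.5,
    ) -> "LJParams":
        return cls(
            epsilon=np.array([[epsilon]]),
            sigma=np.array([[sigma]]),
            mass=np.array([mass]),
            cutoff=cutoff,
        )

    @classmethod
    def mixture(
        cls,
        epsilons: Sequence[float],
        sigmas: Sequence[float],
        masses: Sequence[float],
        cutoff: float = 2.5,
    ) -> "LJParams":
        """Multi-species parameters with Lorentz-Berthelot combining rules:
        arithmetic-mean sigma, geometric-mean epsilon for cross pairs."""
        eps = np.asarray(epsilons, float)
        sig = np.asarray(sigmas, float)
        mass = np.asarray(masses, float)
        if not (len(eps) == len(sig) == len(mass)):
            raise ValueError("epsilons, sigmas, masses must have equal length")
        eps_mat = np.sqrt(np.outer(eps, eps))
        sig_mat = 0.5 * (sig[:, None] + sig[None, :])
        return cls(epsilon=eps_mat, sigma=sig_mat, mass=mass, cutoff=cutoff)
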