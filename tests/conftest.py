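"""Shared fixtures: small equilibrated LJ trajectories generated once per
session so the physics-heavy tests stay fast."""

from __future__ import annotations

import numpy as np
import pytest

from pointrdf.datatypes import Condition, LJParams
from pointrdf.md_engine import run_condition


@pytest.fixture(scope="session")
def lj_params() -> LJParams:
    return LJParams.monatomic()


@pytest.fixture(scope="session")
def liquid_condition() -> Condition:
    return Condition(
        temperature=1.0, pressure_or_density=0.8, condition_id="liq-T1.0"
    )


@pytest.fixture(scope="session")
def liquid_trajectory(liquid_condition, lj_params):
    """50 frames of a 256-atom LJ liquid at rho* = 0.8, T* = 1.0."""
    return run_condition(
        liquid_condition,
        lj_params,
        n_equil_steps=1500,
        n_prod_steps=1000,
        sample_interval=20,
        seed=42,
        n_atoms=256,
        dt=0.004,
    )


@pytest.fixture(scope="session")
def binary_params() -> LJParams:
    return LJParams.mixture(
        epsilons=(1.0, 0.9), sigmas=(1.0, 0.9), masses=(1.0, 0.8)
    )


@pytest.fixture(scope="session")
def binary_trajectory(binary_params):
    """20 frames of a 50/50 binary LJ mixture."""
    cond = Condition(
        temperature=1.0, pressure_or_density=0.8, condition_id="mix-T1.0"
    )
    return run_condition(
        cond,
        binary_params,
        n_equil_steps=1000,
        n_prod_steps=400,
        sample_interval=20,
        seed=7,
        n_atoms=200,
        species_fractions=(0.5, 0.5),
        dt=0.004,
    )


def brute_force_rdf(snapshot, pair, grid) -> np.ndarray:
    """Independent O(N^2) reference RDF with explicit minimum-image
    arithmetic and half-open bins, used as the oracle for snapshot_rdf."""
    a, b = sorted(pair)
    idx_a = [i for i in range(snapshot.n_atoms) if snapshot.species[i] == a]
    idx_b = [i for i in range(snapshot.n_atoms) if snapshot.species[i] == b]
    box = snapshot.box
    counts = np.zeros(grid.n_bins)
    dr = grid.r_max / grid.n_bins
    for i in idx_a:
        for j in idx_b:
            if i == j:
                continue
            d = snapshot.positions[i] - snapshot.positions[j]
            for ax in range(3):
                while d[ax] > 0.5 * box[ax]:
                    d[ax] -= box[ax]
                while d[ax] < -0.5 * box[ax]:
                    d[ax] += box[ax]
            r = float(np.sqrt(np.sum(d * d)))
            if r < grid.r_max:
                counts[int(r // dr)] += 1.0
    # counts are ordered pairs already (both (i, j) and (j, i) for a == b)
    n_a = len(idx_a)
    n_b = len(idx_b)
    n_pairs = n_a * (n_a - 1) if a == b else n_a * n_b
    shell = (4.0 / 3.0) * np.pi * (
        grid.edges[1:] ** 3 - grid.edges[:-1] ** 3
    )
    ideal = n_pairs * shell / float(np.prod(box))
    return counts / ideal
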