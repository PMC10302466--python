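"""Desk-scale end-to-end experiments: simulate a condition grid, train the
surrogate, and compare it with the direct-MD single-snapshot baseline.

The study design mirrors the full-scale protocol in miniature: a grid of
(temperature, density) conditions of a Lennard-Jones liquid, network
inputs sampled only from the leading 20% of each production run, labels
averaged over the whole run, and a condition-wise train/validation/test
split.  Default problem sizes (12 conditions, 400 atoms, 150 production
frames) are chosen so a full experiment runs in a few minutes on one CPU
core while leaving the liquid-state physics intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datatypes import Condition, LJParams
from .md_engine import generate_grid
from .pointcloud_model import FeatureNormalizer, ModelSpec, build_model
from .rdf_core import RadialGrid, species_pairs
from .train_eval import (
    TrainConfig,
    build_dataset,
    evaluate,
    split_conditions,
    train,
)

__all__ = [
    "ExperimentConfig",
    "default_conditions",
    "run_experiment",
    "simple_fluid_experiment",
    "binary_mixture_experiment",
]

#: temperatures and densities spanning a comfortably liquid/dense-fluid
#: region of the LJ phase diagram (reduced units)
DEFAULT_TEMPERATURES = (0.95, 1.05, 1.15, 1.25)
DEFAULT_DENSITIES = (0.75, 0.80, 0.85)


def default_conditions(
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
    densities: Sequence[float] = DEFAULT_DENSITIES,
) -> list[Condition]:
    """The condition grid: the cross product of temperatures and densities."""
    conds = []
    for rho in densities:
        for t in temperatures:
            conds.append(
                Condition(
                    temperature=t,
                    pressure_or_density=rho,
                    condition_id=f"rho{rho:.2f}_T{t:.2f}",
                )
            )
    return conds


@dataclass
class ExperimentConfig:
    """Everything one end-to-end run needs, with desk-scale defaults."""

    conditions: list[Condition] = field(default_factory=default_conditions)
    params: LJParams = field(default_factory=LJParams.monatomic)
    species_fractions: tuple[float, ...] = (1.0,)
    n_atoms: int = 400
    n_equil_steps: int = 2000
    n_prod_frames: int = 150
    sample_interval: int = 20
    dt: float = 0.004
    thermostat_coupling: float = 0.1
    r_max: float = 3.4
    n_bins: int = 100
    input_window: float = 0.2
    stride: int = 1
    include_velocities: bool = True
    pointwise_layer_widths: tuple[int, ...] = (32, 64)
    head_layer_widths: tuple[int, ...] = (128, 128)
    split_fractions: tuple[float, float, float] = (10 / 12, 1 / 12, 1 / 12)
    max_epochs: int = 700
    patience: int = 100
    batch_size: int = 8
    learning_rate: float = 1e-3


def run_experiment(config: ExperimentConfig, seed: int) -> dict:
    """Simulate, train and evaluate once; return the evaluation summary.

    The returned dict includes the held-out conditions' mean per-frame R^2,
    the model and MD-baseline mean epsilon_RDF and their ratio, the split,
    and the training history length.
    """
    sim_seed, split_seed, init_seed, train_seed = (
        int(s % (2**31))
        for s in np.random.SeedSequence(seed).generate_state(4)
    )
    trajectories = generate_grid(
        config.conditions,
        config.params,
        sim_seed,
        n_equil_steps=config.n_equil_steps,
        n_prod_steps=config.n_prod_frames * config.sample_interval,
        sample_interval=config.sample_interval,
        n_atoms=config.n_atoms,
        species_fractions=config.species_fractions,
        dt=config.dt,
        thermostat_coupling=config.thermostat_coupling,
    )
    grid = RadialGrid(config.r_max, config.n_bins)
    split = split_conditions(
        sorted(trajectories), config.split_fractions, split_seed
    )
    samples, truths, normalizer = build_dataset(
        trajectories,
        grid,
        input_window=config.input_window,
        stride=config.stride,
        include_velocities=config.include_velocities,
        split=split,
    )
    n_pairs = len(species_pairs(normalizer.n_species))
    spec = ModelSpec(
        n_point_features=normalizer.n_point_features,
        n_output_pairs=n_pairs,
        n_bins_per_pair=config.n_bins,
        pointwise_layer_widths=config.pointwise_layer_widths,
        head_layer_widths=config.head_layer_widths,
    )
    model = build_model(spec, init_seed)
    train_cfg = TrainConfig(
        learning_rate=config.learning_rate,
        max_epochs=config.max_epochs,
        patience=config.patience,
        batch_size=config.batch_size,
        seed=train_seed,
        input_window=config.input_window,
        stride=config.stride,
    )
    model, history = train(model, samples, split, train_cfg)
    test_samples = [s for s in samples if s.condition_id in split.test]
    report = evaluate(model, test_samples, truths, normalizer)
    out = dict(report.summary)
    out.update(
        {
            "split": {
                "train": list(split.train),
                "validation": list(split.validation),
                "test": list(split.test),
            },
            "epochs_run": int(len(history)),
            "best_val_mse": float(history["best_val_mse"].iloc[-1]),
            "n_pairs": n_pairs,
            "pair_order": [list(p) for p in normalizer.pairs],
            "seed": seed,
        }
    )
    return out


def simple_fluid_experiment(seed: int, **overrides) -> dict:
    """The monatomic LJ experiment: one species, one Ar-like RDF."""
    config = ExperimentConfig(**overrides)
    return run_experiment(config, seed)


def binary_mixture_experiment(seed: int, **overrides) -> dict:
    """The two-species variant: a mild binary LJ mixture with
    Lorentz-Berthelot cross terms and three partial RDFs predicted
    simultaneously from one configuration."""
    defaults = dict(
        params=LJParams.mixture(
            epsilons=(1.0, 0.9), sigmas=(1.0, 0.9), masses=(1.0, 0.8)
        ),
        species_fractions=(0.5, 0.5),
        max_epochs=150,
    )
    defaults.update(overrides)
    config = ExperimentConfig(**defaults)
    return run_experiment(config, seed)
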