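"""Dataset assembly, condition-wise splitting, training and evaluation.

The experimental design: many constant-volume simulations across a grid of
(state, temperature) conditions; network inputs are single snapshots drawn
only from the leading window of each trajectory, while every sample's
regression target is the condition's full-trajectory averaged RDF.  Splits
are by condition, never by frame, so no test condition leaks into training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import Condition, Snapshot, Trajectory
from .pointcloud_model import (
    FeatureNormalizer,
    ModelSpec,
    PointNetRDF,
    build_model,
    forward,
)
from .rdf_core import (
    RadialGrid,
    RDFSet,
    r2_score,
    rdf_error,
    relative_error,
    snapshot_rdf,
    species_pairs,
    trajectory_rdfset,
)

__all__ = [
    "ConditionSplit",
    "TrainConfig",
    "TrainingSample",
    "EvalReport",
    "split_conditions",
    "build_dataset",
    "train",
    "evaluate",
]


@dataclass(frozen=True)
class ConditionSplit:
    """Disjoint condition-id sets; all frames of a condition share a subset."""

    train: tuple[str, ...]
    validation: tuple[str, ...]
    test: tuple[str, ...]
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.validation), set(self.test)]
        if any(not s for s in sets):
            raise ValueError("every split subset must be non-empty")
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("split subsets must be disjoint")

    @property
    def all_ids(self) -> set[str]:
        return set(self.train) | set(self.validation) | set(self.test)

    def subset_of(self, condition_id: str) -> str:
        for name in ("train", "validation", "test"):
            if condition_id in getattr(self, name):
                return name
        raise KeyError(condition_id)


def split_conditions(
    condition_ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> ConditionSplit:
    """Randomly partition conditions into train/validation/test.

    Validation and test sizes are ``round(fraction * n)``; the remainder
    goes to training (400 conditions at (0.8, 0.1, 0.1) give 320/40/40).
    """
    ids = list(condition_ids)
    n = len(ids)
    if n < 5:
        raise ValueError("need at least 5 conditions to split")
    if len(set(ids)) != n:
        raise ValueError("condition ids must be unique")
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    # round half up, so 5 conditions at 10% still yield one each
    n_val = math.floor(fractions[1] * n + 0.5)
    n_test = math.floor(fractions[2] * n + 0.5)
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("each subset must receive at least one condition")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(n)]
    return ConditionSplit(
        train=tuple(order[:n_train]),
        validation=tuple(order[n_train:n_train + n_val]),
        test=tuple(order[n_train + n_val:]),
        fractions=fractions,
        seed=seed,
    )


@dataclass
class TrainingSample:
    """One network input/target: per-point features, state scalars, and the
    condition's full-trajectory averaged RDF as target."""

    point_features: np.ndarray  # (N, 3+M), already normalised
    state_scalars: np.ndarray  # (2,), standardised
    target: np.ndarray  # concatenated per-pair g(r)
    condition_id: str
    snapshot: Snapshot | None = None  # kept for the MD-baseline comparison

    def __post_init__(self) -> None:
        if not (
            np.all(np.isfinite(self.point_features))
            and np.all(np.isfinite(self.state_scalars))
            and np.all(np.isfinite(self.target))
        ):
            raise ValueError("non-finite entries in a training sample")


@dataclass
class TrainConfig:
    """Optimisation settings: Adam at learning rate 1e-3, MSE loss, early
    stopping on validation MSE."""

    learning_rate: float = 1e-3
    max_epochs: int = 1000
    patience: int = 20
    batch_size: int = 32
    seed: int = 0
    input_window: float = 0.2  # leading fraction of each trajectory
    stride: int = 1

    def __post_init__(self) -> None:
        if not self.learning_rate > 0:
            raise ValueError("learning rate must be > 0")
        if self.patience < 1 or self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("patience, max_epochs, batch_size must be >= 1")
        if not 0 < self.input_window <= 1 or self.stride < 1:
            raise ValueError("input_window in (0, 1], stride >= 1")


def build_dataset(
    trajectories: Mapping[str, Trajectory],
    grid: RadialGrid,
    *,
    input_window: float = 0.2,
    stride: int = 1,
    include_velocities: bool = True,
    split: ConditionSplit | None = None,
) -> tuple[list[TrainingSample], dict[str, RDFSet], FeatureNormalizer]:
    """Assemble training samples and ground truths from a condition grid.

    Inputs are drawn only from the leading ``input_window`` fraction of
    each trajectory at the given stride; the target of every sample is the
    condition's RDF averaged over *all* frames.  Normalisation statistics
    (velocity RMS, state mean/std) are fitted on the training conditions
    when a split is provided, otherwise on all conditions.
    """
    if not trajectories:
        raise ValueError("no trajectories given")
    n_species = max(
        t.snapshots[0].n_species for t in trajectories.values()
    )
    fit_ids = set(split.train) if split is not None else set(trajectories)
    vel_sq, n_vel = 0.0, 0
    states = []
    for cid in sorted(fit_ids):
        traj = trajectories[cid]
        states.append(traj.condition.state_scalars)
        for snap in traj:
            vel_sq += float(np.sum(snap.velocities**2))
            n_vel += snap.velocities.size
    states = np.array(states)
    std = states.std(axis=0)
    normalizer = FeatureNormalizer(
        n_species=n_species,
        include_velocities=include_velocities,
        v_rms=math.sqrt(vel_sq / n_vel) if n_vel else 1.0,
        state_mean=states.mean(axis=0),
        state_std=np.where(std > 0, std, 1.0),
        grid=grid,
    )

    samples: list[TrainingSample] = []
    ground_truths: dict[str, RDFSet] = {}
    pairs = species_pairs(n_species)
    for cid in sorted(trajectories):
        traj = trajectories[cid]
        n_frames = len(traj)
        n_window = max(1, int(round(input_window * n_frames)))
        if n_window == 0:
            raise ValueError(f"condition {cid}: empty input window")
        truth = trajectory_rdfset(traj, grid, pairs)
        ground_truths[cid] = truth
        target = truth.concatenated()
        for snap in traj.snapshots[:n_window:stride]:
            samples.append(
                TrainingSample(
                    point_features=normalizer.point_features(snap),
                    state_scalars=normalizer.state_scalars(traj.condition),
                    target=target,
                    condition_id=cid,
                    snapshot=snap,
                )
            )
    return samples, ground_truths, normalizer


def _stack(samples: Sequence[TrainingSample]):
    X = np.stack([s.point_features for s in samples])
    S = np.stack([s.state_scalars for s in samples])
    Y = np.stack([s.target for s in samples])
    return X, S, Y


class _Adam:
    """Adam with the standard defaults (beta1 0.9, beta2 0.999, eps 1e-8)."""

    def __init__(self, params: Sequence[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]):
        self.t += 1
        out = []
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def train(
    model: PointNetRDF,
    samples: Sequence[TrainingSample],
    split: ConditionSplit,
    config: TrainConfig,
) -> tuple[PointNetRDF, pd.DataFrame]:
    """Minibatch Adam on the MSE between predicted and averaged RDFs.

    Stops at ``max_epochs`` or once validation MSE has not improved for
    ``patience`` epochs, restoring the best-validation parameters.  Fully
    reproducible from ``config.seed``.
    """
    sample_ids = {s.condition_id for s in samples}
    if not (sample_ids & set(split.train)) or not (
        sample_ids & set(split.validation)
    ):
        raise ValueError("training and validation sets must both be non-empty")
    train_samples = [s for s in samples if s.condition_id in split.train]
    val_samples = [s for s in samples if s.condition_id in split.validation]
    Xt, St, Yt = _stack(train_samples)
    Xv, Sv, Yv = _stack(val_samples)

    rng = np.random.default_rng(config.seed)
    adam = _Adam(model.parameters, config.learning_rate)
    best_val = math.inf
    best_params = model.copy_parameters()
    best_epoch = -1
    history: list[dict] = []
    n = Xt.shape[0]
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        train_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, sb, yb = Xt[idx], St[idx], Yt[idx]
            pred, caches = model.forward_batch(xb, sb, cache=True)
            diff = pred - yb
            loss = float(np.mean(diff**2))
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            train_loss += loss * len(idx)
            d_out = (2.0 / diff.size) * diff
            grads = model.backward_batch(caches, d_out)
            model.set_parameters(adam.step(model.parameters, grads))
        val_pred = model.forward_batch(Xv, Sv)
        val_loss = float(np.mean((val_pred - Yv) ** 2))
        if not math.isfinite(val_loss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        improved = val_loss < best_val
        if improved:
            best_val = val_loss
            best_params = model.copy_parameters()
            best_epoch = epoch
        history.append(
            {
                "epoch": epoch,
                "train_mse": train_loss / n,
                "val_mse": val_loss,
                "best_val_mse": best_val,
            }
        )
        if epoch - best_epoch >= config.patience:
            break
    model.set_parameters(best_params)
    return model, pd.DataFrame(history)


@dataclass
class EvalReport:
    """Per-frame, per-condition and aggregate metrics of a trained model
    against ground truth, alongside the direct-MD single-snapshot baseline."""

    frames: pd.DataFrame  # condition_id, frame, r2, re, eps, eps_md, pair ...
    per_condition: pd.DataFrame
    summary: dict

    def to_json(self) -> str:
        import json

        return json.dumps(self.summary, indent=2)


def evaluate(
    model: PointNetRDF,
    samples: Sequence[TrainingSample],
    ground_truths: Mapping[str, RDFSet],
    normalizer: FeatureNormalizer,
) -> EvalReport:
    """Per-frame R^2 / epsilon / RE of the model against each condition's
    ground truth, plus the MD single-snapshot baseline on the same frames."""
    if not samples:
        raise ValueError("no evaluation samples")
    pairs = normalizer.pairs
    nb = normalizer.grid.n_bins
    rows = []
    per_cond_frames: dict[str, int] = {}
    for s in samples:
        truth = ground_truths[s.condition_id]
        ref = truth.concatenated()
        pred = np.maximum(
            forward(model, s.point_features, s.state_scalars), 0.0
        )
        frame_idx = per_cond_frames.setdefault(s.condition_id, 0)
        per_cond_frames[s.condition_id] += 1
        row = {
            "condition_id": s.condition_id,
            "frame": frame_idx,
            "r2": r2_score(pred, ref),
            "re": relative_error(pred, ref),
            "eps_model": rdf_error(pred, ref),
        }
        if s.snapshot is not None:
            md = np.concatenate(
                [
                    snapshot_rdf(s.snapshot, p, normalizer.grid).g
                    for p in pairs
                ]
            )
            row["eps_md"] = rdf_error(md, ref)
        for i, p in enumerate(pairs):
            seg = slice(i * nb, (i + 1) * nb)
            row[f"eps_model_{p[0]}-{p[1]}"] = rdf_error(pred[seg], ref[seg])
            if s.snapshot is not None:
                row[f"eps_md_{p[0]}-{p[1]}"] = rdf_error(md[seg], ref[seg])
        rows.append(row)
    frames = pd.DataFrame(rows)
    if (frames.groupby("condition_id").size() < 1).any():
        raise ValueError("a test condition has no frames")
    agg_cols = [c for c in frames.columns if c not in ("condition_id", "frame")]
    per_condition = frames.groupby("condition_id")[agg_cols].agg(["mean", "std"])
    summary = {
        "mean_r2": float(frames["r2"].mean()),
        "mu_re": float(frames["re"].mean()),
        "sigma_re": float(frames["re"].std(ddof=0)),
        "mean_eps_model": float(frames["eps_model"].mean()),
        "std_eps_model": float(frames["eps_model"].std(ddof=0)),
        "n_frames": int(len(frames)),
        "n_conditions": int(frames["condition_id"].nunique()),
    }
    if "eps_md" in frames:
        summary["mean_eps_md"] = float(frames["eps_md"].mean())
        summary["std_eps_md"] = float(frames["eps_md"].std(ddof=0))
        summary["eps_ratio_model_over_md"] = (
            summary["mean_eps_model"] / summary["mean_eps_md"]
        )
    return EvalReport(frames=frames, per_condition=per_condition, summary=summary)
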