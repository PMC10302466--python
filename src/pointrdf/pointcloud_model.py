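"""Permutation-invariant point-cloud regression network for RDF prediction.

Architecture: a shared multilayer perceptron applied to every atom
independently (positions plus optional velocity and one-hot species
features), a per-feature maximum over atoms (symmetric pooling, hence
exact permutation invariance), concatenation of the pooled global feature
with the two thermodynamic state scalars, and a fully connected head
emitting one fixed-length g(r) vector per species pair.

The network and its backward pass are implemented directly in numpy: the
models trained here are small (tens of thousands of parameters) and run
comfortably on one CPU core.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .datatypes import Condition, Snapshot
from .rdf_core import RadialGrid, RDFCurve, RDFSet, species_pairs

__all__ = [
    "ModelSpec",
    "FeatureNormalizer",
    "PointNetRDF",
    "encode_species",
    "build_model",
    "forward",
    "predict_rdfset",
    "save_checkpoint",
    "load_checkpoint",
]

logger = logging.getLogger(__name__)


def encode_species(species: np.ndarray, n_species: int) -> np.ndarray:
    """One-hot encode per-atom species labels.

    Column convention: dense label 0 maps to the *last* column, so in a
    two-species system species 0 encodes as ``[0, 1]`` and species 1 as
    ``[1, 0]``.
    """
    species = np.asarray(species, int)
    if species.size and (species.min() < 0 or species.max() >= n_species):
        raise ValueError(
            f"species labels must lie in [0, {n_species}), got range "
            f"[{species.min()}, {species.max()}]"
        )
    onehot = np.zeros((species.shape[0], n_species))
    onehot[np.arange(species.shape[0]), n_species - 1 - species] = 1.0
    return onehot


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of the point-cloud network."""

    n_point_features: int  # 3 + M
    n_output_pairs: int
    n_bins_per_pair: int
    pointwise_layer_widths: tuple[int, ...] = (64, 64, 128, 256)
    n_state_scalars: int = 2
    head_layer_widths: tuple[int, ...] = (256, 128)

    def __post_init__(self) -> None:
        if self.n_point_features < 3:
            raise ValueError("need at least the 3 position features")
        if min(self.pointwise_layer_widths, default=0) <= 0 or min(
            self.head_layer_widths, default=0
        ) <= 0:
            raise ValueError("all layer widths must be positive")
        if self.n_output_pairs < 1 or self.n_bins_per_pair < 2:
            raise ValueError("need >= 1 output pair and >= 2 bins")

    @property
    def output_dim(self) -> int:
        return self.n_output_pairs * self.n_bins_per_pair

    @property
    def layer_dims(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """(point-layer, head-layer) weight shapes implied by the spec."""
        pt = []
        prev = self.n_point_features
        for w in self.pointwise_layer_widths:
            pt.append((prev, w))
            prev = w
        head = []
        prev = prev + self.n_state_scalars
        for w in (*self.head_layer_widths, self.output_dim):
            head.append((prev, w))
            prev = w
        return pt, head

    def param_count(self) -> int:
        pt, head = self.layer_dims
        return sum(i * o + o for i, o in pt + head)


@dataclass
class FeatureNormalizer:
    """Maps raw snapshots and conditions to network inputs.

    Positions are divided by the box edge (fractional coordinates),
    velocities by the training-set root-mean-square component, and the
    (pressure-or-density, temperature) scalars are standardised with
    training-set mean and deviation.  One-hot species features are appended
    only for multi-species systems, matching the monatomic setup where atom
    types are omitted.
    """

    n_species: int
    include_velocities: bool = True
    v_rms: float = 1.0
    state_mean: np.ndarray = field(default_factory=lambda: np.zeros(2))
    state_std: np.ndarray = field(default_factory=lambda: np.ones(2))
    grid: RadialGrid | None = None

    @property
    def species_encoded(self) -> bool:
        return self.n_species > 1

    @property
    def n_point_features(self) -> int:
        return (
            3
            + (3 if self.include_velocities else 0)
            + (self.n_species if self.species_encoded else 0)
        )

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return species_pairs(self.n_species)

    def point_features(self, snapshot: Snapshot) -> np.ndarray:
        if snapshot.n_species > self.n_species:
            raise ValueError(
                f"snapshot has species up to {snapshot.n_species - 1}, "
                f"normalizer knows {self.n_species}"
            )
        blocks = [snapshot.positions / snapshot.box]
        if self.include_velocities:
            blocks.append(snapshot.velocities / self.v_rms)
        if self.species_encoded:
            blocks.append(encode_species(snapshot.species, self.n_species))
        return np.concatenate(blocks, axis=1)

    def state_scalars(self, condition: Condition) -> np.ndarray:
        return (condition.state_scalars - self.state_mean) / self.state_std


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class PointNetRDF:
    """The network: parameter arrays plus forward/backward passes."""

    def __init__(
        self,
        spec: ModelSpec,
        point_params: list[tuple[np.ndarray, np.ndarray]],
        head_params: list[tuple[np.ndarray, np.ndarray]],
    ):
        self.spec = spec
        self.point_params = point_params
        self.head_params = head_params

    # -- parameter plumbing -------------------------------------------------
    @property
    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for w, b in self.point_params + self.head_params:
            out.extend((w, b))
        return out

    def set_parameters(self, flat: Sequence[np.ndarray]) -> None:
        k = 0
        for layer in (self.point_params, self.head_params):
            for i, (w, b) in enumerate(layer):
                layer[i] = (flat[k].copy(), flat[k + 1].copy())
                k += 2

    def copy_parameters(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters]

    def param_count(self) -> int:
        return sum(p.size for p in self.parameters)

    # -- forward ------------------------------------------------------------
    def forward_batch(
        self, X: np.ndarray, S: np.ndarray, cache: bool = False
    ):
        """Batched forward pass.

        ``X`` is (B, N, F) point features, ``S`` (B, n_state_scalars).
        Returns (B, output_dim) predictions, plus the intermediate
        activations when ``cache`` is requested (for backprop).
        """
        B, N, _ = X.shape
        h = X
        point_acts = [h]
        for w, b in self.point_params:
            # flatten (B, N, f) -> (B*N, f) so the matmul is one BLAS call
            h = _relu(h.reshape(B * N, -1) @ w + b).reshape(B, N, -1)
            point_acts.append(h)
        pooled = h.max(axis=1)  # (B, D): symmetric, permutation invariant
        z = np.concatenate([pooled, S], axis=1)
        head_acts = [z]
        for w, b in self.head_params[:-1]:
            z = _relu(z @ w + b)
            head_acts.append(z)
        w, b = self.head_params[-1]
        out = z @ w + b
        if not cache:
            return out
        argmax = h.argmax(axis=1)  # (B, D) routing indices for pooling grad
        return out, (point_acts, argmax, head_acts)

    def backward_batch(self, caches, d_out: np.ndarray):
        """Gradients of a scalar loss w.r.t. every parameter, given the
        gradient w.r.t. the output.  Returns grads aligned with
        :attr:`parameters`."""
        point_acts, argmax, head_acts = caches
        B = d_out.shape[0]
        grads_head: list[tuple[np.ndarray, np.ndarray]] = []
        dz = d_out
        w, _ = self.head_params[-1]
        grads_head.append((head_acts[-1].T @ dz, dz.sum(axis=0)))
        dz = dz @ w.T
        for li in range(len(self.head_params) - 2, -1, -1):
            act_out = head_acts[li + 1]
            dz = dz * (act_out > 0)
            w, _ = self.head_params[li]
            grads_head.append((head_acts[li].T @ dz, dz.sum(axis=0)))
            dz = dz @ w.T
        grads_head.reverse()

        d_pool = dz[:, : argmax.shape[1]]  # gradient w.r.t. pooled feature
        h_last = point_acts[-1]
        dh = np.zeros_like(h_last)
        np.put_along_axis(dh, argmax[:, None, :], d_pool[:, None, :], axis=1)

        BN = dh.shape[0] * dh.shape[1]
        grads_point: list[tuple[np.ndarray, np.ndarray]] = []
        for li in range(len(self.point_params) - 1, -1, -1):
            act_out = point_acts[li + 1]
            dh = dh * (act_out > 0)
            w, _ = self.point_params[li]
            a_in = point_acts[li]
            dh2 = dh.reshape(BN, -1)
            gw = a_in.reshape(BN, -1).T @ dh2
            gb = dh2.sum(axis=0)
            grads_point.append((gw, gb))
            dh = (dh2 @ w.T).reshape(a_in.shape)
        grads_point.reverse()

        flat: list[np.ndarray] = []
        for gw, gb in grads_point + grads_head:
            flat.extend((gw, gb))
        return flat


def build_model(spec: ModelSpec, seed: int) -> PointNetRDF:
    """He-initialised network, deterministic from the seed."""
    rng = np.random.default_rng(seed)
    pt_dims, head_dims = spec.layer_dims
    def init(dims):
        out = []
        for fan_in, fan_out in dims:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            out.append((w, np.zeros(fan_out)))
        return out
    return PointNetRDF(spec, init(pt_dims), init(head_dims))


def forward(
    model: PointNetRDF, point_features: np.ndarray, state_scalars: np.ndarray
) -> np.ndarray:
    """Single-configuration forward pass: (N, 3+M) features and the two
    state scalars to one flat RDF vector.

    The point set is canonicalised first (duplicate rows collapsed, rows
    sorted): max pooling is exactly idempotent under duplicates, and the
    canonical order makes permutation and duplication invariance hold
    bitwise, not merely to rounding.
    """
    X = np.asarray(point_features, float)
    if X.ndim != 2 or X.shape[1] != model.spec.n_point_features:
        raise ValueError(
            f"expected (N, {model.spec.n_point_features}) features, "
            f"got {X.shape}"
        )
    if X.shape[0] < 1:
        raise ValueError("need at least one point")
    X = np.unique(X, axis=0)
    S = np.asarray(state_scalars, float).reshape(1, -1)
    if S.shape[1] != model.spec.n_state_scalars:
        raise ValueError("state scalar count mismatch")
    out = model.forward_batch(X[None, :, :], S)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite network output")
    return out[0]


def predict_rdfset(
    model: PointNetRDF,
    snapshot: Snapshot,
    condition: Condition,
    normalizer: FeatureNormalizer,
) -> RDFSet:
    """Predict every partial RDF of a configuration in one pass.

    Negative predicted g values are clamped to zero at this interface (with
    a logged count); the raw network output used during training is never
    clamped.
    """
    spec = model.spec
    if normalizer.grid is None:
        raise ValueError("normalizer carries no radial grid")
    out = forward(
        model,
        normalizer.point_features(snapshot),
        normalizer.state_scalars(condition),
    )
    negatives = int(np.sum(out < 0))
    if negatives:
        logger.debug("clamped %d negative predicted g values to 0", negatives)
    out = np.maximum(out, 0.0).reshape(spec.n_output_pairs, spec.n_bins_per_pair)
    pairs = normalizer.pairs
    if len(pairs) != spec.n_output_pairs:
        raise ValueError("normalizer pair count does not match the model spec")
    curves = {
        p: RDFCurve(pair=p, grid=normalizer.grid, g=out[i])
        for i, p in enumerate(pairs)
    }
    return RDFSet(condition=condition, curves=curves)


# ------------------------------------------------------------- checkpoints


def save_checkpoint(
    model: PointNetRDF, normalizer: FeatureNormalizer, path: str | Path
) -> None:
    """Parameter blob (.npz) plus a JSON sidecar with the spec, normaliser
    statistics, pair order and grid — enough to reload and predict."""
    path = Path(path)
    arrays = {f"p{i}": p for i, p in enumerate(model.parameters)}
    np.savez(path, **arrays)
    meta = {
        "spec": asdict(model.spec),
        "normalizer": {
            "n_species": normalizer.n_species,
            "include_velocities": normalizer.include_velocities,
            "v_rms": normalizer.v_rms,
            "state_mean": normalizer.state_mean.tolist(),
            "state_std": normalizer.state_std.tolist(),
            "grid": (
                {"r_max": normalizer.grid.r_max, "n_bins": normalizer.grid.n_bins}
                if normalizer.grid
                else None
            ),
        },
        "pairs": [list(p) for p in normalizer.pairs],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> tuple[PointNetRDF, FeatureNormalizer]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    spec_d = meta["spec"]
    spec_d["pointwise_layer_widths"] = tuple(spec_d["pointwise_layer_widths"])
    spec_d["head_layer_widths"] = tuple(spec_d["head_layer_widths"])
    spec = ModelSpec(**spec_d)
    model = build_model(spec, seed=0)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as blob:
        params = [blob[f"p{i}"] for i in range(len(blob.files))]
    model.set_parameters(params)
    nz = meta["normalizer"]
    normalizer = FeatureNormalizer(
        n_species=nz["n_species"],
        include_velocities=nz["include_velocities"],
        v_rms=nz["v_rms"],
        state_mean=np.array(nz["state_mean"]),
        state_std=np.array(nz["state_std"]),
        grid=RadialGrid(**nz["grid"]) if nz["grid"] else None,
    )
    return model, normalizer
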