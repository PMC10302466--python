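"""Radial distribution functions and the evaluation metrics built on them.

The ground truth for the surrogate is the temporal average of
single-snapshot RDFs over a whole trajectory; the error of either a
single-snapshot MD estimate or a network prediction against that average
is the per-bin mean squared deviation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._kernels import min_image_distances
from .datatypes import Condition, Snapshot, Trajectory

__all__ = [
    "RadialGrid",
    "RDFCurve",
    "RDFSet",
    "snapshot_rdf",
    "snapshot_rdfset",
    "average_rdf",
    "trajectory_rdfset",
    "rdf_error",
    "r2_score",
    "relative_error",
    "baseline_snapshot_errors",
    "write_rdfset_csv",
    "read_rdfset_csv",
    "species_pairs",
]


class GridError(ValueError):
    """The radial grid is incompatible with a snapshot's box."""


class EmptySelectionError(ValueError):
    """A requested species is absent from the snapshot."""


@dataclass(frozen=True)
class RadialGrid:
    """Uniform radial bins ``[k dr, (k+1) dr)`` with ``dr = r_max / n_bins``.

    Bins are half-open; a distance exactly equal to ``r_max`` is discarded.
    """

    r_max: float
    n_bins: int = 100

    def __post_init__(self) -> None:
        if not self.r_max > 0:
            raise ValueError("r_max must be > 0")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    @property
    def dr(self) -> float:
        return self.r_max / self.n_bins

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, self.r_max, self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def shell_volumes(self) -> np.ndarray:
        """Exact spherical-shell volume between consecutive bin edges."""
        e = self.edges
        return (4.0 / 3.0) * np.pi * (e[1:] ** 3 - e[:-1] ** 3)

    @classmethod
    def for_box(cls, box, r_max: float = 4.0, n_bins: int = 100) -> "RadialGrid":
        """Default grid: ``r_max = min(half smallest box edge, r_max)``."""
        return cls(min(0.5 * float(np.min(box)), r_max), n_bins)


@dataclass
class RDFCurve:
    """One pair-specific g(r) on a fixed radial grid."""

    pair: tuple[int, int]
    grid: RadialGrid
    g: np.ndarray
    n_frames_averaged: int = 1

    def __post_init__(self) -> None:
        self.pair = tuple(sorted(int(p) for p in self.pair))  # type: ignore[assignment]
        self.g = np.asarray(self.g, float)
        if self.g.shape != (self.grid.n_bins,):
            raise ValueError("g length must equal n_bins")
        if not np.all(np.isfinite(self.g)) or np.any(self.g < 0):
            raise ValueError("g must be finite and non-negative")
        if self.n_frames_averaged < 1:
            raise ValueError("n_frames_averaged must be >= 1")

    @property
    def r(self) -> np.ndarray:
        return self.grid.centers


def species_pairs(n_species: int) -> list[tuple[int, int]]:
    """All unordered species pairs (a <= b) in lexicographic order."""
    return [(a, b) for a in range(n_species) for b in range(a, n_species)]


@dataclass
class RDFSet:
    """Partial RDFs of one condition, keyed by species pair (a <= b)."""

    condition: Condition | None
    curves: dict[tuple[int, int], RDFCurve] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = {c.grid for c in self.curves.values()}
        if len(grids) > 1:
            raise ValueError("all curves of an RDFSet must share one grid")

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return sorted(self.curves)

    @property
    def grid(self) -> RadialGrid:
        return next(iter(self.curves.values())).grid

    def concatenated(self) -> np.ndarray:
        """Curves stacked in lexicographic pair order into one flat vector."""
        return np.concatenate([self.curves[p].g for p in self.pairs])

    def __getitem__(self, pair) -> RDFCurve:
        return self.curves[tuple(sorted(pair))]


def _pair_distances(snapshot: Snapshot, pair: tuple[int, int]) -> np.ndarray:
    a, b = sorted(pair)
    pos_a = snapshot.positions[snapshot.species == a]
    if a == b:
        if pos_a.shape[0] < 2:
            raise EmptySelectionError(f"fewer than 2 atoms of species {a}")
        return min_image_distances(pos_a, pos_a, snapshot.box, True)
    pos_b = snapshot.positions[snapshot.species == b]
    if pos_a.shape[0] == 0 or pos_b.shape[0] == 0:
        raise EmptySelectionError(f"species pair {(a, b)} not present")
    return min_image_distances(pos_a, pos_b, snapshot.box, False)


def snapshot_rdf(
    snapshot: Snapshot, pair: tuple[int, int], grid: RadialGrid
) -> RDFCurve:
    """Single-snapshot partial RDF for one species pair.

    Normalisation is the standard pair-correlation convention:
    ``g_k = C_k / (N_a N_b' V_shell_k / V_box)`` with ``C_k`` the number of
    ordered minimum-image pair distances in bin k, ``N_b' = N_b`` for a != b
    and ``N_a - 1`` for like pairs (self-pairs excluded).
    """
    a, b = sorted(pair)
    if not grid.r_max <= 0.5 * float(np.min(snapshot.box)) + 1e-12:
        raise GridError(
            f"grid r_max {grid.r_max} exceeds half the smallest box edge "
            f"{0.5 * float(np.min(snapshot.box)):.4f}"
        )
    dist = _pair_distances(snapshot, (a, b))
    counts, _ = np.histogram(dist[dist < grid.r_max], bins=grid.edges)
    n_a = int(np.sum(snapshot.species == a))
    if a == b:
        ordered = 2.0 * counts  # each unordered like pair counted twice
        n_ideal_pairs = n_a * (n_a - 1)
    else:
        ordered = counts.astype(float)
        n_ideal_pairs = n_a * int(np.sum(snapshot.species == b))
    v_box = float(np.prod(snapshot.box))
    ideal = n_ideal_pairs * grid.shell_volumes / v_box
    return RDFCurve(pair=(a, b), grid=grid, g=ordered / ideal)


def snapshot_rdfset(
    snapshot: Snapshot,
    grid: RadialGrid,
    pairs: Sequence[tuple[int, int]] | None = None,
) -> RDFSet:
    """All partial RDFs of one snapshot (default: every species pair)."""
    if pairs is None:
        pairs = species_pairs(snapshot.n_species)
    return RDFSet(
        condition=snapshot.condition,
        curves={tuple(sorted(p)): snapshot_rdf(snapshot, p, grid) for p in pairs},
    )


def average_rdf(curves: Sequence[RDFCurve]) -> RDFCurve:
    """Temporal average: per-bin arithmetic mean of single-snapshot RDFs."""
    if not curves:
        raise ValueError("cannot average an empty list of curves")
    first = curves[0]
    for c in curves[1:]:
        if c.pair != first.pair or c.grid != first.grid:
            raise ValueError("curves must share species pair and grid")
    g = np.mean([c.g for c in curves], axis=0)
    return RDFCurve(
        pair=first.pair,
        grid=first.grid,
        g=g,
        n_frames_averaged=sum(c.n_frames_averaged for c in curves),
    )


def trajectory_rdfset(
    trajectory: Trajectory,
    grid: RadialGrid,
    pairs: Sequence[tuple[int, int]] | None = None,
) -> RDFSet:
    """Ground-truth RDFs: the average over every frame of the trajectory."""
    if pairs is None:
        pairs = species_pairs(trajectory.snapshots[0].n_species)
    pairs = [tuple(sorted(p)) for p in pairs]
    per_pair: dict[tuple[int, int], list[RDFCurve]] = {p: [] for p in pairs}
    for snap in trajectory:
        for p in pairs:
            per_pair[p].append(snapshot_rdf(snap, p, grid))
    return RDFSet(
        condition=trajectory.condition,
        curves={p: average_rdf(cs) for p, cs in per_pair.items()},
    )


def _check_grids(g_pred: RDFCurve | np.ndarray, g_ref: RDFCurve | np.ndarray):
    if isinstance(g_pred, RDFCurve) and isinstance(g_ref, RDFCurve):
        if g_pred.grid != g_ref.grid:
            raise ValueError("curves live on different grids")
    a = g_pred.g if isinstance(g_pred, RDFCurve) else np.asarray(g_pred, float)
    b = g_ref.g if isinstance(g_ref, RDFCurve) else np.asarray(g_ref, float)
    if a.shape != b.shape:
        raise ValueError("curve lengths differ")
    return a, b


def rdf_error(g_pred, g_ref) -> float:
    """Mean squared deviation over bins; 0 iff the curves are identical."""
    a, b = _check_grids(g_pred, g_ref)
    return float(np.mean((a - b) ** 2))


def r2_score(g_pred, g_ref) -> float:
    """Coefficient of determination about the mean of the reference curve."""
    a, b = _check_grids(g_pred, g_ref)
    ss_tot = float(np.sum((b - b.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("reference curve is constant; R^2 undefined")
    ss_res = float(np.sum((a - b) ** 2))
    return 1.0 - ss_res / ss_tot


def relative_error(g_pred, g_ref) -> float:
    """L1 relative error: sum |pred - ref| / sum |ref|."""
    a, b = _check_grids(g_pred, g_ref)
    denom = float(np.sum(np.abs(b)))
    if denom == 0.0:
        raise ValueError("reference curve is identically zero")
    return float(np.sum(np.abs(a - b)) / denom)


def baseline_snapshot_errors(
    trajectory: Trajectory,
    grid: RadialGrid,
    pairs: Sequence[tuple[int, int]] | None = None,
    reference: RDFSet | None = None,
) -> pd.DataFrame:
    """Error of each single-snapshot MD estimate against the full-trajectory
    average — the direct-MD baseline the surrogate is compared with.

    Returns a tidy frame with columns ``frame, time, pair, error``; aggregate
    with :func:`summarize_errors` or ``df.groupby("pair")``.
    """
    if pairs is None:
        pairs = species_pairs(trajectory.snapshots[0].n_species)
    pairs = [tuple(sorted(p)) for p in pairs]
    if reference is None:
        reference = trajectory_rdfset(trajectory, grid, pairs)
    rows = []
    for i, snap in enumerate(trajectory):
        for p in pairs:
            err = rdf_error(snapshot_rdf(snap, p, grid), reference[p])
            rows.append({"frame": i, "time": snap.time, "pair": p, "error": err})
    return pd.DataFrame(rows)


def summarize_errors(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of the per-frame error for each pair."""
    return table.groupby("pair")["error"].agg(["mean", "std"]).fillna(0.0)


def write_rdfset_csv(rdfset: RDFSet, path: str | Path) -> None:
    """CSV with one ``r`` column and one g column per pair, plus a JSON
    metadata sidecar (grid, pair order, frames averaged)."""
    path = Path(path)
    data = {"r": rdfset.grid.centers}
    for p in rdfset.pairs:
        data[f"g_{p[0]}-{p[1]}"] = rdfset.curves[p].g
    pd.DataFrame(data).to_csv(path, index=False)
    meta = {
        "r_max": rdfset.grid.r_max,
        "n_bins": rdfset.grid.n_bins,
        "pairs": [list(p) for p in rdfset.pairs],
        "n_frames_averaged": {
            f"{p[0]}-{p[1]}": rdfset.curves[p].n_frames_averaged
            for p in rdfset.pairs
        },
        "condition": (
            {
                "temperature": rdfset.condition.temperature,
                "pressure_or_density": rdfset.condition.pressure_or_density,
                "condition_id": rdfset.condition.condition_id,
            }
            if rdfset.condition
            else None
        ),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2)
    )


def read_rdfset_csv(path: str | Path) -> RDFSet:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    grid = RadialGrid(meta["r_max"], meta["n_bins"])
    cond = None
    if meta.get("condition"):
        cond = Condition(**meta["condition"])
    curves = {}
    for p in meta["pairs"]:
        key = tuple(p)
        curves[key] = RDFCurve(
            pair=key,
            grid=grid,
            g=df[f"g_{p[0]}-{p[1]}"].to_numpy(),
            n_frames_averaged=meta["n_frames_averaged"][f"{p[0]}-{p[1]}"],
        )
    return RDFSet(condition=cond, curves=curves)
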