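"""Readers and writers for molecular configurations.

Three formats are supported end to end:

* LAMMPS text dump (``ITEM: TIMESTEP`` / ``NUMBER OF ATOMS`` /
  ``BOX BOUNDS pp pp pp`` / ``ATOMS id type x y z vx vy vz``);
* extended XYZ with ``Lattice`` and ``Properties`` comment fields;
* an HDF5 dataset archive holding a whole condition grid.

Every reader normalises into :class:`~pointrdf.datatypes.Snapshot` objects
(positions wrapped to ``[0, L)``, species re-indexed densely from 0, atoms
sorted by id) or fails loudly; silent coercion is forbidden.  Only
orthorhombic boxes are supported.

The dump format has no field for physical time, so the TIMESTEP record
stores the frame index; extended XYZ and the archive store exact times.
"""

from __future__ import annotations

import io
import json
import logging
import re
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import h5py
import numpy as np

from .datatypes import Condition, Snapshot, Trajectory, wrap_positions

__all__ = [
    "read_lammps_dump",
    "write_lammps_dump",
    "read_extxyz",
    "write_extxyz",
    "save_archive",
    "load_archive",
    "FormatError",
    "ArchiveVersionError",
]

logger = logging.getLogger(__name__)

ARCHIVE_VERSION = "1"

REQUIRED_COLUMNS = ("id", "type", "x", "y", "z")
VELOCITY_COLUMNS = ("vx", "vy", "vz")
IMAGE_COLUMNS = ("ix", "iy", "iz")


class FormatError(ValueError):
    """A file violates the supported dialect of its format."""


class ArchiveVersionError(FormatError):
    """Archive format version does not match this reader."""


def _open(stream, mode: str):
    if isinstance(stream, (str, Path)):
        return open(stream, mode), True
    return stream, False


# ---------------------------------------------------------------- LAMMPS dump


def _densify_species(raw_types: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Map file type labels to dense 0-based integers preserving numeric
    order; return the mapping for write-back."""
    labels = sorted(set(int(t) for t in raw_types))
    lookup = {lab: i for i, lab in enumerate(labels)}
    return np.array([lookup[int(t)] for t in raw_types]), labels


def read_lammps_dump(
    stream: str | Path | IO[str],
    column_map: Mapping[str, int] | None = None,
) -> Trajectory:
    """Parse a LAMMPS text dump into a trajectory.

    ``column_map`` (name -> 0-based column) overrides the assignment parsed
    from the ``ITEM: ATOMS`` header line.  Atoms are re-sorted by id; image
    flag columns are accepted and discarded.
    """
    fh, close = _open(stream, "r")
    try:
        frames: list[Snapshot] = []
        line = fh.readline()
        frame_no = 0
        while line:
            if not line.startswith("ITEM: TIMESTEP"):
                raise FormatError(f"frame {frame_no}: expected ITEM: TIMESTEP")
            timestep = int(fh.readline())
            item = fh.readline()
            if not item.startswith("ITEM: NUMBER OF ATOMS"):
                raise FormatError(f"frame {frame_no}: expected NUMBER OF ATOMS")
            n = int(fh.readline())
            bounds_header = fh.readline()
            if not bounds_header.startswith("ITEM: BOX BOUNDS"):
                raise FormatError(f"frame {frame_no}: expected BOX BOUNDS")
            if any(t in bounds_header for t in ("xy", "xz", "yz")):
                raise FormatError(
                    f"frame {frame_no}: triclinic boxes are not supported"
                )
            lo = np.empty(3)
            hi = np.empty(3)
            for ax in range(3):
                parts = fh.readline().split()
                if len(parts) != 2:
                    raise FormatError(
                        f"frame {frame_no}: triclinic boxes are not supported"
                    )
                lo[ax], hi[ax] = float(parts[0]), float(parts[1])
            atoms_header = fh.readline()
            if not atoms_header.startswith("ITEM: ATOMS"):
                raise FormatError(f"frame {frame_no}: expected ITEM: ATOMS")
            header_cols = atoms_header.split()[2:]
            cols = (
                dict(column_map)
                if column_map is not None
                else {name: i for i, name in enumerate(header_cols)}
            )
            missing = [c for c in REQUIRED_COLUMNS if c not in cols]
            if missing:
                raise FormatError(
                    f"frame {frame_no}: missing required columns {missing}"
                )
            if any(c in cols for c in IMAGE_COLUMNS):
                logger.info(
                    "frame %d: image flag columns present; discarded", frame_no
                )
            try:
                rows = np.loadtxt(
                    io.StringIO("".join(fh.readline() for _ in range(n))),
                    ndmin=2,
                )
            except ValueError as err:
                raise FormatError(
                    f"frame {frame_no}: malformed or missing atom rows ({err})"
                ) from err
            if rows.shape[0] != n:
                raise FormatError(f"frame {frame_no}: expected {n} atom rows")
            if frames and n != frames[0].n_atoms:
                raise FormatError(
                    f"frame {frame_no}: atom count {n} differs from first "
                    f"frame ({frames[0].n_atoms})"
                )
            order = np.argsort(rows[:, cols["id"]], kind="stable")
            rows = rows[order]
            box = hi - lo
            positions = wrap_positions(
                rows[:, [cols["x"], cols["y"], cols["z"]]] - lo, box
            )
            have_vel = all(c in cols for c in VELOCITY_COLUMNS)
            velocities = (
                rows[:, [cols["vx"], cols["vy"], cols["vz"]]]
                if have_vel
                else np.zeros((n, 3))
            )
            species, labels = _densify_species(rows[:, cols["type"]])
            frames.append(
                Snapshot(
                    positions=positions,
                    velocities=velocities,
                    species=species,
                    box=box,
                    time=float(timestep),
                    has_velocities=have_vel,
                ).validate()
            )
            frame_no += 1
            line = fh.readline()
        if not frames:
            raise FormatError("stream contains no complete frame")
        traj = Trajectory(
            condition=None,
            snapshots=frames,
            sample_interval=(
                float(frames[1].time - frames[0].time) if len(frames) > 1 else 1.0
            ),
            metadata={"original_type_labels": labels, "source_format": "lammps-dump"},
        )
        return traj.validate()
    finally:
        if close:
            fh.close()


def write_lammps_dump(
    trajectory: Trajectory,
    stream: str | Path | IO[str],
    precision: int = 10,
) -> None:
    """Write a trajectory as a LAMMPS text dump at the stated precision.

    Inverse of :func:`read_lammps_dump` for the supported dialect; the
    TIMESTEP record holds the frame index and type labels are written
    1-based (or with the original labels kept in trajectory metadata).
    """
    labels = trajectory.metadata.get("original_type_labels")
    fh, close = _open(stream, "w")
    fmt = f"%.{precision}g"
    try:
        for idx, snap in enumerate(trajectory):
            n = snap.n_atoms
            fh.write("ITEM: TIMESTEP\n%d\n" % idx)
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % n)
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for ax in range(3):
                fh.write(("0 " + fmt + "\n") % snap.box[ax])
            fh.write("ITEM: ATOMS id type x y z vx vy vz\n")
            for i in range(n):
                t = (
                    labels[snap.species[i]]
                    if labels is not None
                    else int(snap.species[i]) + 1
                )
                row = [fmt % v for v in (*snap.positions[i], *snap.velocities[i])]
                fh.write(f"{i + 1} {t} " + " ".join(row) + "\n")
    finally:
        if close:
            fh.close()


# ------------------------------------------------------------- extended XYZ


_KV_RE = re.compile(r'(\w+)=("([^"]*)"|(\S+))')


def _parse_extxyz_comment(comment: str) -> dict[str, str]:
    return {m.group(1): (m.group(3) if m.group(3) is not None else m.group(4))
            for m in _KV_RE.finditer(comment)}


def read_extxyz(stream: str | Path | IO[str]) -> Trajectory:
    """Read an extended-XYZ trajectory (``Lattice`` and ``Properties``
    comment fields required; velocities optional).

    Frames without velocity columns yield zero-velocity snapshots flagged
    ``has_velocities=False``.  Non-orthorhombic lattices are rejected.
    """
    fh, close = _open(stream, "r")
    try:
        frames: list[Snapshot] = []
        symbols_seen: list[str] = []
        frame_no = 0
        line = fh.readline()
        while line.strip():
            n = int(line)
            fields = _parse_extxyz_comment(fh.readline())
            if "Lattice" not in fields or "Properties" not in fields:
                raise FormatError(
                    f"frame {frame_no}: Lattice and Properties are required"
                )
            lat = np.array(fields["Lattice"].split(), float).reshape(3, 3)
            if not np.allclose(lat, np.diag(np.diag(lat))):
                raise FormatError(
                    f"frame {frame_no}: non-orthorhombic lattice rejected"
                )
            box = np.diag(lat).copy()
            props = fields["Properties"].split(":")
            names = props[0::3]
            counts = [int(c) for c in props[2::3]]
            col = 0
            spans: dict[str, slice] = {}
            for name, cnt in zip(names, counts):
                spans[name] = slice(col, col + cnt)
                col += cnt
            if "pos" not in spans or "species" not in spans:
                raise FormatError(
                    f"frame {frame_no}: species and pos properties required"
                )
            raw = [fh.readline().split() for _ in range(n)]
            if any(len(r) != col for r in raw):
                raise FormatError(f"frame {frame_no}: ragged atom rows")
            symbols = [r[spans["species"].start] for r in raw]
            uniq = sorted(set(symbols))
            species = np.array([uniq.index(s) for s in symbols])
            pos = np.array([[float(v) for v in r[spans["pos"]]] for r in raw])
            have_vel = "vel" in spans
            vel = (
                np.array([[float(v) for v in r[spans["vel"]]] for r in raw])
                if have_vel
                else np.zeros((n, 3))
            )
            frames.append(
                Snapshot(
                    positions=wrap_positions(pos, box),
                    velocities=vel,
                    species=species,
                    box=box,
                    time=float(fields.get("Time", frame_no)),
                    has_velocities=have_vel,
                ).validate()
            )
            symbols_seen = uniq
            frame_no += 1
            line = fh.readline()
        if not frames:
            raise FormatError("stream contains no complete frame")
        return Trajectory(
            condition=None,
            snapshots=frames,
            sample_interval=(
                float(frames[1].time - frames[0].time) if len(frames) > 1 else 1.0
            ),
            metadata={"species_symbols": symbols_seen, "source_format": "extxyz"},
        ).validate()
    finally:
        if close:
            fh.close()


def write_extxyz(
    trajectory: Trajectory,
    stream: str | Path | IO[str],
    precision: int = 10,
) -> None:
    """Write extended XYZ with Lattice, Properties and Time fields."""
    symbols = trajectory.metadata.get("species_symbols")
    fh, close = _open(stream, "w")
    fmt = f"%.{precision}g"
    try:
        for snap in trajectory:
            fh.write("%d\n" % snap.n_atoms)
            lat = " ".join(
                fmt % v for v in np.diag(snap.box).flatten()
            )
            fh.write(
                f'Lattice="{lat}" '
                "Properties=species:S:1:pos:R:3:vel:R:3 "
                f"Time={fmt % snap.time}\n"
            )
            for i in range(snap.n_atoms):
                sym = (
                    symbols[snap.species[i]]
                    if symbols is not None
                    else f"X{int(snap.species[i])}"
                )
                row = [fmt % v for v in (*snap.positions[i], *snap.velocities[i])]
                fh.write(sym + " " + " ".join(row) + "\n")
    finally:
        if close:
            fh.close()


# ------------------------------------------------------------- HDF5 archive


def save_archive(
    trajectories: Mapping[str, Trajectory] | Iterable[Trajectory],
    path: str | Path,
) -> None:
    """Save a condition grid losslessly to one HDF5 file.

    Layout: flat datasets ``<condition_id>/{positions,velocities,species,
    box,times}`` with condition metadata in attributes; root attributes
    carry the format version and unit tag.  Timestamp tracking is disabled
    so identical inputs produce byte-identical files.
    """
    if isinstance(trajectories, Mapping):
        items = list(trajectories.values())
    else:
        items = list(trajectories)
    with h5py.File(path, "w", track_order=False) as f:
        f.attrs["format_version"] = ARCHIVE_VERSION
        f.attrs["units"] = items[0].snapshots[0].units if items else "reduced"
        seen = set()
        for traj in items:
            traj.validate()
            cond = traj.condition
            cid = cond.condition_id if cond else f"traj{len(seen)}"
            if cid in seen:
                raise ValueError(f"duplicate condition_id {cid!r}")
            seen.add(cid)
            grp = f.create_group(cid)
            pos = np.stack([s.positions for s in traj])
            vel = np.stack([s.velocities for s in traj])
            for name, data in (
                ("positions", pos),
                ("velocities", vel),
                ("species", traj.snapshots[0].species),
                ("box", traj.snapshots[0].box),
                ("times", traj.times),
            ):
                grp.create_dataset(name, data=data, track_times=False)
            grp.attrs["sample_interval"] = traj.sample_interval
            if cond is not None:
                grp.attrs["temperature"] = cond.temperature
                grp.attrs["pressure_or_density"] = cond.pressure_or_density
                grp.attrs["condition_id"] = cond.condition_id
            if traj.metadata:
                grp.attrs["metadata_json"] = json.dumps(
                    traj.metadata, sort_keys=True
                )


def load_archive(path: str | Path) -> dict[str, Trajectory]:
    """Inverse of :func:`save_archive`; refuses version mismatches."""
    out: dict[str, Trajectory] = {}
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != ARCHIVE_VERSION:
            raise ArchiveVersionError(
                f"archive version {version!r} != supported {ARCHIVE_VERSION!r}"
            )
        for cid in sorted(f.keys()):
            grp = f[cid]
            cond = None
            if "condition_id" in grp.attrs:
                cond = Condition(
                    temperature=float(grp.attrs["temperature"]),
                    pressure_or_density=float(grp.attrs["pressure_or_density"]),
                    condition_id=str(grp.attrs["condition_id"]),
                )
            pos = grp["positions"][...]
            vel = grp["velocities"][...]
            species = grp["species"][...]
            box = grp["box"][...]
            times = grp["times"][...]
            snaps = [
                Snapshot(
                    positions=pos[i],
                    velocities=vel[i],
                    species=species,
                    box=box,
                    time=float(times[i]),
                    condition=cond,
                )
                for i in range(pos.shape[0])
            ]
            meta = (
                json.loads(grp.attrs["metadata_json"])
                if "metadata_json" in grp.attrs
                else {}
            )
            out[cid] = Trajectory(
                condition=cond,
                snapshots=snaps,
                sample_interval=float(grp.attrs["sample_interval"]),
                metadata=meta,
            ).validate()
    return out
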