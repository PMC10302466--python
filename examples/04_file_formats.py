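"""Write and read configurations in the supported text formats.

Round-trips a short trajectory through a LAMMPS text dump and extended
XYZ, and stores a whole condition grid in the HDF5 archive.
"""

import io
import tempfile
from pathlib import Path

import numpy as np

from pointrdf import Condition, LJParams
from pointrdf.md_engine import run_condition
from pointrdf.trajectory_io import (
    load_archive,
    read_extxyz,
    read_lammps_dump,
    save_archive,
    write_extxyz,
    write_lammps_dump,
)

condition = Condition(temperature=1.0, pressure_or_density=0.8,
                      condition_id="demo")
trajectory = run_condition(
    condition, LJParams.monatomic(),
    n_equil_steps=300, n_prod_steps=100, sample_interval=20,
    seed=3, n_atoms=150, dt=0.004,
)

dump = io.StringIO()
write_lammps_dump(trajectory, dump)
back = read_lammps_dump(io.StringIO(dump.getvalue()))
drift = max(
    float(np.abs(a.positions - b.positions).max())
    for a, b in zip(trajectory, back)
)
print(f"LAMMPS dump round trip: {len(back)} frames, "
      f"max coordinate drift {drift:.2e}")

xyz = io.StringIO()
write_extxyz(back, xyz)
again = read_extxyz(io.StringIO(xyz.getvalue()))
print(f"extended XYZ round trip: {len(again)} frames, "
      f"velocities preserved: {again[0].has_velocities}")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "grid.h5"
    save_archive({"demo": trajectory}, path)
    archive = load_archive(path)
    print(f"HDF5 archive: {len(archive)} condition(s), "
          f"{len(archive['demo'])} frames, lossless: "
          f"{np.array_equal(archive['demo'][0].positions, trajectory[0].positions)}")

# The drift reflects only the writer's decimal precision; the HDF5
# archive stores native floats and is exactly lossless.
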