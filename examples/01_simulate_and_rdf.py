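"""Simulate one Lennard-Jones liquid condition and compute its averaged RDF.

Runs a short constant-volume trajectory of 400 atoms at reduced density
0.8 and temperature 1.0, then averages the single-snapshot radial
distribution functions over all production frames.
"""

import numpy as np

from pointrdf import Condition, LJParams, RadialGrid, trajectory_rdfset
from pointrdf.md_engine import run_condition

condition = Condition(temperature=1.0, pressure_or_density=0.8,
                      condition_id="demo")
params = LJParams.monatomic()

trajectory = run_condition(
    condition, params,
    n_equil_steps=1500, n_prod_steps=2000, sample_interval=20,
    seed=1, n_atoms=400, dt=0.004,
)
print(f"sampled {len(trajectory)} frames of "
      f"{trajectory[0].n_atoms} atoms, box edge "
      f"{trajectory[0].box[0]:.3f} sigma")

grid = RadialGrid.for_box(trajectory[0].box, r_max=3.4)
rdf = trajectory_rdfset(trajectory, grid)[(0, 0)]
peak_bin = int(np.argmax(rdf.g))
print(f"first peak g = {rdf.g[peak_bin]:.3f} at r = {rdf.r[peak_bin]:.3f} sigma")
print(f"tail (last quarter of the grid) averages {rdf.g[75:].mean():.3f}")

# The first peak near 1.1 sigma and height ~2.6 are the signature of a
# dense LJ liquid's first coordination shell; the tail relaxing to 1 means
# the liquid is homogeneous beyond a few particle diameters.
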