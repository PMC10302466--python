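"""Numba-compiled inner loops: minimum-image Lennard-Jones forces.

The kernel is the plain O(N^2) pair double loop; system sizes here stay
below ~1500 atoms, where this is faster in practice than building neighbour
lists every few steps.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def lj_forces_energy(positions, species, box, epsilon, sigma, shift, cutoff):
    """Truncated-and-shifted LJ forces and potential energy.

    Returns ``(forces, potential, min_r2)`` where ``min_r2`` is the smallest
    squared pair distance encountered (for overlap detection by the caller).
    """
    n = positions.shape[0]
    forces = np.zeros((n, 3))
    potential = 0.0
    cut2 = cutoff * cutoff
    min_r2 = 1.0e300
    for i in range(n - 1):
        xi = positions[i, 0]
        yi = positions[i, 1]
        zi = positions[i, 2]
        si = species[i]
        for j in range(i + 1, n):
            dx = xi - positions[j, 0]
            dy = yi - positions[j, 1]
            dz = zi - positions[j, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < min_r2:
                min_r2 = r2
            if r2 < cut2:
                sj = species[j]
                eps = epsilon[si, sj]
                sig = sigma[si, sj]
                sr2 = sig * sig / r2
                sr6 = sr2 * sr2 * sr2
                sr12 = sr6 * sr6
                potential += 4.0 * eps * (sr12 - sr6) - shift[si, sj]
                fmag = 24.0 * eps * (2.0 * sr12 - sr6) / r2
                fx = fmag * dx
                fy = fmag * dy
                fz = fmag * dz
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[i, 2] += fz
                forces[j, 0] -= fx
                forces[j, 1] -= fy
                forces[j, 2] -= fz
    return forces, potential, min_r2


@njit(cache=True, fastmath=False)
def min_image_distances(pos_a, pos_b, box, same_set):
    """All minimum-image pair distances between two position sets.

    With ``same_set`` true only the i<j upper triangle is returned (each
    unordered pair once); otherwise the full cross product.
    """
    na = pos_a.shape[0]
    nb = pos_b.shape[0]
    if same_set:
        out = np.empty(na * (na - 1) // 2)
    else:
        out = np.empty(na * nb)
    k = 0
    for i in range(na):
        j0 = i + 1 if same_set else 0
        for j in range(j0, nb):
            dx = pos_a[i, 0] - pos_b[j, 0]
            dy = pos_a[i, 1] - pos_b[j, 1]
            dz = pos_a[i, 2] - pos_b[j, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            out[k] = np.sqrt(dx * dx + dy * dy + dz * dz)
            k += 1
    return out
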