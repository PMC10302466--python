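# Methods

## Problem

The radial distribution function g(r) of a homogeneous liquid is the
probability, relative to an ideal gas at the same density, of finding a
particle at distance r from a reference particle.  It converges only as
a time or ensemble average over many configurations.  `pointrdf` builds
and evaluates a surrogate that predicts the converged, time-averaged
g(r) of a thermodynamic condition from a *single* configuration sampled
early in a run, together with the condition's two state scalars.

## Data generation: the Lennard-Jones engine

The labelled data come from a bundled constant-volume MD engine rather
than an external simulation package, so every experiment is seeded and
self-contained.

* **Potential.**  Truncated-and-shifted Lennard-Jones,
  u(r) = 4ε[(σ/r)¹² − (σ/r)⁶] − u(r_c), pairwise under the minimum-image
  convention in an orthorhombic periodic box.  Default r_c = 2.5σ.
  Reduced units throughout: σ = ε = m = k_B = 1.  Two-species systems
  use Lorentz–Berthelot combining rules (arithmetic-mean σ,
  geometric-mean ε).
* **Integrator.**  Velocity Verlet; default time step 0.002τ (the
  experiments below use 0.004τ, comfortably stable for the thermostatted
  liquid).  Forces are an exact negative gradient of the pair energy;
  the test suite checks them against central finite differences and
  checks NVE total-energy drift (< 10⁻³ relative over 1000 steps).
* **Thermostat.**  Berendsen velocity rescaling,
  λ = √(1 + α(T₀/T − 1)) per step with dimensionless coupling
  α = dt/τ_T (default 0.1); α = 0 gives NVE.  Kinetic temperature is
  defined with 3(N−1) degrees of freedom since aggregate momentum is
  removed and conserved.
* **Ensemble.**  Constant volume: each condition is labelled by
  (number density, temperature) and the box edge follows from
  L = (N/ρ)^{1/3}.  A pressure label can be carried instead for external
  data; the network consumes two state scalars either way.  A barostat
  was deliberately left out: fixed volume keeps the RDF grid constant
  within a trajectory and removes a source of slow equilibration.
* **Initialisation.**  Atoms on a jittered cubic lattice with a
  worst-case pair separation ≥ 0.85σ, species assigned by
  largest-remainder apportionment and shuffled, velocities
  Maxwell–Boltzmann with the centre-of-mass momentum removed and the
  kinetic temperature rescaled exactly to target.
* **Neighbour search.**  A plain O(N²) double loop (numba-compiled).
  All systems studied here have N ≤ ~1400, where the double loop is
  faster in practice than rebuilding neighbour lists; a cell list was
  judged not worth its complexity at these sizes.

Determinism: every stochastic step draws from a generator seeded by a
deterministic fork of one master seed; identical inputs and seed give
bitwise-identical trajectories on one platform.

## RDF computation and metrics

* **Grid.**  Uniform half-open bins [k·Δr, (k+1)·Δr) with
  Δr = r_max/n_bins; a distance exactly r_max is discarded.  Defaults:
  r_max = min(half the smallest box edge, 4σ), 100 bins.  Half-open bins
  make the brute-force oracle comparison exact rather than approximate.
* **Normalisation.**  g_k = C_k / (N_a N′_b V_shell,k / V) with C_k the
  ordered pair-distance count, N′_b = N_b for unlike pairs and N_a − 1
  for like pairs (self-pairs excluded), and the exact spherical-shell
  volume per bin.  This makes the ideal-gas expectation exactly 1 in
  every bin, which the tests verify to three Poisson standard errors.
* **Ground truth.**  The per-bin arithmetic mean of single-snapshot
  curves over every frame of a trajectory.
* **Metrics.**  ε(g_pred, g_ref) is the per-bin mean squared error —
  consistent with the training loss, so the reported error is on the
  same scale the optimiser sees.  R² is the standard coefficient of
  determination about the reference mean (undefined and rejected for a
  constant reference).  RE is the L1 ratio Σ|Δg| / Σ|g_ref|.

## The network

Input is the (N, 3+M) per-atom feature matrix: positions (always),
optionally velocities, and for multi-species systems a one-hot species
block (the convention maps dense label 0 to the *last* column, so in a
two-species system species 0 encodes as [0, 1]).  Features are
normalised: positions to fractional coordinates, velocities by the
training-set RMS component, state scalars standardised by training-set
mean and deviation.  Normalisation statistics are fitted on training
conditions only and stored with the checkpoint.

Shared per-point dense layers (ReLU) lift each atom independently; a
per-feature maximum over atoms gives a global descriptor that is exactly
permutation invariant and idempotent under point duplication; the two
state scalars are concatenated to it mid-network; a fully connected head
(ReLU, linear output) emits the concatenated per-pair curves in
lexicographic pair order.  Default widths are (64, 64, 128, 256) shared
and (256, 128) head — a scaled-down variant of the original point-cloud
architecture; the desk-scale experiments use (32, 64) and (128, 128),
which train faster and lose nothing measurable at 10 training
conditions.  No learned alignment/transformer blocks are used.  Negative
predicted g values are clamped to zero at the prediction interface only,
never inside the loss.

In the single-configuration prediction path the point set is
canonicalised (duplicate rows collapsed, rows lexicographically sorted)
before the shared layers; max pooling makes this a semantic no-op, and
it turns permutation and duplication invariance into bitwise guarantees
independent of BLAS kernel-selection effects.

The network and its backward pass are written directly in numpy; at
these sizes (tens of thousands of parameters, hundreds of samples) a
full training run is minutes on one core, and a dependency on a deep
learning framework would dominate the install for no benefit.

## Training protocol

* Inputs are drawn only from the leading 20% of each trajectory
  (mirroring a "short run" of a long production); the target of every
  sample is the condition's full-trajectory average.
* Conditions are split 80/10/10 into train/validation/test; all frames
  of a condition inherit its subset, so no test condition ever leaks
  into training.  Subset sizes are round-half-up of the fractions with
  the remainder to training (400 → 320/40/40, 200 → 160/20/20,
  5 → 3/1/1).
* Adam, learning rate 10⁻³, default β/ε; MSE loss; early stopping on
  validation MSE with best-parameter restore.  `TrainConfig` defaults to
  batch size 32 and patience 20; the desk-scale experiments use batch 8
  (with ~300 samples, smaller batches give 4× more optimiser steps per
  epoch at identical cost and converge correspondingly faster),
  patience 100 and at most 700 epochs.

## Desk-scale experiments

`pointrdf.experiments` runs the full design in miniature:

* 12 conditions — temperatures (0.95, 1.05, 1.15, 1.25) × densities
  (0.75, 0.80, 0.85), a comfortably single-phase liquid/dense-fluid
  region of the LJ phase diagram;
* 400 atoms, 2000 equilibration steps, 150 production frames sampled
  every 20 steps (dt = 0.004τ), RDF grid r_max = 3.4σ, 100 bins;
* split (10, 1, 1) conditions; ~30 input snapshots per condition;
* the binary-mixture variant uses a mild 50/50 mixture
  (ε = (1, 0.9), σ = (1, 0.9), m = (1, 0.8), Lorentz–Berthelot cross
  terms) and predicts the three partial RDFs (0-0, 0-1, 1-1)
  simultaneously, at a reduced epoch budget.

These sizes were chosen so one full experiment (simulate, train,
evaluate) completes in a few minutes on a single CPU core.  The
evaluation reports, per held-out frame, R², RE and ε of the prediction
against the condition's reference curve, alongside the ε of the same
frame's direct histogram — the "single-snapshot MD" baseline.

## What the synthetic data do and do not show

The engine emulates the essential structure of the real problem: an
equilibrium liquid whose g(r) varies smoothly with (T, ρ), thermally
noisy single-snapshot estimates, and multi-species partial RDFs.  It
does not emulate molecular force fields (bonds, charges, rigid water),
barostatted density fluctuations, or the frame volumes of full-scale
datasets (hundreds of thousands of configurations versus hundreds
here).  Passing results therefore demonstrate the method's mechanics —
that a pooled point-cloud representation plus state scalars recovers the
averaged structure far better than the raw snapshot histogram — not
force-field-specific accuracy.  With ~10 training conditions the
held-out error is dominated by interpolation across the sparse (T, ρ)
grid, so error ratios are of order 10⁻¹–10⁻² rather than the 10⁻³
achievable with dense condition grids.

## Numerical choices and edge cases

* Ties in max pooling route gradients to the first maximal point;
  forward passes use `max` directly, so invariances are exact.
* The overlap guard (pair distance < 0.5σ) is skipped when ε = 0:
  free particles overlap harmlessly, and the ideal-gas limit is a
  normalisation oracle worth keeping runnable.
* Histogram bins are half-open; a same-position pair (r = 0) falls in
  bin 0; r = r_max is discarded.
* The LAMMPS dump format carries no physical time; the TIMESTEP record
  stores the frame index, and readers label frames 0, 1, 2, …  Extended
  XYZ and the HDF5 archive store exact times.  Files without velocity
  columns load as flagged zero-velocity snapshots.
* HDF5 archives disable timestamp tracking so identical inputs produce
  byte-identical files.

## Known limitations

* NVT only; pressure enters as a label, never as a controlled variable.
* Orthorhombic boxes; constant N and species per trajectory.
* The surrogate does not transfer across species sets or particle
  numbers other than through the permutation-invariant pooling; a model
  trained on one system must be retrained for another.
* Single-platform bitwise reproducibility only; across BLAS builds,
  results agree to rounding.
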