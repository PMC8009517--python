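# Methods

This note documents the models implemented in `nanospec`, their assumptions,
the defaults and units, the synthetic-data generators used for testing, and
the numerical choices made where the design was genuinely open.

## Units

Mechanics is carried in Å, ps, amu; energies cross the interface in kJ/mol
(1 amu·Å²/ps² = 0.01 kJ/mol).  Time steps are accepted in fs.  The Coulomb
constant is pinned to 1389.35457644382 kJ·Å/(mol·e²) so energies are
bit-stable across platforms.  The perturbed-matrix layer works entirely in
Hartree atomic units (hartree, bohr, e); converters live in
`nanospec.units`.

## Rigid-body dynamics

A molecule is split into center-of-mass (COM) translation, propagated with
standard velocity Verlet, and rotation about the principal axes, represented
by a unit quaternion Q mapping the molecular frame (MF) to the laboratory
frame (LF).  Quaternions avoid the singularities of Euler angles.  The
convention is Hamilton product, scalar-first storage, v_LF = Q v_MF Q*, with
w ≥ 0 canonicalization on matrix→quaternion conversion (stable largest-pivot
extraction).

One rotational step:

1. rotate L and T into MF; half-step the MF angular momentum with Euler's
   equation L̇ = T − ω×L, and the LF angular momentum with L += (Δt/2)T;
2. solve the implicit half-step quaternion equation
   Q(t+Δt/2) = Q(t) + (Δt/2)·½Q(t+Δt/2)⊗(0, ω(t+Δt/2)) by fixed-point
   iteration, where ω(t+Δt/2) comes from rotating the half-step LF angular
   momentum by the current quaternion estimate; the Euler half-step supplies
   the initial guess; iteration stops when |Q⁽ᵏ⁾ − Q⁽ᵏ⁻¹⁾| < ϵ;
3. Q(t+Δt) = Q(t) + Δt·Q̇(half), renormalized; a norm deviation larger than
   the instability threshold (default 0.1) aborts the run as unstable;
4. after new forces/torques, the second velocity-Verlet half-step updates
   v_COM and L^LF.

ϵ defaults to 1e-9; the high-accuracy diagnostics regime uses 1e-13.  Both
are test points.  The per-step iteration diagnostic is the maximum over
fragments (the fragments iterate jointly, so the joint convergence count is
that maximum), time-averaged when reported.

Observed behavior on a ~100-molecule acetonitrile droplet at 300 K
(tolerance 1e-13): on average ~5 iterations at δt = 1 fs and ~7–9 at 4 fs;
total-energy deviation scales as Δt² (≈2×10⁻⁶ relative at 0.5 fs over a
300 fs window).  Single-step reversibility is exact to machine precision and
|L| of a torque-free rotor is conserved to 1e-12 relative.

Flexible fragments use velocity Verlet plus RATTLE: the position stage
iteratively enforces each bond length on the advanced coordinates (updating
the half-step velocities consistently), the velocity stage projects the
final velocities onto the constraint manifold (r_ij·v_ij = 0).  With an
empty constraint list the path is bit-identical to plain velocity Verlet.
Intra-fragment nonbonded interactions are excluded throughout: rigid
geometries never change, and solute intramolecular force fields beyond
constraints are out of scope.

Confinement ("rough wall"): after each NVT step, any fragment whose COM lies
beyond the boundary radius receives a fresh Maxwell COM velocity at the
reference temperature with its radial component forced strictly inward (the
tangential Gaussian components are kept), and a fresh Maxwell angular
momentum.  The Berendsen thermostat rescales all velocities and angular
momenta by √(1 + (Δt/τ)(T₀/T − 1)); τ defaults to 0.1 ps.  Operator order
within a step: full integration step, then wall, then thermostat.

Initial momenta are Gaussian draws scaled exactly so the translational and
rotational kinetic energies each equal (n_dof/2)k_BT after the net linear
momentum is removed; two seeds give different momenta with identical
energies.

A crude displacement-capped rigid-body steepest descent
(`minimize_droplet`) relieves packing overlaps before equilibration; it is a
pre-equilibration tool, not a minimizer of record.

## Force field

Pairwise Lennard-Jones 12-6 plus Coulomb between atoms of different
fragments, Lorentz–Berthelot combining rules, no cutoff by default (droplets
are finite); a switched cutoff is available for speed.  Forces are analytic
derivatives (verified against central differences at 1e-6 relative).  A
numba-compiled pair loop is used when numba is importable, with a
numerically equivalent numpy fallback (agreement ~1e-12 relative).

The bundled six-site rigid acetonitrile parameter set
(`data/acetonitrile_synthetic_ff.yaml`) is a **synthetic stand-in**:
net-neutral charges giving a ≈4.1 D axial dipole, AMBER-like LJ radii and a
standard gas-phase geometry.  It is physically sensible but not a published,
validated force field, and quantitative droplet observables computed with it
(cohesive energy, absolute energy-fluctuation amplitudes) should be read
accordingly.

## Boundary mean field

U_vW(r) = Σᵢ λᵢ exp(−(r−rᵢ)²/2σ²) over Ng concentric shells (defaults:
Ng = 81 shells of 0.25 Å; σ equals the shell width, which is the natural
resolution scale and is configurable).  The term acts on fragment COMs; its
energy and exact radial derivative enter the total energy and COM forces.
An electrostatic continuum term can be plugged in through a hook that
defaults to zero (continuum electrostatics is outside this package's scope).

Density feedback: at fixed intervals the per-shell COM density (mol/L) is
compared with the bulk target; shells above the +0.25% band get +step
(more repulsive), shells below the −0.25% band get −step.  The band is read
as [0.9975ρ, 1.0025ρ].  The default step is 0.01 kJ/mol with optional
halving when a shell's update direction flips.  Full-scale optimizations
converge slowly with a fixed small step (tens of ns of sampling); the
desk-scale runs in the test suite instead use a larger starting step with a
deterministic geometric decay (step_decay ≈ 0.96 per epoch) and the flip
heuristic disabled, which reaches a flat profile within ~10⁵ steps on a
72-particle reduced-units LJ droplet.  On that system (σ = 1 Å,
ε = 1 kJ/mol, kT = 1.5ε, wall radius 3σ, equal-volume verdict shells) the
optimized field brings every interior shell within ±2% of the bulk density
while the unoptimized droplet shows up to ±30% near-wall structure.

Before fitting, the profile is truncated: the innermost contiguous region
with |U| < 0.1 kJ/mol is dropped (absolute value — the sign convention of a
one-sided threshold is otherwise ambiguous), keeping the boundary side.

Polynomial compression: for each degree 0..10 a ridge regression on the
Vandermonde design (normal equations; the intercept is penalized like every
other coefficient so that shrinkage → 0 reproduces least squares to machine
precision) is fitted; the shrinkage factor is optimized per degree by a
real-coded genetic algorithm on log₁₀α (population 50, mutation rate 0.3,
crossover rate 0.5, 500 iterations, tournament selection, elitist
replacement).  Because the search space is one-dimensional, a deterministic
log-grid search is provided as an independent cross-check.  The winning
degree minimizes test RMSE (R² gives the same ordering), ties to the lower
degree; when no explicit test set is supplied, even-index points train and
odd-index points test, mimicking profiles sampled on a regular grid (fits
use ~50 points at 0.2 Å resolution).  Coefficient tables for acetonitrile
(degree 4) and methanol (degree 5) ship as text files; U(0) = a₀ by
construction.

## Conformational clustering

Torsion angles (IUPAC sign convention, (−180°, 180°]) are computed from four
atom positions by the atan2 cross-product formula.  Chemically equivalent
rotor orientations are collapsed by a user-declared per-dihedral symmetry
divisor (e.g. 2-fold for a phenyl ring) before analysis.

Dihedral PCA lifts d angles to 2d features (sin, cos), removing the
periodicity artifact, then eigendecomposes the covariance.  The retained
component count is the smallest m whose cumulative explained variance
reaches the threshold (default 0.90; 0.99 reproduces the "first ten
components" regime — both are test points).  Total variance below 1e-14 is
treated as a constant trajectory (zero retained components, warning).

PAM runs on the retained coordinates under the Chebyshev (L∞) distance:
deterministic greedy BUILD (no RNG — clustering is reproducible by
construction) followed by vectorized best-improvement SWAP passes until no
swap lowers the total within-cluster distance.  WSS is reported as the sum
of squared member–medoid distances.  Silhouette uses the same Chebyshev
matrix; the Dunn index is min inter-cluster point distance over max
intra-cluster diameter.  The consensus k over k = 2..20 is the mode of
{argmax SI, argmax DI, WSS elbow}, where the elbow is formalized as the
argmax of the discrete second difference of WSS(k); all ties resolve toward
smaller k (three distinct votes therefore pick the smallest).  Cluster
weights are member counts in percent; Cartesian diagnostics use Kabsch
(SVD, reflection-corrected) RMSD with an optional non-hydrogen mask.

## Perturbed matrix method

Inputs per quantum center (QC): N unperturbed state energies (ascending),
the full symmetric N×N matrix of dipole/transition-dipole 3-vectors,
per-state atomic charges summing to a common net charge, and the QC
geometry — all in atomic units (N = 11 states is the typical working set).
The environment is point charges; V and E are bare Coulomb sums.

Two expansion modes behind one switch:

* **atom-based** (default): H_ii = ε⁰ᵢ + Σₐ qₐ⁽ⁱ⁾V(rₐ) with per-state
  atomic charges; H_ij = −E(r_c)·μ_ij.
* **qc-center**: H_ii = ε⁰ᵢ − E(r_c)·μ_ii + q_net V(r_c); H_ij as above.

r_c defaults to the QC center of mass.  The off-diagonal coupling through
transition dipoles and the field at the expansion center is an explicit
modeling choice, isolated in `build_perturbed_hamiltonian`, chosen because
the coupling operator's dipole term is the leading multipole; each term is
independently testable.  Diagonalization (symmetric eigensolver) yields
ascending perturbed energies; eigenvector signs are fixed by making the
largest-magnitude component positive — a convention that never touches the
energies.  Perturbed ground-state transition dipoles are
μ̃₀ₖ = Σ_ij c_i0 μ_ij c_jk.  For a weak distant charge the perturbed
energies match first-order perturbation theory to O(perturbation²), and a
neutral environment at infinity restores the unperturbed spectrum exactly.

Reference selection: the frame whose QC-center field is closest (Euclidean)
to the trajectory mean, first index on ties.  Collective frames concatenate
n snapshots with every charge scaled by 1/n (n = 30 in the standard
protocol), so their potential is exactly the snapshot mean.

## Spectra

f = (2/3)ΔE|μ|² (atomic units).  Broadening is Gaussian **on the energy
axis** (σ in au of frequency, default 0.0008; broadening in wavelength would
distort band shapes), area-normalized per stick, frame-averaged within a
cluster, then population-weighted across clusters (a convex combination).
The ε scale uses f = 4.319×10⁻⁹ mol·L⁻¹·cm² ∫ε dν̃; this conversion
constant is a single named constant with a unit test.  Because the source
workflow does not state its ε-from-f convention, absolute ε_max values carry
that convention caveat.  λ_max, ε_max and FWHM are read off the grid with
linear interpolation at half height.

## Synthetic data generators

All generators are seed-deterministic; one global seed fans out to
independent per-stage child seeds via `SeedSequence.spawn` (all below 2³¹).

* `pack_droplet`: uniform COMs in a sphere, uniform SO(3) orientations,
  rejection on a minimum inter-fragment atom separation.  Emulates packed
  solvent droplets; it does not produce equilibrated liquid structure, hence
  the minimize → NVT-equilibrate protocol before production.
* `gen_dihedral_trajectory`: von Mises mixture over declared basins with
  declared weights; returns true labels for recovery tests.  Emulates
  multi-basin torsional sampling but has no kinetics (frames are i.i.d.), so
  passing clustering tests demonstrates geometric recovery, not
  time-correlation handling.
* `gen_toy_qc_data`: ascending energies with hartree-scale gaps, symmetric
  random dipole matrix, per-state charges summing exactly to the net charge.
  Valid by construction against every QC-data invariant; it carries no
  chemistry, so PMM tests verify the linear algebra and perturbation
  structure, not spectroscopic realism.

## Problem sizes used in the test and acceptance runs

Chosen once as representative desk-scale analogues of the full-scale study
conditions: droplet runs use ~100 six-site solvent molecules (packing radius
15 Å, wall 13.5 Å, 300 K, 3 ps equilibration; 10 ps NVE for iteration
diagnostics, 300 fs windows for energy-deviation scaling); the mean-field
analogue uses 72 reduced-units LJ particles (wall 3σ, kT = 1.5ε, 80 epochs
× 1250 steps of optimization, 32 ps production); clustering uses 1000 frames
of six dihedrals at κ = 50.

## Known limitations

* The energy-deviation *magnitude* at large time steps depends on the
  force-field stiffness; with the synthetic acetonitrile stand-in the peak
  relative total-energy deviation at δt = 4 fs over 300 fs is ≈1×10⁻⁴
  (Δt²-consistent with ≈2×10⁻⁶ at 0.5 fs), dominated by bounded
  Lennard-Jones collision oscillations rather than secular drift.
* Continuum electrostatics (the reaction-field term of the boundary),
  polarizable/fluctuating-charge force fields, vibronic band shapes and the
  electronic-structure calculations themselves are out of scope; the latter
  are consumed as data.
* PAM is O(k·n²) per swap pass; trajectories beyond ~10⁴ frames should be
  subsampled before clustering.
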