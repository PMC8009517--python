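# nanospec

Electronic absorption spectra of chromophores dissolved in explicit-solvent
**nanodroplets**, computed by an integrated classical/quantum workflow:

1. **Rigid-body molecular dynamics under nonperiodic boundary conditions** —
   solvent molecules are rigid fragments whose orientations are propagated by
   a quaternion rotational velocity-Verlet integrator (fixed-point solve of
   the quaternion equation of motion at the half step), with RATTLE bond
   constraints for flexible solutes, a Berendsen thermostat, and a "rough
   wall" spherical boundary that resamples the velocity and angular momentum
   of any fragment that steps outside the droplet.
2. **Boundary mean-field optimization** — a radial potential
   U_vW(r) = Σᵢ λᵢ G(r − rᵢ; σ) built from Gaussian shells is tuned by
   density feedback until the droplet's radial density matches the bulk
   target, then truncated and compressed into a polynomial
   U_vW(r) = Σₖ aₖ rᵏ by ridge regression with a genetic-algorithm-tuned
   shrinkage factor and learning-curve degree selection.
3. **Conformational clustering** — solute torsions θ are lifted to
   (sin θ, cos θ) (dihedral PCA), frames are clustered by partition around
   medoids (PAM) under the Chebyshev (L∞) distance, and the cluster count k
   is chosen by the consensus of the WSS elbow, the maximum Silhouette score
   and the maximum Dunn index.
4. **Perturbed matrix method (PMM)** — for each cluster, the environment's
   electrostatics perturb a precomputed set of unperturbed electronic states:
   H_ii = ε⁰ᵢ + Σₐ qₐ⁽ⁱ⁾ V(rₐ), H_ij = −E(r_c)·μ_ij (atom-based expansion;
   a QC-center expansion is available behind the same switch).  Reference
   environments can be single frames selected by electric-field closeness to
   the trajectory mean, or collective frames of n snapshots with charges
   scaled by 1/n.
5. **Spectra** — oscillator strengths f = (2/3)ΔE|μ|² are broadened by
   Gaussians on the energy axis (σ = 0.0008 au by default), frame-averaged,
   population-weighted over clusters, and reported as ε(λ) in M⁻¹cm⁻¹ with
   λ_max, ε_max and FWHM.

The electronic-structure inputs (state energies, the full dipole/transition-
dipole matrix, per-state atomic charges) are **consumed**, not computed: they
come from external TD-DFT/electrostatic-embedding calculations, or from the
bundled synthetic generator for testing.

## Worked example

Cluster a synthetic six-dihedral trajectory whose four conformer basins are
centered at the tabulated centroid angles with weights 20/21/37/22 %:

```python
import numpy as np
from nanospec import clustmd, fixio

centroids = np.array([[-163, -71, -177,  71,  -80,  2],
                      [-119, -65,    0, -57,  -96,  6],
                      [-116, -61,  177, -63, -103,  4],
                      [-156, -66,    9,  68,  -75, -3]], float)
series, _ = fixio.gen_dihedral_trajectory(centroids, [20, 21, 37, 22],
                                          kappa=50.0, n_frames=1000, seed=1)
model, coords = clustmd.dpca_fit_transform(series, variance_threshold=0.90)
curves, k = clustmd.select_k(coords, range(2, 21))
weights = clustmd.pam_cluster(coords, k).weights_percent()
print(k, np.round(np.sort(weights), 1))
```

prints

```
4 [18.8 23.5 23.5 34.2]
```

— the consensus of the three validation criteria lands on k = 4 clusters, and
the recovered statistical weights (here sorted) match the generating mixture
within binomial counting error at 1000 frames.

A droplet simulation from the shell (using the bundled six-site rigid
acetonitrile stand-in parameters):

```bash
nanospec simulate --config src/nanospec/data/acetonitrile_synthetic_ff.yaml \
    --n-molecules 50 --radius 11 --ensemble NVT --wall-radius 12 \
    --n-steps 2000 --stride 500 --seed 1
```

writes `trajectory.xyz` (frame comments carry time and total energy) and
`diagnostics.tsv` with per-step kinetic/potential energies, temperature and
the quaternion fixed-point iteration count.  Other subcommands:
`optimize-mf`, `cluster`, `pmm`, `spectrum`, `fixtures` (see `--help`).

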