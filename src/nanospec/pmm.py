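"""Perturbed matrix method (PMM) for environment-tuned electronic states.

The electronic Hamiltonian of the quantum center (QC) is expanded on its N
unperturbed eigenstates and perturbed by the electrostatics of the classical
environment.  Two expansion modes are provided:

* ``qc-center``: the perturbing field is expanded around a single reference
  point r_c (the QC center of mass by default):
  H_ii = ε⁰_i − E(r_c)·μ_ii + q_net·V(r_c),  H_ij = −E(r_c)·μ_ij.
* ``atom``: the diagonal uses per-state atomic charges in the potential at
  each QC atom, H_ii = ε⁰_i + Σ_a q_a^(i) V(r_a), while the off-diagonal
  coupling keeps the transition-dipole form −E(r_c)·μ_ij.

Diagonalizing the perturbed matrix gives instantaneous perturbed energies and
(via the eigenvector rotation of the dipole matrix) perturbed transition
dipoles for every frame of a trajectory.  Collective "averaged environment"
frames concatenate n snapshots with charges scaled by 1/n.

Everything in this module is in Hartree atomic units (energies hartree,
lengths bohr, charges e, dipoles e·bohr).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "UnperturbedQCData",
    "EnvironmentFrame",
    "PerturbedStates",
    "env_potential_field",
    "build_perturbed_hamiltonian",
    "diagonalize_perturbed",
    "select_reference_frame",
    "build_collective_frame",
    "pmm_pipeline",
]

#: minimum point-charge separation (bohr) before the Coulomb sum is singular
_MIN_SEP = 1e-6


@dataclass
class UnperturbedQCData:
    """Unperturbed electronic structure of the quantum center.

    ``energies`` are the N state energies (hartree, ascending);
    ``dipoles`` the full N×N matrix of permanent/transition dipole 3-vectors
    (symmetric in the state indices); ``charges`` the per-state atomic
    partial charges (N, n_atoms), each state summing to the same net charge;
    ``atom_positions`` the QC geometry in bohr.
    """

    energies: np.ndarray          # (N,)
    dipoles: np.ndarray           # (N, N, 3)
    charges: np.ndarray           # (N, n_atoms)
    atom_positions: np.ndarray    # (n_atoms, 3)
    masses: np.ndarray | None = None  # amu, for the COM expansion center
    expansion_center: np.ndarray | None = None

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.dipoles = np.asarray(self.dipoles, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.atom_positions = np.asarray(self.atom_positions, dtype=float)
        n = len(self.energies)
        if np.any(np.diff(self.energies) < 0):
            raise ValueError("state energies must be ascending")
        if self.dipoles.shape != (n, n, 3):
            raise ValueError("dipoles must be (N, N, 3)")
        if not np.allclose(self.dipoles, np.swapaxes(self.dipoles, 0, 1), atol=1e-10):
            raise ValueError("dipole matrix must be symmetric in the state indices")
        if self.charges.shape[0] != n or self.charges.shape[1] != len(self.atom_positions):
            raise ValueError("charges must be (N, n_atoms)")
        nets = self.charges.sum(axis=1)
        if np.any(np.abs(nets - nets[0]) > 1e-6):
            raise ValueError("per-state charges must sum to the same net charge")
        if self.expansion_center is None:
            if self.masses is not None:
                m = np.asarray(self.masses, dtype=float)
                self.expansion_center = m @ self.atom_positions / m.sum()
            else:
                self.expansion_center = self.atom_positions.mean(axis=0)
        self.expansion_center = np.asarray(self.expansion_center, dtype=float)

    @property
    def n_states(self) -> int:
        return len(self.energies)

    @property
    def net_charge(self) -> float:
        return float(self.charges[0].sum())


@dataclass
class EnvironmentFrame:
    """Classical point-charge environment (charges e, positions bohr)."""

    charges: np.ndarray
    positions: np.ndarray
    frame_id: int | None = None

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.charges), 3):
            raise ValueError("positions must be (n_charges, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite environment positions")


@dataclass
class PerturbedStates:
    """Eigen-solution of one perturbed Hamiltonian."""

    energies: np.ndarray            # (N,) hartree, ascending
    eigenvectors: np.ndarray        # (N, N), columns = perturbed states
    transition_dipoles: np.ndarray  # (N, 3): ground → state k, perturbed basis
    frame_id: int | None = None

    @property
    def excitation_energies(self) -> np.ndarray:
        return self.energies[1:] - self.energies[0]


def env_potential_field(
    frame: EnvironmentFrame, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Electrostatic potential and field of the environment at given points.

    Atomic units: V(p) = Σ_s q_s/|p−r_s| (hartree/e) and
    E(p) = Σ_s q_s (p−r_s)/|p−r_s|³ (hartree/(e·bohr)).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(frame.charges) == 0:
        return np.zeros(len(points)), np.zeros((len(points), 3))
    dr = points[:, None, :] - frame.positions[None, :, :]
    r = np.linalg.norm(dr, axis=-1)
    if r.min() < _MIN_SEP:
        raise ValueError("environment charge (nearly) coincides with an evaluation point")
    v = (frame.charges / r).sum(axis=1)
    e = np.einsum("s,psi->pi", frame.charges, dr / r[..., None] ** 3)
    return v, e


def build_perturbed_hamiltonian(
    qc: UnperturbedQCData,
    frame: EnvironmentFrame,
    expansion: str = "atom",
) -> np.ndarray:
    """Assemble the N×N perturbed Hamiltonian (hartree), exactly symmetric."""
    n = qc.n_states
    center = qc.expansion_center
    if len(frame.charges) == 0:
        return np.diag(qc.energies)
    v_c, e_c = env_potential_field(frame, center[None, :])
    e_c = e_c[0]
    # off-diagonal coupling through transition dipoles and the field at r_c
    h = -np.einsum("ijx,x->ij", qc.dipoles, e_c)
    if expansion == "atom":
        v_atoms, _ = env_potential_field(frame, qc.atom_positions)
        diag = qc.energies + qc.charges @ v_atoms
    elif expansion == "qc-center":
        mu_ii = np.einsum("iix->ix", qc.dipoles)
        diag = qc.energies - mu_ii @ e_c + qc.net_charge * v_c[0]
    else:
        raise ValueError("expansion must be 'atom' or 'qc-center'")
    h[np.diag_indices(n)] = diag
    return 0.5 * (h + h.T)


def diagonalize_perturbed(
    h: np.ndarray, qc: UnperturbedQCData, frame_id: int | None = None
) -> PerturbedStates:
    """Eigen-solve the perturbed Hamiltonian and rotate the dipole matrix.

    Eigenvalues ascend; each eigenvector's sign is fixed by making its
    largest-magnitude component positive (a deterministic convention that
    never affects energies).  Perturbed ground→k transition dipoles are
    μ̃_0k = Σ_ij c_i0 μ_ij c_jk.
    """
    h = np.asarray(h, dtype=float)
    if not np.allclose(h, h.T, atol=1e-12):
        raise ValueError("Hamiltonian must be symmetric")
    evals, evecs = np.linalg.eigh(h)
    pivot = np.argmax(np.abs(evecs), axis=0)
    signs = np.sign(evecs[pivot, np.arange(len(evals))])
    signs[signs == 0] = 1.0
    evecs = evecs * signs
    trans = np.einsum("i,ijx,jk->kx", evecs[:, 0], qc.dipoles, evecs)
    return PerturbedStates(evals, evecs, trans, frame_id=frame_id)


def select_reference_frame(fields: np.ndarray) -> int:
    """Pick the frame whose QC-center field is closest to the trajectory mean.

    ``fields`` is (n_frames, 3); returns the argmin of the Euclidean distance
    to the mean field, first index on ties.
    """
    fields = np.asarray(fields, dtype=float)
    if fields.ndim != 2 or fields.shape[0] < 1:
        raise ValueError("need at least one frame of field components")
    mean = fields.mean(axis=0)
    dist = np.linalg.norm(fields - mean, axis=1)
    return int(np.argmin(dist))


def build_collective_frame(frames: list[EnvironmentFrame]) -> EnvironmentFrame:
    """Averaged-environment collective frame: concatenate n snapshots,
    scaling every charge by 1/n, so its potential is the snapshot mean."""
    if not frames:
        raise ValueError("no frames to combine")
    n = len(frames)
    charges = np.concatenate([f.charges for f in frames]) / n
    positions = np.concatenate([f.positions for f in frames])
    return EnvironmentFrame(charges, positions)


def pmm_pipeline(
    qc_per_cluster: dict[int, UnperturbedQCData],
    frames: list[EnvironmentFrame],
    labels: np.ndarray,
    expansion: str = "atom",
) -> dict[int, list[PerturbedStates]]:
    """Apply the PMM frame by frame, basin by basin.

    Every trajectory frame is perturbed with the unperturbed state data of
    its own cluster; the result maps cluster label → list of
    :class:`PerturbedStates` in frame order, ready for spectral synthesis and
    fluctuation diagnostics.
    """
    labels = np.asarray(labels)
    if len(labels) != len(frames):
        raise ValueError("one label per frame required")
    missing = set(np.unique(labels).tolist()) - set(qc_per_cluster)
    if missing:
        raise ValueError(f"frames assigned to clusters without QC data: {sorted(missing)}")
    out: dict[int, list[PerturbedStates]] = {c: [] for c in qc_per_cluster}
    for i, (frame, lab) in enumerate(zip(frames, labels)):
        qc = qc_per_cluster[int(lab)]
        h = build_perturbed_hamiltonian(qc, frame, expansion=expansion)
        fid = frame.frame_id if frame.frame_id is not None else i
        out[int(lab)].append(diagonalize_perturbed(h, qc, frame_id=fid))
    return out
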