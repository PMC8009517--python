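"""Classical pairwise force field for droplet systems.

Interactions are Lennard-Jones 12-6 plus Coulomb between all atom pairs of
*different* fragments (intra-fragment pairs are excluded: rigid fragments
have fixed geometry and solute intramolecular terms are out of scope beyond
bond constraints).  Lorentz–Berthelot combining rules; no cutoff by default —
droplets are finite — with an optional switched cutoff for speed.

Forces are returned per atom; per-fragment center-of-mass forces and
laboratory-frame torques are accumulated by :func:`fragment_forces_torques`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import COULOMB_KJ

try:  # optional numba fast path for the pair loop
    import numba as _numba

    @_numba.njit(cache=True)
    def _pair_kernel(pos, pi, pj, sig_ij, eps4, qq, forces):
        energy = 0.0
        r2_min = 1e30
        for p in range(len(pi)):
            i = pi[p]
            j = pj[p]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < r2_min:
                r2_min = r2
            inv_r2 = 1.0 / r2
            inv_r = np.sqrt(inv_r2)
            sr2 = sig_ij[p] * sig_ij[p] * inv_r2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            energy += eps4[p] * (sr12 - sr6) + qq[p] * inv_r
            fscal = (eps4[p] * (12.0 * sr12 - 6.0 * sr6) + qq[p] * inv_r) * inv_r2
            fx = fscal * dx
            fy = fscal * dy
            fz = fscal * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
        return energy, r2_min

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

__all__ = [
    "FragmentTopology",
    "ForceTorqueSet",
    "PairForceField",
    "pair_interactions",
    "fragment_forces_torques",
    "NearSingularityError",
]

#: atoms closer than this (Å) make the pair energy numerically meaningless
MIN_SEPARATION = 0.1


class NearSingularityError(ValueError):
    """Two interacting atoms are (nearly) overlapping."""


@dataclass
class FragmentTopology:
    """Static description of one molecular fragment.

    Parameters
    ----------
    local_coords
        Atom positions (Å) in an arbitrary fragment-fixed frame.  For rigid
        fragments these are immutable and define the geometry forever; for
        flexible fragments they are only the starting structure.
    constraints
        ``(i, j, length)`` holonomic bond constraints (Å), used by RATTLE for
        flexible fragments.  Ignored for rigid fragments.
    """

    name: str
    atom_names: list[str]
    masses: np.ndarray          # amu
    charges: np.ndarray         # e
    sigma: np.ndarray           # Å
    epsilon: np.ndarray         # kJ/mol
    local_coords: np.ndarray    # (n_atoms, 3) Å
    rigid: bool = True
    constraints: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.local_coords = np.asarray(self.local_coords, dtype=float)
        n = len(self.atom_names)
        if n < 1:
            raise ValueError("fragment needs at least one atom")
        for arr, what in [
            (self.masses, "masses"),
            (self.charges, "charges"),
            (self.sigma, "sigma"),
            (self.epsilon, "epsilon"),
        ]:
            if arr.shape != (n,):
                raise ValueError(f"{what} has shape {arr.shape}, expected ({n},)")
        if self.local_coords.shape != (n, 3):
            raise ValueError("local_coords must be (n_atoms, 3)")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if self.rigid:
            self.local_coords.setflags(write=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())


@dataclass
class ForceTorqueSet:
    """Energy, per-atom forces and per-fragment COM forces/LF torques."""

    energy: float                     # kJ/mol
    atom_forces: np.ndarray           # (N, 3) kJ/mol/Å
    com_forces: np.ndarray | None = None   # (M, 3) kJ/mol/Å
    torques: np.ndarray | None = None      # (M, 3) kJ/mol (about each COM)


def fragment_forces_torques(
    atom_forces: np.ndarray,
    positions: np.ndarray,
    fragment_ids: np.ndarray,
    masses: np.ndarray,
    n_fragments: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate per-fragment COM forces and laboratory-frame torques.

    ``F_COM = Σ_a f_a`` and ``T^LF = Σ_a (r_a − r_COM) × f_a`` with the COM
    mass-weighted from ``positions``/``masses``.
    """
    atom_forces = np.asarray(atom_forces, dtype=float)
    positions = np.asarray(positions, dtype=float)
    fragment_ids = np.asarray(fragment_ids)
    masses = np.asarray(masses, dtype=float)
    if n_fragments is None:
        n_fragments = int(fragment_ids.max()) + 1

    def _scatter(values):  # bincount is much faster than np.add.at here
        return np.stack(
            [np.bincount(fragment_ids, weights=values[:, k], minlength=n_fragments)
             for k in range(values.shape[1])],
            axis=1,
        )

    com_f = _scatter(atom_forces)
    mtot = np.bincount(fragment_ids, weights=masses, minlength=n_fragments)
    com = _scatter(positions * masses[:, None]) / mtot[:, None]
    torque = _scatter(np.cross(positions - com[fragment_ids], atom_forces))
    return com_f, torque


class PairForceField:
    """Vectorized LJ + Coulomb evaluator over a fixed fragment composition.

    The inter-fragment pair list and mixed parameters are precomputed once;
    :meth:`evaluate` then costs one pass over the pair arrays per call.
    """

    def __init__(
        self,
        topologies: list[FragmentTopology],
        fragment_topology: np.ndarray | list[int],
        cutoff: float | None = None,
        switch_width: float = 1.0,
    ):
        self.topologies = topologies
        self.fragment_topology = np.asarray(fragment_topology, dtype=int)
        self.cutoff = cutoff
        self.switch_width = switch_width

        charges, sigma, eps, masses, frag_ids, names = [], [], [], [], [], []
        for f, t_idx in enumerate(self.fragment_topology):
            t = topologies[t_idx]
            charges.append(t.charges)
            sigma.append(t.sigma)
            eps.append(t.epsilon)
            masses.append(t.masses)
            frag_ids.append(np.full(t.n_atoms, f))
            names.extend(t.atom_names)
        self.charges = np.concatenate(charges)
        self.sigma = np.concatenate(sigma)
        self.epsilon = np.concatenate(eps)
        self.masses = np.concatenate(masses)
        self.fragment_ids = np.concatenate(frag_ids)
        self.atom_names = names
        self.n_atoms = len(self.charges)
        self.n_fragments = len(self.fragment_topology)

        ii, jj = np.triu_indices(self.n_atoms, k=1)
        keep = self.fragment_ids[ii] != self.fragment_ids[jj]
        self._pi = ii[keep]
        self._pj = jj[keep]
        # Lorentz–Berthelot mixing, precomputed per pair
        self._sig_ij = 0.5 * (self.sigma[self._pi] + self.sigma[self._pj])
        self._eps4 = 4.0 * np.sqrt(self.epsilon[self._pi] * self.epsilon[self._pj])
        self._qq = COULOMB_KJ * self.charges[self._pi] * self.charges[self._pj]

    def evaluate(self, positions: np.ndarray) -> ForceTorqueSet:
        """Energy (kJ/mol), per-atom forces, COM forces and torques."""
        positions = np.asarray(positions, dtype=float)
        if _HAVE_NUMBA and self.cutoff is None and len(self._pi):
            forces = np.zeros_like(positions)
            energy, r2_min = _pair_kernel(
                positions, self._pi, self._pj, self._sig_ij, self._eps4, self._qq, forces
            )
            if r2_min < MIN_SEPARATION**2:
                raise NearSingularityError(
                    f"atoms closer than {MIN_SEPARATION} Å (r_min = {np.sqrt(r2_min):.3g} Å)"
                )
            com_f, torque = fragment_forces_torques(
                forces, positions, self.fragment_ids, self.masses, self.n_fragments
            )
            return ForceTorqueSet(float(energy), forces, com_f, torque)
        dr = positions[self._pi] - positions[self._pj]
        r2 = np.einsum("ij,ij->i", dr, dr)
        if r2.size and r2.min() < MIN_SEPARATION**2:
            raise NearSingularityError(
                f"atoms closer than {MIN_SEPARATION} Å (r_min = {np.sqrt(r2.min()):.3g} Å)"
            )
        inv_r2 = 1.0 / r2
        inv_r = np.sqrt(inv_r2)
        sr2 = self._sig_ij**2 * inv_r2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        e_pair = self._eps4 * (sr12 - sr6) + self._qq * inv_r
        # dU/dr·(1/r): force on i is +fscal·dr
        fscal = (self._eps4 * (12.0 * sr12 - 6.0 * sr6) + self._qq * inv_r) * inv_r2

        if self.cutoff is not None:
            e_pair, fscal = self._apply_switch(e_pair, fscal, np.sqrt(r2), dr)

        fij = fscal[:, None] * dr
        n = len(positions)
        forces = np.stack(
            [
                np.bincount(self._pi, weights=fij[:, k], minlength=n)
                - np.bincount(self._pj, weights=fij[:, k], minlength=n)
                for k in range(3)
            ],
            axis=1,
        )
        energy = float(e_pair.sum())
        com_f, torque = fragment_forces_torques(
            forces, positions, self.fragment_ids, self.masses, self.n_fragments
        )
        return ForceTorqueSet(energy, forces, com_f, torque)

    def _apply_switch(self, e_pair, fscal, r, dr):
        """Smooth cubic switch to zero between cutoff−width and cutoff."""
        rc, w = self.cutoff, self.switch_width
        r_on = rc - w
        x = np.clip((r - r_on) / w, 0.0, 1.0)
        s = 1.0 - x * x * (3.0 - 2.0 * x)
        ds_dr = np.where((r > r_on) & (r < rc), -6.0 * x * (1.0 - x) / w, 0.0)
        # f = -(dU/dr)/r → switched: s·f − U·ds/dr /r
        fscal = s * fscal - e_pair * ds_dr / r
        e_pair = s * e_pair
        return e_pair, fscal

    def energy(self, positions: np.ndarray) -> float:
        return self.evaluate(positions).energy


def pair_interactions(
    positions: np.ndarray,
    topologies: list[FragmentTopology],
    fragment_topology: np.ndarray | list[int],
    cutoff: float | None = None,
) -> ForceTorqueSet:
    """One-shot evaluation (convenience wrapper around :class:`PairForceField`)."""
    return PairForceField(topologies, fragment_topology, cutoff=cutoff).evaluate(positions)
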