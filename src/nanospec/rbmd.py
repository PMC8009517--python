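"""Rigid-body and mixed rigid/flexible molecular dynamics under nonperiodic
boundary conditions.

The rotational propagator is a rotational velocity-Verlet scheme: angular
momenta are half-stepped with Euler's equation in the principal (molecular)
frame, the orientation quaternion at the half step is obtained by fixed-point
iteration of its equation of motion dQ/dt = ½ Q ⊗ (0, ω_MF), and the full-step
quaternion follows from the converged half-step derivative.  Translations use
standard velocity Verlet; flexible fragments are propagated with velocity
Verlet plus RATTLE bond constraints.  Confinement is a "rough wall": any
fragment whose COM leaves the sphere gets a fresh Maxwell velocity with the
radial component forced inward, plus a fresh angular momentum.

Internal units: Å, ps, amu (energies converted to kJ/mol at the interface;
time steps accepted in fs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import quatcore as qc
from .ffield import FragmentTopology, ForceTorqueSet, PairForceField
from .units import INTERNAL_PER_KJ, KB_INTERNAL, KJ_PER_INTERNAL

__all__ = [
    "IntegratorSettings",
    "RigidBodyState",
    "DegenerateRotorError",
    "IntegratorDivergenceError",
    "ConstraintError",
    "init_fragment",
    "build_state",
    "sample_momenta",
    "rvv1_step",
    "rough_wall",
    "run_md",
    "MDResult",
]

#: relative threshold below which a principal moment is treated as zero
_LINEAR_TOL = 1e-10


class DegenerateRotorError(ValueError):
    """All principal moments vanish (single point mass has no orientation)."""


class IntegratorDivergenceError(RuntimeError):
    """Quaternion fixed-point iteration failed to converge."""


class ConstraintError(RuntimeError):
    """RATTLE constraint solver failed to converge."""


@dataclass
class IntegratorSettings:
    """Time step, tolerances, thermostat and boundary parameters.

    ``dt_fs`` is accepted in femtoseconds.  ``quat_tol`` is the fixed-point
    threshold ϵ on |Q(k) − Q(k−1)| (default 1e-9; 1e-13 reproduces the
    high-accuracy diagnostics regime).  ``instability_threshold`` bounds the
    tolerated per-step quaternion norm drift before the run is declared
    unstable.
    """

    dt_fs: float = 1.0
    quat_tol: float = 1e-9
    max_quat_iter: int = 200
    temperature: float = 300.0        # K (thermostat target / wall resampling)
    tau_ps: float = 0.1               # Berendsen coupling time
    boundary_radius: float | None = None  # Å; None = no wall
    seed: int = 0
    instability_threshold: float = 0.1
    rattle_tol: float = 1e-10
    max_rattle_iter: int = 500

    def __post_init__(self):
        if self.dt_fs <= 0:
            raise ValueError("dt_fs must be positive")
        if self.quat_tol <= 0:
            raise ValueError("quat_tol must be positive")

    @property
    def dt_ps(self) -> float:
        return self.dt_fs * 1e-3


def init_fragment(
    local_coords: np.ndarray, masses: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal-axis setup of one rigid fragment.

    Returns ``(moments, q0, canonical_coords)``: the sorted (ascending)
    principal moments of inertia (amu Å²), the quaternion encoding the
    rotation from the principal frame to the input frame, and the atom
    coordinates re-expressed in the COM-centered principal frame.

    Raises
    ------
    DegenerateRotorError
        For a single point mass (no rotational degrees of freedom).
    """
    local_coords = np.asarray(local_coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if local_coords.ndim != 2 or local_coords.shape[1] != 3 or len(local_coords) < 1:
        raise ValueError("local_coords must be (n_atoms, 3) with n_atoms >= 1")
    com = masses @ local_coords / masses.sum()
    r = local_coords - com
    inertia = np.einsum("a,a->", masses, np.einsum("ai,ai->a", r, r)) * np.eye(3)
    inertia -= np.einsum("a,ai,aj->ij", masses, r, r)
    moments, axes = np.linalg.eigh(inertia)  # ascending
    scale = max(moments[-1], 1.0)
    moments = np.where(moments < _LINEAR_TOL * scale, 0.0, moments)
    if np.all(moments == 0.0):
        raise DegenerateRotorError("single point mass: all principal moments vanish")
    if np.count_nonzero(moments == 0.0) == 1:
        warnings.warn("linear fragment: one zero principal moment", stacklevel=2)
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    q0 = qc.quat_from_rotation_matrix(axes)
    canonical = r @ axes  # coordinates in the principal frame
    return moments, q0, canonical


@dataclass
class RigidBodyState:
    """Dynamic state of a droplet of rigid, point and flexible fragments.

    Rigid fragments carry (COM position/velocity, orientation quaternion,
    laboratory-frame angular momentum); point and flexible fragments carry
    per-atom positions/velocities.  ``positions`` is the full per-atom
    laboratory coordinate array, kept consistent with the fragment state.
    """

    topologies: list[FragmentTopology]
    fragment_topology: np.ndarray            # (M,) topology index per fragment

    # rigid block (arrays over rigid fragments, possibly empty)
    rigid_frag: np.ndarray = field(default=None)   # fragment indices
    com: np.ndarray = field(default=None)          # (Mr,3) Å
    vcom: np.ndarray = field(default=None)         # (Mr,3) Å/ps
    quat: np.ndarray = field(default=None)         # (Mr,4)
    ang_mom: np.ndarray = field(default=None)      # (Mr,3) amu Å²/ps, LF
    inertia: np.ndarray = field(default=None)      # (Mr,3) amu Å², principal
    rigid_mass: np.ndarray = field(default=None)   # (Mr,)
    canonical: list[np.ndarray] = field(default=None)  # per rigid fragment (n,3)
    rigid_atom_slices: list[slice] = field(default=None)

    # flexible/point block (global atom indices)
    flex_atoms: np.ndarray = field(default=None)   # (Nf,) global atom indices
    flex_vel: np.ndarray = field(default=None)     # (Nf,3)
    flex_mass: np.ndarray = field(default=None)
    constraints: list[tuple[int, int, float]] = field(default_factory=list)  # flex-local

    positions: np.ndarray = field(default=None)    # (N,3) Å
    time: float = 0.0                              # ps

    # --- derived bookkeeping -------------------------------------------------
    @property
    def n_fragments(self) -> int:
        return len(self.fragment_topology)

    @property
    def rotational_dof(self) -> int:
        if self.inertia is None or len(self.inertia) == 0:
            return 0
        return int(np.count_nonzero(self.inertia > 0))

    @property
    def translational_dof(self) -> int:
        n_entities = (0 if self.rigid_frag is None else len(self.rigid_frag)) + (
            0 if self.flex_atoms is None else len(self.flex_atoms)
        )
        return 3 * n_entities - 3  # net linear momentum removed at start

    @property
    def n_dof(self) -> int:
        return self.translational_dof + self.rotational_dof - len(self.constraints)

    def kinetic_energies(self) -> tuple[float, float]:
        """(translational, rotational) kinetic energy in kJ/mol."""
        e_tr = 0.0
        if self.rigid_frag is not None and len(self.rigid_frag):
            e_tr += 0.5 * float(
                np.einsum("m,mi,mi->", self.rigid_mass, self.vcom, self.vcom)
            )
        if self.flex_atoms is not None and len(self.flex_atoms):
            e_tr += 0.5 * float(
                np.einsum("a,ai,ai->", self.flex_mass, self.flex_vel, self.flex_vel)
            )
        e_rot = 0.0
        if self.rigid_frag is not None and len(self.rigid_frag):
            l_mf = qc.quat_rotate(self.quat, self.ang_mom, qc.LF_TO_MF)
            inv_i = np.where(self.inertia > 0, 1.0 / np.where(self.inertia > 0, self.inertia, 1.0), 0.0)
            e_rot = 0.5 * float(np.einsum("mi,mi,mi->", l_mf, l_mf, inv_i))
        return e_tr * KJ_PER_INTERNAL, e_rot * KJ_PER_INTERNAL

    def temperature(self) -> float:
        e_tr, e_rot = self.kinetic_energies()
        dof = self.n_dof
        if dof <= 0:
            return 0.0
        return 2.0 * (e_tr + e_rot) * INTERNAL_PER_KJ / (dof * KB_INTERNAL)

    def fragment_coms(self) -> np.ndarray:
        """Current COM of every fragment (Å), in fragment order."""
        m = self._atom_masses
        wpos = np.zeros((self.n_fragments, 3))
        np.add.at(wpos, self._atom_frag, self.positions * m[:, None])
        mtot = np.zeros(self.n_fragments)
        np.add.at(mtot, self._atom_frag, m)
        coms = wpos / mtot[:, None]
        if self.rigid_frag is not None and len(self.rigid_frag):
            coms[self.rigid_frag] = self.com  # exact stored COMs for rigid
        return coms

    def rebuild_rigid_positions(self) -> None:
        """Recompute rigid-fragment atom positions from (COM, quaternion).

        Fragments sharing a topology are rotated in one batched matrix
        product; the per-topology groups are prepared by :func:`build_state`.
        """
        if self._rigid_groups is not None:
            for rows, atom_idx, canon in self._rigid_groups:
                R = qc.quat_to_rotation_matrix(self.quat[rows])        # (F,3,3)
                pts = np.einsum("fij,aj->fai", R, canon)               # (F,a,3)
                self.positions[atom_idx] = (self.com[rows][:, None, :] + pts).reshape(-1, 3)
            return
        for idx in range(len(self.rigid_frag)):
            sl = self.rigid_atom_slices[idx]
            self.positions[sl] = self.com[idx] + qc.quat_rotate(
                self.quat[idx], self.canonical[idx], qc.MF_TO_LF
            )

    # filled by build_state
    _atom_masses: np.ndarray = field(default=None)
    _frag_first_atom: np.ndarray = field(default=None)
    _atom_frag: np.ndarray = field(default=None)
    _rigid_groups: list | None = field(default=None)
    _point_atoms: np.ndarray = field(default=None)   # single-atom fragments
    _point_frags: np.ndarray = field(default=None)
    _multiflex_frags: list = field(default_factory=list)

    def _fragment_atom_indices(self, f: int) -> slice:
        start = self._frag_first_atom[f]
        stop = self._frag_first_atom[f + 1] if f + 1 < len(self._frag_first_atom) else len(self.positions)
        return slice(start, stop)

    def copy(self) -> "RigidBodyState":
        import copy as _copy

        new = _copy.copy(self)
        for name in ("com", "vcom", "quat", "ang_mom", "positions", "flex_vel"):
            arr = getattr(self, name)
            if arr is not None:
                setattr(new, name, arr.copy())
        return new


def build_state(
    topologies: list[FragmentTopology],
    fragment_topology: np.ndarray | list[int],
    com_positions: np.ndarray,
    orientations: np.ndarray | None = None,
) -> RigidBodyState:
    """Assemble a :class:`RigidBodyState` with fragments placed at given COMs.

    ``orientations`` are unit quaternions applied on top of each fragment's
    canonical (principal-frame) geometry; identity if omitted.  Single-atom
    and non-rigid fragments become point/flexible entities.
    """
    fragment_topology = np.asarray(fragment_topology, dtype=int)
    com_positions = np.asarray(com_positions, dtype=float)
    n_frag = len(fragment_topology)
    if com_positions.shape != (n_frag, 3):
        raise ValueError("com_positions must be (n_fragments, 3)")
    if orientations is None:
        orientations = np.tile(qc.quat_identity(), (n_frag, 1))
    orientations = np.asarray(orientations, dtype=float)

    # canonical geometry per topology
    topo_init: dict[int, tuple] = {}
    for t_idx in sorted(set(fragment_topology.tolist())):
        t = topologies[t_idx]
        if t.rigid and t.n_atoms >= 2:
            topo_init[t_idx] = init_fragment(t.local_coords, t.masses)
        else:
            topo_init[t_idx] = None

    n_atoms_total = sum(topologies[t].n_atoms for t in fragment_topology)
    positions = np.zeros((n_atoms_total, 3))
    atom_masses = np.zeros(n_atoms_total)
    frag_first = np.zeros(n_frag, dtype=int)

    rigid_frag, com, quat, inertia, rigid_mass, canonical, rigid_slices = (
        [], [], [], [], [], [], []
    )
    flex_atoms, flex_mass, constraints = [], [], []

    cursor = 0
    for f, t_idx in enumerate(fragment_topology):
        t = topologies[t_idx]
        frag_first[f] = cursor
        sl = slice(cursor, cursor + t.n_atoms)
        atom_masses[sl] = t.masses
        if topo_init[t_idx] is not None:
            moments, _q0, canon = topo_init[t_idx]
            q = qc.quat_normalize(orientations[f])
            positions[sl] = com_positions[f] + qc.quat_rotate(q, canon, qc.MF_TO_LF)
            rigid_frag.append(f)
            com.append(com_positions[f])
            quat.append(q)
            inertia.append(moments)
            rigid_mass.append(t.total_mass)
            canonical.append(canon)
            rigid_slices.append(sl)
        else:
            # place using local coords centered at COM, rotated by orientation
            local = t.local_coords - t.masses @ t.local_coords / t.total_mass
            q = qc.quat_normalize(orientations[f])
            positions[sl] = com_positions[f] + qc.quat_rotate(q, local, qc.MF_TO_LF)
            for i, j, d in t.constraints:
                constraints.append((len(flex_atoms) + i, len(flex_atoms) + j, d))
            flex_atoms.extend(range(cursor, cursor + t.n_atoms))
            flex_mass.extend(t.masses)
        cursor += t.n_atoms

    state = RigidBodyState(
        topologies=topologies,
        fragment_topology=fragment_topology,
        rigid_frag=np.array(rigid_frag, dtype=int),
        com=np.array(com).reshape(-1, 3),
        vcom=np.zeros((len(rigid_frag), 3)),
        quat=np.array(quat).reshape(-1, 4),
        ang_mom=np.zeros((len(rigid_frag), 3)),
        inertia=np.array(inertia).reshape(-1, 3),
        rigid_mass=np.array(rigid_mass),
        canonical=canonical,
        rigid_atom_slices=rigid_slices,
        flex_atoms=np.array(flex_atoms, dtype=int),
        flex_vel=np.zeros((len(flex_atoms), 3)),
        flex_mass=np.array(flex_mass),
        constraints=constraints,
        positions=positions,
    )
    state._atom_masses = atom_masses
    state._frag_first_atom = frag_first
    state._atom_frag = np.repeat(
        np.arange(n_frag), [topologies[t].n_atoms for t in fragment_topology]
    )
    # index the non-rigid fragments by kind for fast mean-field application
    rigid_set = set(state.rigid_frag.tolist())
    point_atoms, point_frags, multiflex = [], [], []
    for f in range(n_frag):
        if f in rigid_set:
            continue
        n_a = topologies[fragment_topology[f]].n_atoms
        if n_a == 1:
            point_atoms.append(frag_first[f])
            point_frags.append(f)
        else:
            multiflex.append(f)
    state._point_atoms = np.array(point_atoms, dtype=int)
    state._point_frags = np.array(point_frags, dtype=int)
    state._multiflex_frags = multiflex
    # group rigid fragments by topology for batched position rebuilds
    groups = []
    rigid_topo = fragment_topology[state.rigid_frag] if len(state.rigid_frag) else []
    for t_idx in sorted(set(np.asarray(rigid_topo).tolist())):
        rows = np.where(fragment_topology[state.rigid_frag] == t_idx)[0]
        atom_idx = np.concatenate(
            [np.arange(state.rigid_atom_slices[r].start, state.rigid_atom_slices[r].stop)
             for r in rows]
        )
        groups.append((rows, atom_idx, state.canonical[rows[0]]))
    state._rigid_groups = groups
    return state


def sample_momenta(
    state: RigidBodyState, temperature: float, rng: np.random.Generator
) -> RigidBodyState:
    """Draw Maxwell velocities and angular momenta, then rescale exactly.

    Gaussian draws per fragment are followed by removal of the net linear
    momentum and an exact rescaling so the translational and rotational
    kinetic energies each equal (n_dof/2)·k_B·T.
    """
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    state = state.copy()
    n_rigid = len(state.rigid_frag)
    n_flex = len(state.flex_atoms)
    if temperature == 0.0:
        state.vcom[:] = 0.0
        state.ang_mom[:] = 0.0
        state.flex_vel[:] = 0.0
        return state

    kt = KB_INTERNAL * temperature
    if n_rigid:
        state.vcom = rng.standard_normal((n_rigid, 3)) * np.sqrt(kt / state.rigid_mass)[:, None]
    if n_flex:
        state.flex_vel = rng.standard_normal((n_flex, 3)) * np.sqrt(kt / state.flex_mass)[:, None]

    # remove net linear momentum
    masses = np.concatenate([state.rigid_mass, state.flex_mass])
    vels = np.concatenate([state.vcom, state.flex_vel]) if (n_rigid and n_flex) else (
        state.vcom if n_rigid else state.flex_vel
    )
    total_m = masses.sum()
    p_net = masses @ vels.reshape(len(masses), 3)
    v_drift = p_net / total_m
    if n_rigid:
        state.vcom -= v_drift
    if n_flex:
        state.flex_vel -= v_drift

    # exact translational rescale
    e_tr, _ = state.kinetic_energies()
    target_tr = 0.5 * state.translational_dof * KB_INTERNAL * temperature * KJ_PER_INTERNAL
    if e_tr > 0:
        s = np.sqrt(target_tr / e_tr)
        if n_rigid:
            state.vcom *= s
        if n_flex:
            state.flex_vel *= s

    # angular momenta in the principal frame, then exact rotational rescale
    if n_rigid:
        l_mf = rng.standard_normal((n_rigid, 3)) * np.sqrt(kt * state.inertia)
        l_mf[state.inertia == 0.0] = 0.0
        state.ang_mom = qc.quat_rotate(state.quat, l_mf, qc.MF_TO_LF)
        _, e_rot = state.kinetic_energies()
        target_rot = 0.5 * state.rotational_dof * KB_INTERNAL * temperature * KJ_PER_INTERNAL
        if e_rot > 0:
            state.ang_mom *= np.sqrt(target_rot / e_rot)
    return state


# ---------------------------------------------------------------------------
# force plumbing
# ---------------------------------------------------------------------------

def _evaluate_forces(state: RigidBodyState, ff, com_field=None) -> ForceTorqueSet:
    """Pair forces + optional COM-radial mean-field contribution."""
    fts = ff.evaluate(state.positions)
    if com_field is not None:
        coms = state.fragment_coms()
        r = np.linalg.norm(coms, axis=1)
        energy, f_rad = com_field(r)
        fts.energy += float(np.sum(energy))
        safe_r = np.where(r > 0, r, 1.0)
        f_vec = (f_rad / safe_r)[:, None] * coms
        fts.com_forces += f_vec
        if state._point_atoms is not None and len(state._point_atoms):
            # single-atom fragments: COM force acts on the atom directly
            fts.atom_forces[state._point_atoms] += f_vec[state._point_frags]
        # distribute COM force of multi-atom flexible fragments ∝ mass
        for f in state._multiflex_frags:
            sl = state._fragment_atom_indices(f)
            m = state._atom_masses[sl]
            fts.atom_forces[sl] += f_vec[f] * (m / m.sum())[:, None]
    return fts


def _rigid_atom_forces_to_frag(state: RigidBodyState, fts: ForceTorqueSet):
    """COM force (kJ/mol/Å) and LF torque (kJ/mol) per rigid fragment."""
    f_com = fts.com_forces[state.rigid_frag]
    torque = fts.torques[state.rigid_frag]
    return f_com, torque


# ---------------------------------------------------------------------------
# the RVV1 rotational step
# ---------------------------------------------------------------------------

def _rotation_step(
    quat: np.ndarray,
    ang_mom: np.ndarray,
    torque_int: np.ndarray,
    inertia: np.ndarray,
    dt: float,
    tol: float,
    max_iter: int,
    instability_threshold: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Advance orientations by one step; returns (quat_new, L_lab_half, iters).

    All arrays are batched over fragments.  The fixed-point loop iterates all
    fragments jointly until the largest per-fragment quaternion change drops
    below ``tol``; the returned count is therefore the per-step maximum over
    fragments, the diagnostic used for integrator-economy analyses.
    """
    inv_i = np.where(inertia > 0.0, 1.0 / np.where(inertia > 0.0, inertia, 1.0), 0.0)

    l_mf = qc.quat_rotate(quat, ang_mom, qc.LF_TO_MF)
    t_mf = qc.quat_rotate(quat, torque_int, qc.LF_TO_MF)
    omega = l_mf * inv_i
    # Euler's equation half-step in the molecular frame: supplies the initial
    # estimate of the half-step angular velocity for the fixed-point loop
    l_mf_half = l_mf + 0.5 * dt * (t_mf - np.cross(omega, l_mf))
    omega_half0 = l_mf_half * inv_i
    # laboratory-frame half-step (velocity-Verlet analogue)
    l_lab_half = ang_mom + 0.5 * dt * torque_int

    zeros = np.zeros(quat.shape[:-1] + (1,))
    qdot = 0.5 * qc.quat_multiply(quat, np.concatenate([zeros, omega_half0], axis=-1))
    q_half = quat + 0.5 * dt * qdot

    iters = 0
    for k in range(1, max_iter + 1):
        qh_unit = q_half / np.linalg.norm(q_half, axis=-1, keepdims=True)
        l_mf_h = qc.quat_rotate(qh_unit, l_lab_half, qc.LF_TO_MF)
        omega_h = l_mf_h * inv_i
        qdot = 0.5 * qc.quat_multiply(qh_unit, np.concatenate([zeros, omega_h], axis=-1))
        q_half_new = quat + 0.5 * dt * qdot
        diff = np.max(np.linalg.norm(q_half_new - q_half, axis=-1)) if q_half.size else 0.0
        q_half = q_half_new
        iters = k
        if diff < tol:
            break
    else:
        raise IntegratorDivergenceError(
            f"quaternion fixed point did not converge in {max_iter} iterations"
        )

    q_new = quat + dt * qdot
    q_new = qc.quat_normalize(q_new, instability_threshold=instability_threshold)
    return q_new, l_lab_half, iters


# ---------------------------------------------------------------------------
# RATTLE
# ---------------------------------------------------------------------------

def _rattle_positions(pos_new, v_half, pos_old, constraints, masses, dt, tol, max_iter):
    """Iteratively enforce bond lengths on the advanced positions (in place)."""
    if not constraints:
        return
    for _ in range(max_iter):
        done = True
        for i, j, d in constraints:
            rij = pos_new[i] - pos_new[j]
            diff = rij @ rij - d * d
            if abs(diff) > tol * d * d:
                done = False
                rij_old = pos_old[i] - pos_old[j]
                denom = 2.0 * (1.0 / masses[i] + 1.0 / masses[j]) * (rij_old @ rij)
                if denom == 0.0:
                    raise ConstraintError("degenerate constraint geometry")
                g = diff / denom
                corr = g * rij_old
                pos_new[i] -= corr / masses[i]
                pos_new[j] += corr / masses[j]
                v_half[i] -= corr / (masses[i] * dt)
                v_half[j] += corr / (masses[j] * dt)
        if done:
            return
    raise ConstraintError("RATTLE position stage did not converge")


def _rattle_velocities(pos, vel, constraints, masses, tol, max_iter):
    """Project velocities onto the constraint manifold (in place)."""
    if not constraints:
        return
    for _ in range(max_iter):
        done = True
        for i, j, d in constraints:
            rij = pos[i] - pos[j]
            vij = vel[i] - vel[j]
            rv = rij @ vij
            if abs(rv) > tol * d * d:
                done = False
                k = rv / (d * d * (1.0 / masses[i] + 1.0 / masses[j]))
                vel[i] -= k * rij / masses[i]
                vel[j] += k * rij / masses[j]
        if done:
            return
    raise ConstraintError("RATTLE velocity stage did not converge")


# ---------------------------------------------------------------------------
# single step and driver
# ---------------------------------------------------------------------------

def rvv1_step(
    state: RigidBodyState,
    ff,
    settings: IntegratorSettings,
    forces: ForceTorqueSet | None = None,
    com_field=None,
) -> tuple[RigidBodyState, int, ForceTorqueSet]:
    """One full velocity-Verlet / RVV1 / RATTLE step.

    Returns the advanced state, the per-step maximum fixed-point iteration
    count, and the force set at the new positions (reusable next step).
    """
    dt = settings.dt_ps
    if forces is None:
        forces = _evaluate_forces(state, ff, com_field)
    new = state.copy()
    n_rigid = len(state.rigid_frag)
    n_flex = len(state.flex_atoms)

    iters = 0
    if n_rigid:
        f_com, torque = _rigid_atom_forces_to_frag(state, forces)
        acc = f_com * INTERNAL_PER_KJ / state.rigid_mass[:, None]
        v_half = state.vcom + 0.5 * dt * acc
        new.com = state.com + dt * v_half
        new.quat, l_lab_half, iters = _rotation_step(
            state.quat,
            state.ang_mom,
            torque * INTERNAL_PER_KJ,
            state.inertia,
            dt,
            settings.quat_tol,
            settings.max_quat_iter,
            settings.instability_threshold,
        )
    if n_flex:
        fa = forces.atom_forces[state.flex_atoms]
        acc_f = fa * INTERNAL_PER_KJ / state.flex_mass[:, None]
        vf_half = state.flex_vel + 0.5 * dt * acc_f
        pos_old = state.positions[state.flex_atoms].copy()
        pos_new = pos_old + dt * vf_half
        _rattle_positions(
            pos_new, vf_half, pos_old, state.constraints, state.flex_mass, dt,
            settings.rattle_tol, settings.max_rattle_iter,
        )
        new.positions[state.flex_atoms] = pos_new

    if n_rigid:
        new.rebuild_rigid_positions()

    forces_new = _evaluate_forces(new, ff, com_field)

    if n_rigid:
        f_com_new, torque_new = _rigid_atom_forces_to_frag(new, forces_new)
        acc_new = f_com_new * INTERNAL_PER_KJ / state.rigid_mass[:, None]
        new.vcom = v_half + 0.5 * dt * acc_new
        new.ang_mom = l_lab_half + 0.5 * dt * torque_new * INTERNAL_PER_KJ
    if n_flex:
        fa_new = forces_new.atom_forces[state.flex_atoms]
        acc_f_new = fa_new * INTERNAL_PER_KJ / state.flex_mass[:, None]
        new.flex_vel = vf_half + 0.5 * dt * acc_f_new
        _rattle_velocities(
            new.positions[state.flex_atoms], new.flex_vel, state.constraints,
            state.flex_mass, settings.rattle_tol, settings.max_rattle_iter,
        )

    new.time = state.time + dt
    return new, iters, forces_new


def rattle_step(
    state: RigidBodyState,
    ff,
    settings: IntegratorSettings,
    com_field=None,
) -> RigidBodyState:
    """One velocity-Verlet + RATTLE step for a state with flexible fragments.

    Constraints are carried by the state; with an empty constraint list this
    reduces exactly to plain velocity Verlet.  Rigid fragments present in the
    same state advance with the quaternion propagator as usual.
    """
    new, _iters, _f = rvv1_step(state, ff, settings, com_field=com_field)
    return new


def rough_wall(
    state: RigidBodyState,
    radius: float,
    temperature: float,
    rng: np.random.Generator,
) -> RigidBodyState:
    """Resample velocity/angular momentum of fragments beyond the boundary.

    The new COM velocity keeps its tangential Maxwell components but its
    radial component is forced strictly inward; angular momenta are redrawn
    from the Maxwell distribution at ``temperature``.  Fragments inside the
    sphere are untouched.  Operates in place on a copy of the state.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    state = state.copy()
    kt = KB_INTERNAL * temperature

    if len(state.rigid_frag):
        r = np.linalg.norm(state.com, axis=1)
        out = np.where(r > radius)[0]
        for idx in out:
            rhat = state.com[idx] / r[idx]
            v = rng.standard_normal(3) * np.sqrt(kt / state.rigid_mass[idx])
            vr = v @ rhat
            v_in = v - vr * rhat - abs(vr) * rhat
            if v_in @ rhat >= 0.0:  # vr == 0 exactly: force an inward kick
                v_in -= np.sqrt(kt / state.rigid_mass[idx]) * rhat
            state.vcom[idx] = v_in
            l_mf = rng.standard_normal(3) * np.sqrt(kt * state.inertia[idx])
            l_mf[state.inertia[idx] == 0.0] = 0.0
            state.ang_mom[idx] = qc.quat_rotate(state.quat[idx], l_mf, qc.MF_TO_LF)

    if len(state.flex_atoms):
        # point particles / flexible fragments: resample atom velocities of
        # any non-rigid fragment whose COM escaped
        rigid_set = set(state.rigid_frag.tolist())
        coms = state.fragment_coms()
        rr_all = np.linalg.norm(coms, axis=1)
        flex_pos_map = {int(a): k for k, a in enumerate(state.flex_atoms)}
        for f in np.where(rr_all > radius)[0]:
            if f in rigid_set:
                continue
            sl = state._fragment_atom_indices(f)
            m = state._atom_masses[sl]
            rhat = coms[f] / rr_all[f]
            rows = [flex_pos_map[a] for a in range(sl.start, sl.stop)]
            v = rng.standard_normal((len(rows), 3)) * np.sqrt(kt / m)[:, None]
            vcom = m @ v / m.sum()
            vr = vcom @ rhat
            shift = -vr * rhat - abs(vr) * rhat
            if (vcom + shift) @ rhat >= 0.0:
                shift -= np.sqrt(kt / m.sum()) * rhat
            state.flex_vel[rows] = v + shift
    return state


def minimize_droplet(
    state: RigidBodyState,
    ff,
    com_field=None,
    max_steps: int = 300,
    initial_step: float = 0.05,
    rot_cap: float = 0.2,
    f_tol: float = 50.0,
) -> RigidBodyState:
    """Crude rigid-body steepest descent to relieve packing overlaps.

    Fragments translate along their COM force and rotate about their torque
    axis with an adaptive, displacement-capped step (Å); a trial move is
    accepted only if the energy drops.  Meant to precede equilibration, not
    to find minima: it stops once the largest COM force falls below
    ``f_tol`` kJ/mol/Å.
    """
    state = state.copy()
    fts = _evaluate_forces(state, ff, com_field)
    energy = fts.energy
    step = initial_step
    for _ in range(max_steps):
        f_all = [np.abs(fts.com_forces).max() if fts.com_forces is not None else 0.0]
        if len(state.flex_atoms):
            f_all.append(np.abs(fts.atom_forces[state.flex_atoms]).max())
        f_max = max(f_all)
        if f_max < f_tol or step < 1e-8:
            break
        trial = state.copy()
        scale = step / f_max
        if len(state.rigid_frag):
            f_com = fts.com_forces[state.rigid_frag]
            torque = fts.torques[state.rigid_frag]
            trial.com = state.com + f_com * scale
            t_norm = np.linalg.norm(torque, axis=1)
            t_max = t_norm.max() if len(t_norm) else 0.0
            if t_max > 0:
                angles = np.minimum(t_norm / t_max, 1.0) * rot_cap * min(step / initial_step, 1.0)
                for i in range(len(trial.quat)):
                    if t_norm[i] > 0:
                        dq = qc.quat_from_axis_angle(torque[i] / t_norm[i], angles[i])
                        trial.quat[i] = qc.quat_normalize(qc.quat_multiply(dq, state.quat[i]))
            trial.rebuild_rigid_positions()
        if len(state.flex_atoms):
            trial.positions[state.flex_atoms] = (
                state.positions[state.flex_atoms]
                + fts.atom_forces[state.flex_atoms] * scale
            )
        fts_trial = _evaluate_forces(trial, ff, com_field)
        if fts_trial.energy < energy:
            state, fts, energy = trial, fts_trial, fts_trial.energy
            step = min(step * 1.25, 0.5)
        else:
            step *= 0.5
    return state


@dataclass
class MDResult:
    """Trajectory frames and per-step diagnostics of one MD run."""

    frames: list[np.ndarray]          # (N,3) position snapshots
    frame_times: list[float]          # ps
    diagnostics: pd.DataFrame         # step, t, E terms, T, max_iters
    final_state: RigidBodyState

    def diagnostics_text(self) -> str:
        return self.diagnostics.to_csv(sep="\t", index=False, float_format="%.10g")


def run_md(
    state: RigidBodyState,
    ff,
    settings: IntegratorSettings,
    ensemble: str = "NVE",
    n_steps: int = 1000,
    com_field=None,
    stride: int = 0,
    observers: list | None = None,
    rng: np.random.Generator | None = None,
) -> MDResult:
    """Propagate ``n_steps`` of dynamics in the NVE or NVT-Berendsen ensemble.

    The total energy reported in the diagnostics includes translational and
    rotational kinetic terms, the pair potential, and the boundary mean-field
    energy when a ``com_field`` hook is supplied.  ``stride`` > 0 stores a
    position snapshot every that many steps.  The rough wall (NVT runs with
    ``settings.boundary_radius`` set) and the Berendsen thermostat act after
    the full integration step, in that operator order.
    """
    if ensemble not in ("NVE", "NVT"):
        raise ValueError("ensemble must be 'NVE' or 'NVT'")
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    dt = settings.dt_ps

    frames: list[np.ndarray] = []
    times: list[float] = []
    rows = np.zeros((n_steps, 8))
    forces = _evaluate_forces(state, ff, com_field)

    for step in range(n_steps):
        state, iters, forces = rvv1_step(state, ff, settings, forces=forces, com_field=com_field)

        if ensemble == "NVT":
            if settings.boundary_radius is not None:
                state = rough_wall(state, settings.boundary_radius, settings.temperature, rng)
            temp = state.temperature()
            if temp > 0:
                lam = np.sqrt(
                    1.0 + dt / settings.tau_ps * (settings.temperature / temp - 1.0)
                )
                # velocity-only rescale: positions unchanged, forces stay valid
                state.vcom *= lam
                state.ang_mom *= lam
                if len(state.flex_atoms):
                    state.flex_vel *= lam

        e_tr, e_rot = state.kinetic_energies()
        e_pot = forces.energy
        rows[step] = (
            step + 1,
            state.time,
            e_tr,
            e_rot,
            e_pot,
            e_tr + e_rot + e_pot,
            state.temperature(),
            iters,
        )
        if stride and (step + 1) % stride == 0:
            frames.append(state.positions.copy())
            times.append(state.time)
        if observers:
            for obs in observers:
                obs(state, step)

    diag = pd.DataFrame(
        rows,
        columns=["step", "t_ps", "E_kin_trans", "E_kin_rot", "E_pot", "E_tot", "T", "max_iters"],
    )
    return MDResult(frames, times, diag, state)
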