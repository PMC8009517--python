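"""File I/O, configuration and synthetic fixture generators.

Every stage of the workflow is testable without external data: this module
provides XYZ trajectory round-tripping (with per-frame comment metadata),
readers/writers for mean-field profiles and polynomial coefficient blocks,
the structured text format for unperturbed quantum-center state data, a
YAML force-field/fragment config, and seeded generators for packed solvent
droplets, multi-basin dihedral trajectories, and random-but-valid QC data.

One global seed fans out to per-stage child seeds through
:func:`child_seeds`, so each stage is independently reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import yaml

from . import quatcore as qc
from .clustmd import DihedralSeries
from .ffield import FragmentTopology
from .globmf import PolynomialMF
from .pmm import UnperturbedQCData

__all__ = [
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "read_polynomial_mf",
    "write_polynomial_mf",
    "read_profile",
    "write_profile",
    "read_qc_data",
    "write_qc_data",
    "load_topology_config",
    "pack_droplet",
    "gen_dihedral_trajectory",
    "gen_toy_qc_data",
    "child_seeds",
]


class XYZParseError(ValueError):
    """Malformed XYZ input; the message carries the offending line number."""


def child_seeds(global_seed: int, n: int) -> list[int]:
    """Deterministically derive ``n`` independent child seeds (< 2**31)."""
    ss = np.random.SeedSequence(global_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# XYZ trajectories
# ---------------------------------------------------------------------------

def read_xyz(path) -> tuple[list[np.ndarray], list[list[str]], list[str]]:
    """Read a (multi-frame) XYZ file.

    Returns (frames, element lists, comment lines).  Empty files give empty
    lists with a warning; malformed count lines raise :class:`XYZParseError`
    with the line number.
    """
    frames, elements, comments = [], [], []
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        warnings.warn(f"{path}: empty XYZ file", stacklevel=2)
        return frames, elements, comments
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(f"line {i+1}: expected atom count, got {lines[i]!r}")
        if i + 2 + n > len(lines):
            raise XYZParseError(f"line {i+1}: frame declares {n} atoms but file ends early")
        comment = lines[i + 1].rstrip("\n")
        coords = np.empty((n, 3))
        elems = []
        for a in range(n):
            parts = lines[i + 2 + a].split()
            if len(parts) < 4:
                raise XYZParseError(f"line {i+3+a}: expected 'element x y z'")
            elems.append(parts[0])
            coords[a] = [float(x) for x in parts[1:4]]
        frames.append(coords)
        elements.append(elems)
        comments.append(comment)
        i += 2 + n
    return frames, elements, comments


def write_xyz(path, frames, elements, comments=None) -> None:
    """Write frames to XYZ with 1e-8 Å round-trip precision."""
    if comments is None:
        comments = ["" for _ in frames]
    with open(path, "w") as fh:
        for coords, elems, comment in zip(frames, elements, comments):
            coords = np.asarray(coords, dtype=float)
            fh.write(f"{len(coords)}\n{comment}\n")
            for el, (x, y, z) in zip(elems, coords):
                fh.write(f"{el} {x:.10f} {y:.10f} {z:.10f}\n")


# ---------------------------------------------------------------------------
# mean-field profile / polynomial text formats
# ---------------------------------------------------------------------------

def write_profile(path, r: np.ndarray, u: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("# r_angstrom  U_kJ_per_mol\n")
        for ri, ui in zip(r, u):
            fh.write(f"{ri:.6f}  {ui:.10g}\n")


def read_profile(path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path)
    return data[:, 0], data[:, 1]


def write_polynomial_mf(path, poly: PolynomialMF, label: str = "") -> None:
    """Coefficient block: one ``a_k value`` line per coefficient."""
    with open(path, "w") as fh:
        fh.write(f"# polynomial mean field {label}\n")
        fh.write(f"degree {poly.degree}\n")
        fh.write(f"domain {poly.fit_domain[0]:.6f} {poly.fit_domain[1]:.6f}\n")
        for k, a in enumerate(poly.coefficients):
            fh.write(f"a_{k} {float(a)!r}\n")


def read_polynomial_mf(path) -> PolynomialMF:
    degree, domain, coeffs = None, (0.0, 0.0), {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, *vals = line.split()
            if key == "degree":
                degree = int(vals[0])
            elif key == "domain":
                domain = (float(vals[0]), float(vals[1]))
            elif key.startswith("a_"):
                coeffs[int(key[2:])] = float(vals[0])
    if degree is None or len(coeffs) != degree + 1:
        raise ValueError(f"{path}: inconsistent polynomial block")
    c = np.array([coeffs[k] for k in range(degree + 1)])
    return PolynomialMF(c, domain, shrinkage=0.0, rmse_train=np.nan,
                        rmse_test=np.nan, r2_train=np.nan, r2_test=np.nan)


# ---------------------------------------------------------------------------
# unperturbed QC state data (structured text)
# ---------------------------------------------------------------------------

_QC_HEADER = "NANOSPEC_QCDATA v1"


def write_qc_data(path, qc: UnperturbedQCData) -> None:
    """Blocks: STATES (index, hartree), DIPOLES (i j x y z, au), CHARGES
    (state atom q), GEOMETRY (atom x y z, bohr)."""
    with open(path, "w") as fh:
        fh.write(f"# {_QC_HEADER}\n")
        fh.write("STATES\n")
        for i, e in enumerate(qc.energies):
            fh.write(f"{i} {float(e)!r}\n")
        fh.write("DIPOLES\n")
        n = qc.n_states
        for i in range(n):
            for j in range(i, n):
                x, y, z = (float(v) for v in qc.dipoles[i, j])
                fh.write(f"{i} {j} {x!r} {y!r} {z!r}\n")
        fh.write("CHARGES\n")
        for s in range(n):
            for a, q in enumerate(qc.charges[s]):
                fh.write(f"{s} {a} {float(q)!r}\n")
        fh.write("GEOMETRY\n")
        for a, pos_a in enumerate(qc.atom_positions):
            x, y, z = (float(v) for v in pos_a)
            fh.write(f"{a} {x!r} {y!r} {z!r}\n")


def read_qc_data(path) -> UnperturbedQCData:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    if not lines or _QC_HEADER not in lines[0]:
        raise ValueError(f"{path}: missing {_QC_HEADER} header")
    section = None
    states, dipoles, charges, geometry = {}, {}, {}, {}
    for ln in lines[1:]:
        if not ln or ln.startswith("#"):
            continue
        if ln in ("STATES", "DIPOLES", "CHARGES", "GEOMETRY"):
            section = ln
            continue
        parts = ln.split()
        if section == "STATES":
            states[int(parts[0])] = float(parts[1])
        elif section == "DIPOLES":
            i, j = int(parts[0]), int(parts[1])
            dipoles[(i, j)] = [float(x) for x in parts[2:5]]
        elif section == "CHARGES":
            charges[(int(parts[0]), int(parts[1]))] = float(parts[2])
        elif section == "GEOMETRY":
            geometry[int(parts[0])] = [float(x) for x in parts[1:4]]
        else:
            raise ValueError(f"{path}: data outside any block: {ln!r}")
    n = len(states)
    n_atoms = len(geometry)
    energies = np.array([states[i] for i in range(n)])
    dip = np.zeros((n, n, 3))
    for (i, j), v in dipoles.items():
        dip[i, j] = v
        dip[j, i] = v
    chg = np.zeros((n, n_atoms))
    for (s, a), q in charges.items():
        chg[s, a] = q
    pos = np.array([geometry[a] for a in range(n_atoms)])
    return UnperturbedQCData(energies, dip, chg, pos)


# ---------------------------------------------------------------------------
# force-field / fragment YAML config
# ---------------------------------------------------------------------------

def load_topology_config(path) -> dict[str, FragmentTopology]:
    """Load fragment topologies from a YAML config.

    Schema per fragment: ``atoms`` (list of [name, mass, charge, sigma,
    epsilon]), ``coords`` (list of [x, y, z] in Å), optional ``rigid``
    (default true) and ``constraints`` (list of [i, j, length]).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "fragments" not in raw:
        raise ValueError(f"{path}: expected a top-level 'fragments' mapping")
    out = {}
    for name, block in raw["fragments"].items():
        atoms = block["atoms"]
        coords = np.asarray(block["coords"], dtype=float)
        out[name] = FragmentTopology(
            name=name,
            atom_names=[a[0] for a in atoms],
            masses=np.array([a[1] for a in atoms], dtype=float),
            charges=np.array([a[2] for a in atoms], dtype=float),
            sigma=np.array([a[3] for a in atoms], dtype=float),
            epsilon=np.array([a[4] for a in atoms], dtype=float),
            local_coords=coords,
            rigid=bool(block.get("rigid", True)),
            constraints=[(int(c[0]), int(c[1]), float(c[2]))
                         for c in block.get("constraints", [])],
        )
    return out


def builtin_data_path(filename: str):
    from importlib.resources import files

    return files("nanospec.data").joinpath(filename)


# ---------------------------------------------------------------------------
# synthetic fixture generators
# ---------------------------------------------------------------------------

def pack_droplet(
    n_fragments: int,
    radius: float,
    min_separation: float,
    topology: FragmentTopology,
    seed: int = 0,
    max_attempts: int = 20000,
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly pack fragments in a sphere with a minimum atom separation.

    COMs are uniform in the sphere of ``radius`` (Å), orientations uniform on
    SO(3) via unit quaternions.  Insertion is rejected while any inter-
    fragment atom pair is closer than ``min_separation``.  Returns
    (com_positions, orientations); raises if packing fails.
    """
    rng = np.random.default_rng(seed)
    moments_ok = topology.n_atoms >= 2
    local = topology.local_coords - (
        topology.masses @ topology.local_coords / topology.total_mass
    )
    coms = np.zeros((n_fragments, 3))
    quats = np.zeros((n_fragments, 4))
    placed_atoms: list[np.ndarray] = []
    for f in range(n_fragments):
        for _attempt in range(max_attempts):
            # uniform point in the sphere
            p = rng.standard_normal(3)
            p *= radius * rng.random() ** (1.0 / 3.0) / np.linalg.norm(p)
            q = qc.random_unit_quaternion(rng) if moments_ok else qc.quat_identity()
            atoms = p + qc.quat_rotate(q, local, qc.MF_TO_LF)
            ok = True
            if placed_atoms:
                existing = np.concatenate(placed_atoms)
                d2 = ((existing[:, None, :] - atoms[None, :, :]) ** 2).sum(-1)
                ok = d2.min() >= min_separation**2
            if ok:
                coms[f] = p
                quats[f] = q
                placed_atoms.append(atoms)
                break
        else:
            raise RuntimeError(
                f"could not place fragment {f+1}/{n_fragments} after {max_attempts} "
                "attempts; lower n_fragments or min_separation"
            )
    return coms, quats


def gen_dihedral_trajectory(
    basin_means_deg: np.ndarray,
    weights: np.ndarray,
    kappa: float,
    n_frames: int,
    seed: int = 0,
) -> tuple[DihedralSeries, np.ndarray]:
    """Sample a multi-basin dihedral trajectory from a von Mises mixture.

    ``basin_means_deg`` is (n_basins, n_dihedrals); ``weights`` the mixture
    proportions (normalized internally).  Returns the series and the true
    basin labels for recovery tests.
    """
    means = np.atleast_2d(np.asarray(basin_means_deg, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    w = weights / weights.sum()
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(w), size=n_frames, p=w)
    angles = np.degrees(rng.vonmises(np.radians(means[labels]), kappa))
    return DihedralSeries(angles), labels


def gen_toy_qc_data(
    n_states: int,
    n_atoms: int,
    seed: int = 0,
    net_charge: float = 0.0,
    energy_gap_scale: float = 0.05,
) -> UnperturbedQCData:
    """Random-but-valid unperturbed QC data for exercising the PMM layer.

    Ascending energies with hartree-scale gaps, a symmetric dipole matrix,
    per-state atomic charges that sum exactly to ``net_charge``, and a
    compact random geometry (bohr).
    """
    if n_states < 2:
        raise ValueError("need at least two states")
    rng = np.random.default_rng(seed)
    gaps = rng.uniform(0.5, 1.5, size=n_states - 1) * energy_gap_scale
    energies = np.concatenate([[0.0], np.cumsum(gaps)])
    dip = rng.normal(0.0, 1.0, size=(n_states, n_states, 3))
    dip = 0.5 * (dip + np.swapaxes(dip, 0, 1))
    chg = rng.normal(0.0, 0.2, size=(n_states, n_atoms))
    chg += (net_charge - chg.sum(axis=1, keepdims=True)) / n_atoms
    pos = rng.normal(0.0, 2.0, size=(n_atoms, 3))
    return UnperturbedQCData(energies, dip, chg, pos)
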