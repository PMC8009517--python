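"""Unit system and physical constants.

Mechanical quantities are carried internally in Å, ps, amu; energies at the
interface are kJ/mol.  One amu·Å²/ps² equals 0.01 kJ/mol, so kinetic energies
computed from (amu, Å/ps) velocities convert with :data:`KJ_PER_INTERNAL`.
The perturbed-matrix layer works in Hartree atomic units; converters for the
Å/bohr and energy/wavelength boundaries live here.
"""

from __future__ import annotations

# mechanical units -----------------------------------------------------------
KB_KJMOL = 8.31446261815324e-3  # Boltzmann constant, kJ/(mol K)
KJ_PER_INTERNAL = 0.01          # kJ/mol per amu Å²/ps²
INTERNAL_PER_KJ = 100.0         # amu Å²/ps² per kJ/mol
KB_INTERNAL = KB_KJMOL * INTERNAL_PER_KJ  # amu Å²/(ps² K)

# electrostatics: Coulomb constant in kJ·Å/(mol·e²), CODATA-derived and fixed
# so that energies are bit-stable across platforms.
COULOMB_KJ = 1389.35457644382

# atomic units ---------------------------------------------------------------
BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
ANGSTROM_PER_BOHR = 0.529177210903
HARTREE_PER_EV = 1.0 / 27.211386245988
EV_PER_HARTREE = 27.211386245988
WAVENUMBER_PER_HARTREE = 219474.6313632  # cm⁻¹ per hartree
NM_TO_WAVENUMBER = 1.0e7                 # λ(nm) = 1e7 / ν̃(cm⁻¹)

# Avogadro constant and density conversion: molecules/Å³ → mol/L
AVOGADRO = 6.02214076e23
MOL_PER_L_PER_INV_A3 = 1.0e27 / AVOGADRO  # ≈ 1660.539


def angstrom_to_bohr(x):
    return x * BOHR_PER_ANGSTROM


def bohr_to_angstrom(x):
    return x * ANGSTROM_PER_BOHR


def hartree_to_ev(e):
    return e * EV_PER_HARTREE


def hartree_to_nm(e):
    """Photon energy in hartree → wavelength in nm."""
    return NM_TO_WAVENUMBER / (e * WAVENUMBER_PER_HARTREE)


def nm_to_hartree(lam):
    return NM_TO_WAVENUMBER / lam / WAVENUMBER_PER_HARTREE
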