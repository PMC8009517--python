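"""UV-vis spectral synthesis from perturbed electronic states.

Per-frame excitation energies and transition dipoles become oscillator
strengths f = (2/3)·ΔE·|μ|² (atomic units); each stick is broadened by an
area-normalized Gaussian on the *energy* axis (spread σ in au of frequency,
default 0.0008), frames are averaged within a cluster, cluster spectra are
combined as a population-weighted convex sum, and the result is reported as a
molar absorption coefficient ε(λ) in M⁻¹cm⁻¹ using the standard relation
between integrated absorptivity and oscillator strength,
f = 4.319×10⁻⁹ mol L⁻¹ cm² · ∫ε(ν̃) dν̃ (ν̃ in cm⁻¹).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .units import EV_PER_HARTREE, NM_TO_WAVENUMBER, WAVENUMBER_PER_HARTREE

__all__ = [
    "StickSpectrum",
    "BroadSpectrum",
    "oscillator_strength",
    "sticks_from_states",
    "broaden",
    "combine_weighted",
    "spectrum_metrics",
    "OSCILLATOR_TO_EPSILON",
]

#: f = 4.319e-9 mol·L⁻¹·cm² × ∫ε dν̃  →  ∫ε dν̃ = f / 4.319e-9
OSCILLATOR_TO_EPSILON = 1.0 / 4.319e-9

#: default Gaussian broadening, au of frequency
DEFAULT_SIGMA_AU = 0.0008


def oscillator_strength(delta_e: float, mu: np.ndarray) -> float:
    """f = (2/3)·ΔE·|μ|² with ΔE in hartree and μ in e·bohr (au)."""
    mu = np.asarray(mu, dtype=float)
    de = np.asarray(delta_e, dtype=float)
    if np.any(de <= 0):
        raise ValueError("excitation energy must be positive")
    return (2.0 / 3.0) * de * np.einsum("...x,...x->...", mu, mu)


@dataclass
class StickSpectrum:
    """Per-frame, per-state excitation energies (hartree) and strengths."""

    energies: np.ndarray   # (n_frames, n_excited)
    strengths: np.ndarray  # (n_frames, n_excited), f ≥ 0

    def __post_init__(self):
        self.energies = np.atleast_2d(np.asarray(self.energies, dtype=float))
        self.strengths = np.atleast_2d(np.asarray(self.strengths, dtype=float))
        if self.energies.shape != self.strengths.shape:
            raise ValueError("energies and strengths must have the same shape")
        if self.energies.size and np.any(self.energies <= 0):
            raise ValueError("excitation energies must be positive")
        if self.strengths.size and np.any(self.strengths < 0):
            raise ValueError("oscillator strengths must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.energies.shape[0]


def sticks_from_states(states_list) -> StickSpectrum:
    """Assemble a stick spectrum from per-frame :class:`PerturbedStates`."""
    energies, strengths = [], []
    for st in states_list:
        de = st.excitation_energies
        mu = st.transition_dipoles[1:]
        energies.append(de)
        strengths.append(oscillator_strength(de, mu))
    return StickSpectrum(np.array(energies), np.array(strengths))


@dataclass
class BroadSpectrum:
    """Broadened molar absorption spectrum on a fixed energy grid."""

    energy_grid: np.ndarray   # hartree, ascending
    epsilon: np.ndarray       # M⁻¹cm⁻¹
    sigma_au: float

    def __post_init__(self):
        self.energy_grid = np.asarray(self.energy_grid, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.energy_grid.shape != self.epsilon.shape:
            raise ValueError("grid/epsilon shape mismatch")

    @property
    def wavelength_nm(self) -> np.ndarray:
        return NM_TO_WAVENUMBER / (self.energy_grid * WAVENUMBER_PER_HARTREE)

    def to_text(self) -> str:
        lines = ["# lambda_nm  epsilon_M-1cm-1"]
        for lam, eps in zip(self.wavelength_nm[::-1], self.epsilon[::-1]):
            lines.append(f"{lam:.4f}  {eps:.6g}")
        return "\n".join(lines) + "\n"


def make_energy_grid(sticks: StickSpectrum, sigma_au: float, n_points: int = 2000,
                     pad_sigmas: float = 6.0) -> np.ndarray:
    lo = sticks.energies.min() - pad_sigmas * sigma_au
    hi = sticks.energies.max() + pad_sigmas * sigma_au
    return np.linspace(max(lo, 1e-6), hi, n_points)


def broaden(
    sticks: StickSpectrum,
    sigma_au: float = DEFAULT_SIGMA_AU,
    grid: np.ndarray | None = None,
) -> BroadSpectrum:
    """Gaussian-broaden sticks on the energy axis and average over frames.

    Each stick contributes an area-normalized Gaussian (in cm⁻¹) weighted by
    its oscillator strength; the frame average is converted to ε(ν̃) so that
    ∫ε dν̃ = ⟨Σ f⟩ / 4.319×10⁻⁹.
    """
    if sigma_au <= 0:
        raise ValueError("sigma must be positive")
    if sticks.energies.size == 0:
        warnings.warn("empty stick spectrum: returning zero spectrum", stacklevel=2)
        g = grid if grid is not None else np.linspace(0.05, 0.5, 100)
        return BroadSpectrum(g, np.zeros_like(g), sigma_au)
    if grid is None:
        grid = make_energy_grid(sticks, sigma_au)
    grid = np.asarray(grid, dtype=float)
    if grid[0] > sticks.energies.min() - 5 * sigma_au or grid[-1] < sticks.energies.max() + 5 * sigma_au:
        warnings.warn("grid does not cover sticks ± 5σ; band tails clipped", stacklevel=2)

    sigma_cm = sigma_au * WAVENUMBER_PER_HARTREE
    grid_cm = grid * WAVENUMBER_PER_HARTREE
    e0_cm = sticks.energies.ravel() * WAVENUMBER_PER_HARTREE
    f = sticks.strengths.ravel()
    norm = 1.0 / (sigma_cm * np.sqrt(2.0 * np.pi))
    # (n_sticks, n_grid) Gaussian table; frame average = sum / n_frames
    gauss = np.exp(-0.5 * ((grid_cm[None, :] - e0_cm[:, None]) / sigma_cm) ** 2)
    eps = OSCILLATOR_TO_EPSILON * norm * (f @ gauss) / sticks.n_frames
    return BroadSpectrum(grid, eps, sigma_au)


def combine_weighted(spectra: list[BroadSpectrum], weights: np.ndarray) -> BroadSpectrum:
    """Population-weighted convex combination of cluster spectra."""
    if len(spectra) != len(weights):
        raise ValueError("one weight per spectrum required")
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    grid = spectra[0].energy_grid
    for s in spectra[1:]:
        if s.energy_grid.shape != grid.shape or not np.allclose(s.energy_grid, grid):
            raise ValueError("spectra are on different grids")
    w = weights / weights.sum()
    eps = np.einsum("c,cg->g", w, np.array([s.epsilon for s in spectra]))
    return BroadSpectrum(grid, eps, spectra[0].sigma_au)


def spectrum_metrics(spectrum: BroadSpectrum) -> tuple[float, float, float]:
    """(λ_max nm, ε_max M⁻¹cm⁻¹, FWHM eV) of the dominant band.

    The half-height crossings are located by linear interpolation on the
    energy grid around the absolute maximum.
    """
    eps = spectrum.epsilon
    if eps.max() <= 0 or np.allclose(eps, eps[0]):
        raise ValueError("flat spectrum: no peak to report")
    i_max = int(np.argmax(eps))
    e = spectrum.energy_grid
    eps_max = float(eps[i_max])
    lam_max = float(NM_TO_WAVENUMBER / (e[i_max] * WAVENUMBER_PER_HARTREE))
    half = eps_max / 2.0

    def _cross(idx_range, reverse=False):
        rng = idx_range[::-1] if reverse else idx_range
        prev = i_max
        for i in rng:
            if eps[i] < half:
                e1, e2 = e[i], e[prev]
                y1, y2 = eps[i], eps[prev]
                return e1 + (half - y1) * (e2 - e1) / (y2 - y1)
            prev = i
        return None

    e_lo = _cross(range(i_max - 1, -1, -1))
    e_hi = _cross(range(i_max + 1, len(e)))
    if e_lo is None or e_hi is None:
        raise ValueError("half-height not reached within the grid window")
    fwhm_ev = (e_hi - e_lo) * EV_PER_HARTREE
    return lam_max, eps_max, float(fwhm_ev)
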