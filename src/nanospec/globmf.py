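"""Nonperiodic-boundary mean field: Gaussian-shell boundary potential,
density-feedback optimization, profile truncation, and polynomial fitting.

The nonelectrostatic boundary term U_vW(r) is a sum of Gaussians of constant
spread σ centered on concentric shells, U_vW(r) = Σ_i λ_i G(r − r_i; σ),
acting on fragment centers of mass.  The shell heights λ_i are optimized by
feedback against the radial density profile: shells denser than the bulk
target get more repulsive, depleted shells more attractive, until the droplet
density is flat.  The converged profile is truncated where negligible and
compressed into a polynomial U_vW(r) = Σ_k a_k r^k via ridge regression whose
shrinkage factor is tuned by a small genetic algorithm, with the degree
picked from RMSE/R² learning curves.

The electrostatic continuum term of the boundary (a reaction field) is not
computed here: :func:`combine_com_fields` lets callers stack any user-supplied
``(r) -> (energy, radial force)`` hook on top of U_vW; with no hook the
electrostatic contribution is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .units import MOL_PER_L_PER_INV_A3

__all__ = [
    "MeanFieldProfile",
    "DensityProfile",
    "PolynomialMF",
    "GASettings",
    "combine_com_fields",
    "uvw_energy_force",
    "accumulate_density",
    "update_lambdas",
    "truncate_profile",
    "fit_polynomial_mf",
    "evaluate_polynomial_mf",
    "run_mf_optimization",
]

#: |U| below this (kJ/mol) is considered negligible for truncation
TRUNCATION_LEVEL = 0.1


@dataclass
class MeanFieldProfile:
    """Gaussian-shell boundary potential U_vW.

    ``n_shells`` concentric shells of constant ``shell_width`` (Å) span the
    cavity; ``sigma`` is the common Gaussian spread (defaults to the shell
    width) and ``lambdas`` the per-shell heights in kJ/mol.
    """

    n_shells: int = 81
    shell_width: float = 0.25
    sigma: float | None = None
    lambdas: np.ndarray | None = None
    boundary_radius: float | None = None

    def __post_init__(self):
        if self.n_shells < 1:
            raise ValueError("need at least one shell")
        if self.sigma is None:
            self.sigma = self.shell_width
        if self.lambdas is None:
            self.lambdas = np.zeros(self.n_shells)
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if self.lambdas.shape != (self.n_shells,):
            raise ValueError("lambdas must have one entry per shell")
        if self.boundary_radius is None:
            self.boundary_radius = self.n_shells * self.shell_width

    @property
    def centers(self) -> np.ndarray:
        """Shell centers r_i (Å), strictly increasing."""
        return (np.arange(self.n_shells) + 0.5) * self.shell_width

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.n_shells + 1) * self.shell_width

    def __call__(self, r):
        """Energy/force hook with the (energy, radial force) signature."""
        return uvw_energy_force(r, self)


def uvw_energy_force(r, profile: MeanFieldProfile):
    """Evaluate U_vW and its radial force −dU/dr at radius r (Å, kJ/mol).

    Scalar or array ``r``; the Gaussian shells are evaluated analytically so
    the force is the exact derivative of the energy.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be >= 0")
    dr = r[..., None] - profile.centers
    g = np.exp(-0.5 * (dr / profile.sigma) ** 2)
    energy = g @ profile.lambdas
    force = (g * dr / profile.sigma**2) @ profile.lambdas  # −dU/dr
    return energy, force


def combine_com_fields(*fields):
    """Compose COM-radial field hooks, e.g. U_vW plus an electrostatic term.

    Each hook maps radii (Å) to ``(energy kJ/mol, radial force kJ/mol/Å)``;
    the combination sums both.  With no arguments the result is the zero
    field (the default when no continuum electrostatics is supplied).
    """

    def combined(r):
        r = np.asarray(r, dtype=float)
        energy = np.zeros_like(r)
        force = np.zeros_like(r)
        for f in fields:
            e_i, f_i = f(r)
            energy = energy + e_i
            force = force + f_i
        return energy, force

    return combined


@dataclass
class DensityProfile:
    """Radial number-density histogram over COM positions."""

    edges: np.ndarray       # (n_shells+1,) Å
    density: np.ndarray     # (n_shells,) mol/L
    counts: np.ndarray      # raw COM counts per shell
    n_samples: int          # number of (frame × molecule) observations
    overflow: int = 0       # COMs beyond the outermost edge

    @property
    def shell_volumes(self) -> np.ndarray:
        return 4.0 / 3.0 * np.pi * (self.edges[1:] ** 3 - self.edges[:-1] ** 3)


def shell_edges(radius: float, n_shells: int, mode: str = "equal-width") -> np.ndarray:
    """Edges of concentric shells of equal width or equal volume."""
    if mode == "equal-width":
        return np.linspace(0.0, radius, n_shells + 1)
    if mode == "equal-volume":
        return radius * (np.arange(n_shells + 1) / n_shells) ** (1.0 / 3.0)
    raise ValueError("mode must be 'equal-width' or 'equal-volume'")


def accumulate_density(
    com_frames: list[np.ndarray] | np.ndarray,
    edges: np.ndarray,
) -> DensityProfile:
    """Average radial density (mol/L) of COMs over trajectory frames.

    ``com_frames`` is a sequence of (M, 3) COM arrays (or a single stacked
    (F, M, 3) array).  COMs beyond the outermost edge are counted in an
    overflow bin and reported with a warning.
    """
    frames = np.asarray(com_frames, dtype=float)
    if frames.size == 0:
        raise ValueError("empty trajectory")
    if frames.ndim == 2:
        frames = frames[None]
    edges = np.asarray(edges, dtype=float)
    radii = np.linalg.norm(frames, axis=-1).ravel()
    counts, _ = np.histogram(radii, bins=edges)
    overflow = int(np.sum(radii >= edges[-1]))
    if overflow:
        warnings.warn(f"{overflow} COM samples beyond the outermost shell", stacklevel=2)
    n_frames = frames.shape[0]
    volumes = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    density = counts / n_frames / volumes * MOL_PER_L_PER_INV_A3
    return DensityProfile(edges, density, counts, n_samples=radii.size, overflow=overflow)


def update_lambdas(
    profile: MeanFieldProfile,
    density: DensityProfile,
    rho_bulk: float,
    step: float = 0.01,
    band: float = 0.0025,
) -> MeanFieldProfile:
    """Density-feedback update of the shell heights.

    Shells whose density lies within ``[(1−band)ρ_bulk, (1+band)ρ_bulk]``
    (default ±0.25%) are left alone; denser shells become more repulsive by
    ``step`` kJ/mol, depleted shells more attractive by the same amount.
    Returns a new profile.
    """
    if len(density.density) != profile.n_shells or not np.allclose(
        density.edges, profile.edges
    ):
        raise ValueError("density shells do not align with profile shells")
    lam = profile.lambdas.copy()
    hi = density.density > (1.0 + band) * rho_bulk
    lo = density.density < (1.0 - band) * rho_bulk
    lam[hi] += step
    lam[lo] -= step
    return MeanFieldProfile(
        n_shells=profile.n_shells,
        shell_width=profile.shell_width,
        sigma=profile.sigma,
        lambdas=lam,
        boundary_radius=profile.boundary_radius,
    )


def truncate_profile(r: np.ndarray, u: np.ndarray, level: float = TRUNCATION_LEVEL):
    """Drop the innermost contiguous region where |U| < ``level`` kJ/mol.

    The mean field acts only near the boundary; the flat interior is removed
    before polynomial fitting so the fit spends its flexibility where the
    potential actually varies.  Returns the kept (r, u) arrays.
    """
    r = np.asarray(r, dtype=float)
    u = np.asarray(u, dtype=float)
    significant = np.abs(u) >= level
    if not np.any(significant):
        warnings.warn("entire profile below truncation level; nothing kept", stacklevel=2)
        return r[:0], u[:0]
    first = int(np.argmax(significant))
    return r[first:], u[first:]


@dataclass
class GASettings:
    """Genetic-algorithm settings for the 1-D shrinkage search (log10 α)."""

    population: int = 50
    mutation_rate: float = 0.3
    crossover_rate: float = 0.5
    iterations: int = 500
    log_alpha_range: tuple[float, float] = (-12.0, 2.0)
    seed: int = 0


@dataclass
class PolynomialMF:
    """Fitted polynomial mean field U(r) = Σ_k a_k r^k."""

    coefficients: np.ndarray        # a_0 .. a_degree, kJ/mol per Å^k
    fit_domain: tuple[float, float]
    shrinkage: float
    rmse_train: float
    rmse_test: float
    r2_train: float
    r2_test: float

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1


def _ridge_fit(x, y, degree, alpha):
    """Plain normal-equations ridge on the Vandermonde design.

    The intercept is penalized like every other coefficient, so α → 0
    recovers ordinary least squares exactly (needed for the noise-free
    polynomial-recovery contract).
    """
    X = np.vander(x, degree + 1, increasing=True)
    A = X.T @ X + alpha * np.eye(degree + 1)
    try:
        coef = np.linalg.solve(A, X.T @ y)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate design matrix") from exc
    return coef


def _rmse_r2(x, y, coef):
    pred = np.polynomial.polynomial.polyval(x, coef)
    resid = y - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return rmse, r2


def _ga_optimize_shrinkage(x_tr, y_tr, x_te, y_te, degree, ga: GASettings) -> float:
    """Minimize test RMSE over log10(α) with a small real-coded GA."""
    rng = np.random.default_rng(ga.seed)
    lo, hi = ga.log_alpha_range

    def fitness(log_alpha):
        coef = _ridge_fit(x_tr, y_tr, degree, 10.0**log_alpha)
        rmse, _ = _rmse_r2(x_te, y_te, coef)
        return rmse

    pop = rng.uniform(lo, hi, size=ga.population)
    fit = np.array([fitness(g) for g in pop])
    for _ in range(ga.iterations):
        # tournament selection of parents
        a, b = rng.integers(0, ga.population, size=(2, ga.population))
        parents = np.where(fit[a] <= fit[b], pop[a], pop[b])
        children = parents.copy()
        # arithmetic crossover between consecutive parents
        do_cx = rng.random(ga.population) < ga.crossover_rate
        mates = rng.permutation(ga.population)
        w = rng.random(ga.population)
        children = np.where(do_cx, w * parents + (1 - w) * parents[mates], children)
        # Gaussian mutation
        do_mut = rng.random(ga.population) < ga.mutation_rate
        children = np.where(
            do_mut, np.clip(children + rng.normal(0, 0.5, ga.population), lo, hi), children
        )
        child_fit = np.array([fitness(g) for g in children])
        # elitist replacement: keep the better of parent/child slots
        better = child_fit < fit
        pop = np.where(better, children, pop)
        fit = np.where(better, child_fit, fit)
    return float(10.0 ** pop[np.argmin(fit)])


def grid_search_shrinkage(x_tr, y_tr, x_te, y_te, degree, n=200, log_range=(-12.0, 2.0)) -> float:
    """Deterministic log-grid cross-check for the 1-D shrinkage search."""
    grid = np.logspace(log_range[0], log_range[1], n)
    rmses = []
    for alpha in grid:
        coef = _ridge_fit(x_tr, y_tr, degree, alpha)
        rmses.append(_rmse_r2(x_te, y_te, coef)[0])
    return float(grid[int(np.argmin(rmses))])


def fit_polynomial_mf(
    r: np.ndarray,
    u: np.ndarray,
    r_test: np.ndarray | None = None,
    u_test: np.ndarray | None = None,
    degrees=range(0, 11),
    ga: GASettings | None = None,
    alpha_override: float | None = None,
) -> tuple[PolynomialMF, "pd.DataFrame"]:
    """Ridge-fit the truncated profile for every degree and pick the best.

    If no explicit test set is given, even-indexed points train and
    odd-indexed points test (profiles are sampled on a regular grid, so this
    mimics drawing the test set the same way as the training set).  For each
    degree the shrinkage is GA-optimized (or fixed by ``alpha_override``);
    the selected degree minimizes test RMSE, ties to the lower degree.
    Returns the winning :class:`PolynomialMF` and the per-degree learning
    curves (degree, shrinkage, train/test RMSE and R²) as a DataFrame.
    """
    import pandas as pd

    r = np.asarray(r, dtype=float)
    u = np.asarray(u, dtype=float)
    if r_test is None:
        r_test, u_test = r[1::2], u[1::2]
        r, u = r[0::2], u[0::2]
    if ga is None:
        ga = GASettings()

    rows = []
    fits: dict[int, tuple[np.ndarray, float]] = {}
    for deg in degrees:
        if len(r) < deg + 2:
            continue
        if alpha_override is not None:
            alpha = alpha_override
        else:
            alpha = _ga_optimize_shrinkage(r, u, r_test, u_test, deg, ga)
        coef = _ridge_fit(r, u, deg, alpha)
        rmse_tr, r2_tr = _rmse_r2(r, u, coef)
        rmse_te, r2_te = _rmse_r2(r_test, u_test, coef)
        fits[deg] = (coef, alpha)
        rows.append((deg, alpha, rmse_tr, rmse_te, r2_tr, r2_te))
    if not rows:
        raise ValueError("not enough points for any requested degree")
    curves = pd.DataFrame(
        rows, columns=["degree", "shrinkage", "rmse_train", "rmse_test", "r2_train", "r2_test"]
    )
    best_deg = int(curves.loc[curves["rmse_test"].idxmin(), "degree"])
    coef, alpha = fits[best_deg]
    rmse_tr, r2_tr = _rmse_r2(r, u, coef)
    rmse_te, r2_te = _rmse_r2(r_test, u_test, coef)
    poly = PolynomialMF(
        coefficients=coef,
        fit_domain=(float(min(r.min(), r_test.min())), float(max(r.max(), r_test.max()))),
        shrinkage=alpha,
        rmse_train=rmse_tr,
        rmse_test=rmse_te,
        r2_train=r2_tr,
        r2_test=r2_te,
    )
    return poly, curves


def evaluate_polynomial_mf(r, poly: PolynomialMF, warn_extrapolation: bool = True):
    """U(r) and radial force −dU/dr from the fitted polynomial (Horner)."""
    r = np.asarray(r, dtype=float)
    lo, hi = poly.fit_domain
    if warn_extrapolation and (np.any(r < lo) or np.any(r > hi)):
        warnings.warn("evaluating polynomial mean field outside its fit domain", stacklevel=2)
    c = poly.coefficients
    energy = np.polynomial.polynomial.polyval(r, c)
    dcoef = np.polynomial.polynomial.polyder(c) if len(c) > 1 else np.zeros(1)
    force = -np.polynomial.polynomial.polyval(r, dcoef)
    return energy, force


@dataclass
class MFOptimizationResult:
    profile: MeanFieldProfile
    density_history: list[DensityProfile]
    max_deviation_history: list[float]   # max_i |ρ_i − ρ_bulk| per epoch, mol/L
    lambda_history: list[np.ndarray] = field(default_factory=list)


def run_mf_optimization(
    state,
    ff,
    settings,
    profile: MeanFieldProfile,
    rho_bulk: float,
    n_epochs: int,
    steps_per_epoch: int,
    sample_stride: int = 10,
    lambda_step: float = 0.01,
    band: float = 0.0025,
    rng: np.random.Generator | None = None,
    halve_on_oscillation: bool = True,
    step_decay: float = 1.0,
) -> MFOptimizationResult:
    """Alternate NVT propagation under the current U_vW with λ updates.

    Each epoch runs ``steps_per_epoch`` MD steps sampling fragment COMs every
    ``sample_stride`` steps, then applies the density-feedback update.  If a
    shell's update direction flips (oscillation around the band), the global
    step is halved once per detected flip, stabilizing the late phase; for
    short, noisy (desk-scale) schedules a deterministic geometric schedule
    ``step_decay`` < 1 is the better anneal and the flip heuristic should be
    disabled.  Returns the final profile and the per-epoch density history.
    """
    from .rbmd import run_md

    if rng is None:
        rng = np.random.default_rng(settings.seed)
    density_history: list[DensityProfile] = []
    dev_history: list[float] = []
    lam_history: list[np.ndarray] = []
    prev_direction: np.ndarray | None = None
    step = lambda_step

    for _epoch in range(n_epochs):
        com_samples: list[np.ndarray] = []

        def collect(st, istep):
            if (istep + 1) % sample_stride == 0:
                com_samples.append(st.fragment_coms().copy())

        result = run_md(
            state, ff, settings, ensemble="NVT",
            n_steps=steps_per_epoch, com_field=profile, observers=[collect], rng=rng,
        )
        state = result.final_state
        density = accumulate_density(com_samples, profile.edges)
        direction = np.sign(
            (density.density > (1 + band) * rho_bulk).astype(int)
            - (density.density < (1 - band) * rho_bulk).astype(int)
        )
        if (
            halve_on_oscillation
            and prev_direction is not None
            and np.any(direction * prev_direction < 0)
        ):
            step = max(step * 0.5, lambda_step / 64.0)
        prev_direction = direction
        profile = update_lambdas(profile, density, rho_bulk, step=step, band=band)
        step *= step_decay
        density_history.append(density)
        dev_history.append(float(np.max(np.abs(density.density - rho_bulk))))
        lam_history.append(profile.lambdas.copy())

    return MFOptimizationResult(profile, density_history, dev_history, lam_history)
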