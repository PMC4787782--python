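"""Bell-Evans two-state kinetics on a single-barrier landscape.

The folded state sits at reaction coordinate x = 0, the unfolded state at
x = L, separated by a single barrier at x_fwd (= x_→); L = x_fwd + x_rev.
An external force F tilts the landscape, lowering the unfolding barrier by
F·x_fwd and raising the folding barrier by F·x_rev:

    k_unfold(F) = k0 · exp(+F·x_fwd / k_BT)
    k_fold(F)   = k1 · exp(−F·x_rev / k_BT),   k1 = k0 · exp(ΔG / k_BT)

with ΔG the zero-force free-energy difference (unfolded − folded, total
including elastic contributions) and k0 the zero-force unfolding rate.
Under a linear force ramp of loading rate r these rates give closed-form
first-transition force densities; the distribution of the force hysteresis
F_unfold − F_fold is their cross-correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import fftconvolve

from .constants import DEFAULT_TEMPERATURE_K, kj_per_mol_to_pn_nm, thermal_energy
from .elasticity import ConstructModel, effective_stiffness, solve_force_balance
from .errors import ConfigurationError, DomainError, GridError

#: Default uniform force grid for densities: 0–30 pN, 0.01 pN step.
DEFAULT_GRID_STEP_PN = 0.01
DEFAULT_GRID_MAX_PN = 30.0


@dataclass(frozen=True)
class TwoStateParams:
    """Bell-Evans parameter bundle for one hairpin.

    Parameters
    ----------
    L_nm : float
        Folded-to-unfolded distance along the pulling coordinate.
    x_fwd_nm : float
        Folded-state-to-barrier distance x_→ (0 < x_fwd < L).
    dG_kj_mol : float
        Zero-force free-energy difference (unfolded minus folded), kJ/mol.
    k0_per_s : float
        Zero-force unfolding rate.
    nu0_per_s, E_kj_mol : float, optional
        Attempt frequency and barrier height.  Only their combination
        k0 = ν0·exp(−E/k_BT) is identifiable from ramp data; when both are
        given they are validated for consistency with k0 and otherwise
        carried as metadata.
    """

    L_nm: float
    x_fwd_nm: float
    dG_kj_mol: float
    k0_per_s: float
    nu0_per_s: float | None = None
    E_kj_mol: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.x_fwd_nm < self.L_nm:
            raise DomainError(
                f"x_fwd_nm must satisfy 0 < x_fwd < L, got x_fwd={self.x_fwd_nm}"
                f" L={self.L_nm}")
        if self.k0_per_s <= 0:
            raise DomainError("k0_per_s must be > 0")
        if self.dG_kj_mol <= 0:
            raise DomainError("dG_kj_mol must be > 0")
        if (self.nu0_per_s is None) != (self.E_kj_mol is None):
            raise ConfigurationError("nu0_per_s and E_kj_mol must be set together")
        if self.nu0_per_s is not None:
            kbt = thermal_energy(DEFAULT_TEMPERATURE_K)
            implied = self.nu0_per_s * math.exp(
                -kj_per_mol_to_pn_nm(self.E_kj_mol) / kbt)
            if abs(implied - self.k0_per_s) > 1e-6 * self.k0_per_s:
                raise ConfigurationError(
                    f"nu0·exp(−E/kBT) = {implied:g} inconsistent with "
                    f"k0 = {self.k0_per_s:g}")

    @property
    def x_rev_nm(self) -> float:
        """Barrier-to-unfolded distance x_← = L − x_fwd."""
        return self.L_nm - self.x_fwd_nm

    def dG_pn_nm(self) -> float:
        return kj_per_mol_to_pn_nm(self.dG_kj_mol)


@dataclass(frozen=True)
class RampSpec:
    """Linear force ramp: loading rate r = k_eff·v, start/end forces, direction."""

    loading_rate_pn_s: float
    F_start_pn: float
    F_max_pn: float
    direction: Literal["stretch", "release"] = "stretch"

    def __post_init__(self) -> None:
        if self.loading_rate_pn_s <= 0:
            raise DomainError("loading_rate_pn_s must be > 0")
        if not self.F_start_pn < self.F_max_pn:
            raise DomainError("F_start_pn must be < F_max_pn")
        if self.direction not in ("stretch", "release"):
            raise DomainError(f"unknown ramp direction {self.direction!r}")


@dataclass
class ForceDensity:
    """Probability density of a transition force on a uniform grid.

    ``escape_mass`` is the probability that no transition occurred over the
    grid, so trapezoid mass + escape_mass = 1.
    """

    grid_pn: np.ndarray
    density_per_pn: np.ndarray
    escape_mass: float

    def __post_init__(self) -> None:
        self.grid_pn = np.asarray(self.grid_pn, dtype=float)
        self.density_per_pn = np.asarray(self.density_per_pn, dtype=float)
        if self.grid_pn.shape != self.density_per_pn.shape:
            raise GridError("grid and density must have equal shapes")

    @property
    def step_pn(self) -> float:
        return float(self.grid_pn[1] - self.grid_pn[0])

    def mass(self) -> float:
        """Trapezoid integral of the density over its grid."""
        return float(np.trapezoid(self.density_per_pn, self.grid_pn))

    def mean(self) -> float:
        """Mean transition force (conditional on a transition occurring)."""
        m = self.mass()
        if m <= 0:
            raise DomainError("density carries no mass")
        return float(np.trapezoid(self.grid_pn * self.density_per_pn,
                                  self.grid_pn) / m)

    def validate(self, tol: float = 1e-6) -> None:
        if np.any(self.density_per_pn < -1e-300):
            raise DomainError("density must be non-negative")
        total = self.mass() + self.escape_mass
        if abs(total - 1.0) > tol:
            raise DomainError(f"mass + escape = {total} differs from 1 by > {tol}")

    def cdf(self) -> np.ndarray:
        """Cumulative trapezoid integral on the grid."""
        inc = 0.5 * (self.density_per_pn[1:] + self.density_per_pn[:-1]) * np.diff(self.grid_pn)
        return np.concatenate([[0.0], np.cumsum(inc)])


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def rate_unfold(params: TwoStateParams, force_pn,
                temperature_k: float = DEFAULT_TEMPERATURE_K):
    """Force-dependent unfolding rate k0·exp(F·x_fwd/k_BT), 1/s."""
    force = np.asarray(force_pn, dtype=float)
    if np.any(force < 0):
        raise DomainError("force must be >= 0")
    kbt = thermal_energy(temperature_k)
    out = params.k0_per_s * np.exp(force * params.x_fwd_nm / kbt)
    return float(out) if np.isscalar(force_pn) else out


def log_rate_fold(params: TwoStateParams, force_pn,
                  temperature_k: float = DEFAULT_TEMPERATURE_K):
    """Natural log of the folding rate, computed without overflow."""
    force = np.asarray(force_pn, dtype=float)
    kbt = thermal_energy(temperature_k)
    out = (math.log(params.k0_per_s) + params.dG_pn_nm() / kbt
           - force * params.x_rev_nm / kbt)
    return float(out) if np.isscalar(force_pn) else out


def rate_fold(params: TwoStateParams, force_pn,
              temperature_k: float = DEFAULT_TEMPERATURE_K):
    """Force-dependent folding rate k1·exp(−F·x_rev/k_BT), 1/s.

    k1 = k0·exp(ΔG/k_BT) can be astronomically large at zero force; the
    computation is done in log space and only exponentiated at the end.
    """
    force = np.asarray(force_pn, dtype=float)
    if np.any(force < 0):
        raise DomainError("force must be >= 0")
    out = np.exp(log_rate_fold(params, force, temperature_k))
    return float(out) if np.isscalar(force_pn) else out


def coexistence_force(params: TwoStateParams) -> float:
    """Force at which unfolding and folding rates are equal: F* = ΔG/L."""
    return params.dG_pn_nm() / params.L_nm


# ---------------------------------------------------------------------------
# Ramp first-transition densities
# ---------------------------------------------------------------------------

def _grid(ramp: RampSpec, grid_step_pn: float) -> np.ndarray:
    n = int(round((ramp.F_max_pn - ramp.F_start_pn) / grid_step_pn))
    if n < 2:
        raise GridError("force grid must contain at least 2 points")
    return ramp.F_start_pn + grid_step_pn * np.arange(n + 1)


def ramp_density(params: TwoStateParams, ramp: RampSpec,
                 grid_step_pn: float = DEFAULT_GRID_STEP_PN,
                 temperature_k: float = DEFAULT_TEMPERATURE_K,
                 min_mode_bins: int = 5) -> ForceDensity:
    """Closed-form first-transition force density under a linear ramp.

    For a stretch ramp starting folded at F_start the density is
    p_→(F) = (k_→(F)/r)·exp(−(1/r)∫_{F_start}^F k_→),
    with the Bell integral in closed form
    (k0·k_BT)/(r·x_fwd)·(e^{F·x_fwd/k_BT} − e^{F_start·x_fwd/k_BT}).
    A release ramp starts unfolded at F_max and integrates downward with the
    folding rate.  The escape mass is the survival probability at the end of
    the ramp.

    Raises
    ------
    GridError
        If the density mode is narrower than ``min_mode_bins`` grid steps.
    """
    kbt = thermal_energy(temperature_k)
    grid = _grid(ramp, grid_step_pn)
    r = ramp.loading_rate_pn_s
    if ramp.direction == "stretch":
        x = params.x_fwd_nm
        # hazard integral from F_start up to F
        hazard = (params.k0_per_s * kbt) / (r * x) * (
            np.exp(grid * x / kbt) - math.exp(ramp.F_start_pn * x / kbt))
        log_density = (np.log(params.k0_per_s) + grid * x / kbt
                       - math.log(r) - hazard)
        survival_end = math.exp(-float(hazard[-1]))
    else:
        x_rev = params.x_rev_nm
        log_kf = log_rate_fold(params, grid, temperature_k)
        log_kf_max = log_rate_fold(params, ramp.F_max_pn, temperature_k)
        # ∫_F^{F_max} k_fold dF' = (k_BT/x_rev)·(k_fold(F) − k_fold(F_max))
        hazard = (kbt / (r * x_rev)) * (np.exp(log_kf) - math.exp(log_kf_max))
        log_density = log_kf - math.log(r) - hazard
        survival_end = math.exp(-float(hazard[0]))
    density = np.exp(log_density)
    fd = ForceDensity(grid_pn=grid, density_per_pn=density,
                      escape_mass=survival_end)
    _check_mode_resolution(fd, min_mode_bins)
    return fd


def _check_mode_resolution(fd: ForceDensity, min_mode_bins: int) -> None:
    peak = float(fd.density_per_pn.max())
    if peak <= 0:
        return
    above_half = int(np.count_nonzero(fd.density_per_pn > 0.5 * peak))
    # an escape-dominated (monotone, massless) density has no mode to resolve
    if fd.mass() > 1e-3 and above_half < min_mode_bins:
        raise GridError(
            f"density mode spans only {above_half} grid steps "
            f"(< {min_mode_bins}); refine grid_step_pn")


def ode_survival_density(params: TwoStateParams, ramp: RampSpec,
                         grid_step_pn: float = DEFAULT_GRID_STEP_PN,
                         temperature_k: float = DEFAULT_TEMPERATURE_K,
                         rtol: float = 1e-10) -> ForceDensity:
    """Independent oracle: integrate the survival ODE dS/dF = −k(F)/r·S.

    Numerically integrates the first-passage survival equation with
    ``scipy.integrate.solve_ivp`` and returns the transition-force density
    k(F)·S(F)/r on the same grid as :func:`ramp_density`.  Used to
    cross-validate the closed form; not meant for production fitting.
    """
    from scipy.integrate import solve_ivp

    grid = _grid(ramp, grid_step_pn)
    r = ramp.loading_rate_pn_s
    f_lo, f_hi = float(grid[0]), float(grid[-1])
    kbt = thermal_energy(temperature_k)
    # restrict the span to where the hazard is below ~1e5·r: beyond it the
    # integrated hazard exceeds many thousands and survival is exactly 0 in
    # double precision, while the ODE becomes needlessly stiff
    rate_cap = 1e5 * r
    if ramp.direction == "stretch":
        def hazard_rate(force: float) -> float:
            force = min(max(force, f_lo), f_hi)
            return rate_unfold(params, force, temperature_k)
        f_cap = (math.log(rate_cap / params.k0_per_s) * kbt / params.x_fwd_nm)
        stop = min(f_hi, max(f_lo, f_cap))
        span = (f_lo, stop)
        eval_mask = grid <= stop
        eval_grid = grid[eval_mask]
    else:
        log_k1 = math.log(params.k0_per_s) + params.dG_pn_nm() / kbt

        def hazard_rate(force: float) -> float:
            force = min(max(force, f_lo), f_hi)
            return math.exp(min(log_rate_fold(params, force, temperature_k),
                                700.0))
        f_cap = (log_k1 - math.log(rate_cap)) * kbt / params.x_rev_nm
        stop = max(f_lo, min(f_hi, f_cap))
        span = (f_hi, stop)
        eval_mask = grid >= stop
        eval_grid = grid[eval_mask][::-1]

    # dS/dt = −k·S with F = F_start ± r·t, so dS/dF = ∓k/r·S
    sign = -1.0 if ramp.direction == "stretch" else 1.0

    def rhs(force, s):
        return [sign * hazard_rate(float(force)) / r * s[0]]

    sol = solve_ivp(rhs, span, [1.0], t_eval=eval_grid, rtol=rtol,
                    atol=1e-14, method="LSODA")
    survival = np.zeros(len(grid))
    vals = np.clip(sol.y[0], 0.0, None)
    if ramp.direction == "release":
        survival[eval_mask] = vals[::-1]
        escape = float(survival[0])
    else:
        survival[eval_mask] = vals
        escape = float(survival[-1])
    rates = np.array([hazard_rate(float(f)) for f in grid])
    density = np.where(survival > 0, rates * survival / r, 0.0)
    return ForceDensity(grid_pn=grid, density_per_pn=density, escape_mass=escape)


# ---------------------------------------------------------------------------
# Hysteresis distribution
# ---------------------------------------------------------------------------

def hysteresis_density(stretch: ForceDensity, release: ForceDensity) -> ForceDensity:
    """Density of the force hysteresis ΔF = F_unfold − F_fold.

    h(Δ) = ∫ p_→(F)·p_←(F − Δ) dF, the cross-correlation of the two
    first-transition densities, evaluated by FFT on the common uniform step.
    Its total mass is (1 − escape_stretch)·(1 − escape_release); the escape
    mass records the probability that either ramp ended without an event.
    """
    ds, dr = stretch.step_pn, release.step_pn
    if abs(ds - dr) > 1e-9 * max(ds, dr):
        raise GridError(f"incommensurate grid steps {ds} and {dr}")
    step = ds
    # conv(p_s, reversed p_r)[k] = Σ_i p_s[i]·p_r[j] with (i + (Nr-1-j)) = k,
    # i.e. Δ = grid_s[i] − grid_r[j] = grid_s[0] − grid_r[-1] + k·step
    corr = fftconvolve(stretch.density_per_pn, release.density_per_pn[::-1]) * step
    corr = np.clip(corr, 0.0, None)
    delta0 = stretch.grid_pn[0] - release.grid_pn[-1]
    delta_grid = delta0 + step * np.arange(corr.size)
    mass = float(np.trapezoid(corr, delta_grid))
    return ForceDensity(grid_pn=delta_grid, density_per_pn=corr,
                        escape_mass=1.0 - mass)


# ---------------------------------------------------------------------------
# Constant-extension (hopping) rates
# ---------------------------------------------------------------------------

def hopping_rates_at_separation(
        params: TwoStateParams, construct: ConstructModel, separation_nm: float,
        correction: Literal["none", "trap_relaxation"] = "none",
) -> tuple[float, float, float]:
    """Unfolding/folding rates and folded occupancy at fixed trap separation.

    The unfolding rate is evaluated at the folded-branch force, the folding
    rate at the unfolded-branch force (each state sees the tension of its own
    branch).  With ``correction="trap_relaxation"`` the quadratic elastic
    relaxation of the trap over the distance to the barrier is subtracted
    from each tilt: the unfolding exponent becomes
    (F₁·x_fwd − ½k_eff·x_fwd²)/k_BT and the folding exponent
    (−F₂·x_rev − ½k_eff·x_rev²)/k_BT + ΔG/k_BT.

    Returns ``(k_unfold, k_fold, occupancy_folded)`` with
    occupancy_folded = k_fold / (k_fold + k_unfold).
    """
    kbt = thermal_energy(construct.temperature_k)
    f_folded, _ = solve_force_balance(construct, separation_nm, "folded")
    f_unfolded, _ = solve_force_balance(construct, separation_nm, "unfolded")
    log_ku = math.log(params.k0_per_s) + f_folded * params.x_fwd_nm / kbt
    log_kf = log_rate_fold(params, f_unfolded, construct.temperature_k)
    if correction == "trap_relaxation":
        k_eff_f = effective_stiffness(construct, f_folded, "folded")
        k_eff_u = effective_stiffness(construct, f_unfolded, "unfolded")
        log_ku -= 0.5 * k_eff_f * params.x_fwd_nm ** 2 / kbt
        log_kf -= 0.5 * k_eff_u * params.x_rev_nm ** 2 / kbt
    elif correction != "none":
        raise ConfigurationError(f"unknown correction mode {correction!r}")
    k_unfold = math.exp(log_ku)
    k_fold = math.exp(log_kf)
    occupancy = k_fold / (k_fold + k_unfold)
    return k_unfold, k_fold, occupancy


def equal_occupancy_separation(params: TwoStateParams, construct: ConstructModel,
                               correction: Literal["none", "trap_relaxation"] = "none",
                               bracket_nm: tuple[float, float] | None = None) -> float:
    """Trap separation at which folded occupancy is 1/2 (hopping midpoint)."""
    from scipy.optimize import brentq

    def gap(sep: float) -> float:
        k_u, k_f, _ = hopping_rates_at_separation(params, construct, sep, correction)
        return math.log(k_f) - math.log(k_u)

    if bracket_nm is None:
        lc = construct.crystallographic_length_nm
        bracket_nm = (lc * 0.95, lc * 1.45)
    return brentq(gap, *bracket_nm, xtol=1e-6)
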