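"""Weighted hysteresis histograms and the global Bell-Evans fit.

For each molecule all measured unfolding forces are paired with all
measured folding forces to generate every possible hysteresis value
F_unfold − F_fold; each pair of molecule m (u_m unfolds, f_m folds, c_m
cycles performed) carries weight c_m/(u_m·f_m), so a molecule's total
weight is proportional to the number of force cycles actually performed on
it; weights are normalised to one.  The model histogram integrates the
analytic hysteresis density (cross-correlation of the stretch and release
first-transition densities) over the same bins, and the transition-state
distance x_→ and zero-force rate k0 are fitted globally across all pulling
speeds by minimising the summed per-speed root-mean-square bin error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.signal import fftconvolve

from .constants import DEFAULT_TEMPERATURE_K, kj_per_mol_to_pn_nm, thermal_energy
from .errors import DomainError, EmptyDataError, GridError
from .kinetics import RampSpec, TwoStateParams, hysteresis_density, ramp_density

DEFAULT_BIN_WIDTH_PN = 0.5

#: Default search box of the global fit: x_→ in 1–10 nm, k0 in 1e-7–1e-1 1/s.
DEFAULT_X_RANGE_NM = (1.0, 10.0)
DEFAULT_LOG10_K0_RANGE = (-7.0, -1.0)


@dataclass
class HysteresisHistogram:
    """Normalised, cycle-weighted hysteresis histogram at one pulling speed."""

    speed_nm_s: float
    bin_edges_pn: np.ndarray
    weights: np.ndarray
    n_molecules: int
    n_cycles: int

    def __post_init__(self) -> None:
        self.bin_edges_pn = np.asarray(self.bin_edges_pn, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.bin_edges_pn) - 1:
            raise GridError("weights must have one entry per bin")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise DomainError("histogram weights must sum to 1")


@dataclass
class FitResult:
    """Outcome of the global hysteresis fit."""

    x_fwd_hat_nm: float
    k0_hat_per_s: float
    x_fwd_interval_nm: tuple[float, float]
    k0_interval_per_s: tuple[float, float]
    rmse_per_speed: dict[float, float]
    rmse_total: float
    boundary_warning: bool = False


def build_hysteresis_histogram(events: pd.DataFrame, speed_nm_s: float,
                               bin_width_pn: float = DEFAULT_BIN_WIDTH_PN,
                               weighting: str = "cycles",
                               bin_edges_pn: np.ndarray | None = None
                               ) -> HysteresisHistogram:
    """Cycle-weighted histogram of all per-molecule hysteresis pairs.

    ``weighting`` selects the pair-weight strategy: ``"cycles"`` (default)
    gives each of molecule m's u_m·f_m pairs weight c_m/(u_m·f_m);
    ``"pair"`` weights every pair equally; ``"molecule"`` gives every
    molecule equal total weight.
    """
    if weighting not in ("cycles", "pair", "molecule"):
        raise DomainError(f"unknown weighting strategy {weighting!r}")
    sel = events[events["speed_nm_s"] == speed_nm_s]
    deltas, weights = [], []
    n_molecules = 0
    n_cycles = 0
    for _, group in sel.groupby("molecule_id"):
        unfolds = group["F_unfold_pN"].dropna().to_numpy()
        folds = group["F_fold_pN"].dropna().to_numpy()
        cycles = len(group)
        if len(unfolds) == 0 or len(folds) == 0:
            continue
        n_molecules += 1
        n_cycles += cycles
        pair_delta = (unfolds[:, None] - folds[None, :]).ravel()
        if weighting == "cycles":
            w = cycles / pair_delta.size
        elif weighting == "molecule":
            w = 1.0 / pair_delta.size
        else:
            w = 1.0
        deltas.append(pair_delta)
        weights.append(np.full(pair_delta.size, w))
    if not deltas:
        raise EmptyDataError(
            f"no molecule with both unfolding and folding events at "
            f"{speed_nm_s} nm/s")
    deltas = np.concatenate(deltas)
    weights = np.concatenate(weights)
    weights = weights / weights.sum()
    if bin_edges_pn is None:
        lo = math.floor(deltas.min() / bin_width_pn)
        hi = math.ceil(deltas.max() / bin_width_pn)
        if hi == lo:
            hi += 1
        bin_edges_pn = bin_width_pn * np.arange(lo, hi + 1)
    counts, _ = np.histogram(deltas, bins=bin_edges_pn, weights=weights)
    total = counts.sum()
    if total <= 0:
        raise EmptyDataError("all hysteresis values fall outside the bins")
    return HysteresisHistogram(speed_nm_s=speed_nm_s,
                               bin_edges_pn=np.asarray(bin_edges_pn, float),
                               weights=counts / total,
                               n_molecules=n_molecules, n_cycles=n_cycles)


def rmse(model_weights: np.ndarray, data_weights: np.ndarray) -> float:
    """Root-mean-square difference between two equal-length bin vectors."""
    model_weights = np.asarray(model_weights, dtype=float)
    data_weights = np.asarray(data_weights, dtype=float)
    if model_weights.shape != data_weights.shape:
        raise DomainError(
            f"length mismatch: model {model_weights.shape} vs data "
            f"{data_weights.shape}")
    return float(np.sqrt(np.mean((model_weights - data_weights) ** 2)))


def model_histogram(params: TwoStateParams, speed_nm_s: float,
                    k_eff_pn_nm: float, bin_edges_pn: np.ndarray,
                    f_start_pn: float = 0.0, f_max_pn: float = 20.0,
                    grid_step_pn: float = 0.01,
                    temperature_k: float = DEFAULT_TEMPERATURE_K) -> np.ndarray:
    """Model bin weights: the hysteresis density integrated over the bins.

    The stretch and release first-transition densities are evaluated at
    loading rate r = k_eff·v, cross-correlated, integrated over
    ``bin_edges_pn`` and renormalised over that observed support.
    """
    r = k_eff_pn_nm * speed_nm_s
    stretch = ramp_density(params, RampSpec(r, f_start_pn, f_max_pn, "stretch"),
                           grid_step_pn, temperature_k)
    release = ramp_density(params, RampSpec(r, f_start_pn, f_max_pn, "release"),
                           grid_step_pn, temperature_k)
    h = hysteresis_density(stretch, release)
    cdf = h.cdf()
    bin_mass = np.diff(np.interp(bin_edges_pn, h.grid_pn, cdf))
    total = bin_mass.sum()
    if total <= 0:
        raise DomainError("model density carries no mass on the given bins")
    return bin_mass / total


# ---------------------------------------------------------------------------
# Batched model evaluation (vectorised over k0 at fixed x_fwd)
# ---------------------------------------------------------------------------

def _batched_bin_weights(x_fwd_nm: float, k0_array: np.ndarray, L_nm: float,
                         dG_pn_nm: float, loading_rate: float,
                         bin_edges: np.ndarray, f_start: float, f_max: float,
                         grid_step: float, kbt: float) -> np.ndarray:
    """Model bin weights for many k0 values at one x_fwd, shape (n_k0, n_bins).

    Exploits that both Bell hazard integrals are linear in k0, so the grid
    of densities for all k0 follows from two k0-independent profiles.
    """
    n = int(round((f_max - f_start) / grid_step))
    grid = f_start + grid_step * np.arange(n + 1)
    k0 = np.asarray(k0_array, dtype=float)[:, None]
    x_rev = L_nm - x_fwd_nm
    a = x_fwd_nm / kbt
    b = x_rev / kbt
    r = loading_rate

    eaf = np.exp(a * grid)
    hazard_s = (kbt / (r * x_fwd_nm)) * (eaf - math.exp(a * f_start))
    p_stretch = k0 * (eaf / r) * np.exp(-k0 * hazard_s)

    log_c = dG_pn_nm / kbt - b * grid
    c = np.exp(np.minimum(log_c, 700.0))
    hazard_r = (kbt / (r * x_rev)) * (c - c[-1])
    p_release = k0 * (c / r) * np.exp(-k0 * hazard_r)

    corr = fftconvolve(p_stretch, p_release[:, ::-1], axes=1) * grid_step
    corr = np.clip(corr, 0.0, None)
    delta0 = 2.0 * f_start - f_max  # grid_s[0] − grid_r[-1]
    delta_grid = delta0 + grid_step * np.arange(corr.shape[1])

    inc = 0.5 * (corr[:, 1:] + corr[:, :-1]) * grid_step
    cdf = np.concatenate([np.zeros((corr.shape[0], 1)), np.cumsum(inc, axis=1)],
                         axis=1)
    out = np.empty((corr.shape[0], len(bin_edges) - 1))
    for row in range(corr.shape[0]):
        mass = np.diff(np.interp(bin_edges, delta_grid, cdf[row]))
        total = mass.sum()
        out[row] = mass / total if total > 0 else np.nan
    return out


def _objective_components(x_fwd: float, k0_array: np.ndarray,
                          histograms: list[HysteresisHistogram],
                          L_nm: float, dG_pn_nm: float,
                          k_eff_by_speed: dict[float, float],
                          f_start: float, f_max: float, grid_step: float,
                          kbt: float) -> np.ndarray:
    """Summed per-speed rmse for every k0 in ``k0_array`` (vector)."""
    total = np.zeros(len(k0_array))
    for hist in histograms:
        r = k_eff_by_speed[hist.speed_nm_s] * hist.speed_nm_s
        model = _batched_bin_weights(x_fwd, k0_array, L_nm, dG_pn_nm, r,
                                     hist.bin_edges_pn, f_start, f_max,
                                     grid_step, kbt)
        diff = model - hist.weights[None, :]
        bad = np.isnan(diff).any(axis=1)
        diff = np.where(np.isnan(diff), 0.0, diff)
        contrib = np.sqrt(np.mean(diff ** 2, axis=1))
        contrib[bad] = 10.0  # massless model: push the optimiser away
        total += contrib
    return total


def global_fit(histograms: list[HysteresisHistogram], L_nm: float,
               dG_kj_mol: float, k_eff_by_speed: dict[float, float],
               x_range_nm: tuple[float, float] = DEFAULT_X_RANGE_NM,
               log10_k0_range: tuple[float, float] = DEFAULT_LOG10_K0_RANGE,
               n_grid: tuple[int, int] = (60, 60),
               f_start_pn: float = 0.0, f_max_pn: float = 20.0,
               scan_grid_step_pn: float = 0.05,
               refine_grid_step_pn: float = 0.01,
               temperature_k: float = DEFAULT_TEMPERATURE_K,
               profile_cut: float = 1.1) -> FitResult:
    """Global fit of x_→ and k0 across pulling speeds.

    A coarse log10(k0) × x_→ grid scan locates the basin of the summed
    per-speed rmse; a Nelder-Mead refinement polishes the optimum on a
    finer force grid.  Uncertainty intervals are the parameter extents of
    the region where the scanned objective stays below ``profile_cut``
    times its minimum.  L and ΔG are fixed inputs (measured / predicted
    elsewhere), as are the per-speed effective stiffnesses.
    """
    if not histograms:
        raise EmptyDataError("global_fit needs at least one histogram")
    missing = [h.speed_nm_s for h in histograms
               if h.speed_nm_s not in k_eff_by_speed]
    if missing:
        raise DomainError(f"k_eff missing for speeds {missing}")
    kbt = thermal_energy(temperature_k)
    dg = kj_per_mol_to_pn_nm(dG_kj_mol)
    x_grid = np.linspace(x_range_nm[0], x_range_nm[1], n_grid[0])
    # keep x below L (x_rev must stay positive)
    x_grid = x_grid[x_grid < 0.98 * L_nm]
    logk_grid = np.linspace(log10_k0_range[0], log10_k0_range[1], n_grid[1])
    k0_grid = 10.0 ** logk_grid

    surface = np.empty((len(x_grid), len(k0_grid)))
    for i, x in enumerate(x_grid):
        surface[i] = _objective_components(float(x), k0_grid, histograms,
                                           L_nm, dg, k_eff_by_speed,
                                           f_start_pn, f_max_pn,
                                           scan_grid_step_pn, kbt)
    i_best, j_best = np.unravel_index(np.nanargmin(surface), surface.shape)
    x0, logk0 = float(x_grid[i_best]), float(logk_grid[j_best])

    def fine_objective(theta: np.ndarray) -> float:
        x, logk = float(theta[0]), float(theta[1])
        if not (x_range_nm[0] <= x <= min(x_range_nm[1], 0.98 * L_nm)):
            return 1e6
        if not (log10_k0_range[0] <= logk <= log10_k0_range[1]):
            return 1e6
        return float(_objective_components(
            x, np.array([10.0 ** logk]), histograms, L_nm, dg,
            k_eff_by_speed, f_start_pn, f_max_pn, refine_grid_step_pn, kbt)[0])

    res = minimize(fine_objective, np.array([x0, logk0]),
                   method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-8, "maxiter": 400})
    x_hat, logk_hat = float(res.x[0]), float(res.x[1])
    rmse_total = float(res.fun)

    # profile intervals from the scanned surface (plus the refined point)
    cut = profile_cut * min(rmse_total, float(np.nanmin(surface)))
    inside = surface <= cut
    if inside.any():
        xi, ki = np.nonzero(inside)
        x_lo = min(float(x_grid[xi.min()]), x_hat)
        x_hi = max(float(x_grid[xi.max()]), x_hat)
        k_lo = min(float(k0_grid[ki.min()]), 10.0 ** logk_hat)
        k_hi = max(float(k0_grid[ki.max()]), 10.0 ** logk_hat)
    else:
        x_lo = x_hi = x_hat
        k_lo = k_hi = 10.0 ** logk_hat
    boundary = (i_best in (0, len(x_grid) - 1)
                or j_best in (0, len(k0_grid) - 1))

    per_speed = {}
    k0_hat = 10.0 ** logk_hat
    for hist in histograms:
        r = k_eff_by_speed[hist.speed_nm_s] * hist.speed_nm_s
        model = _batched_bin_weights(x_hat, np.array([k0_hat]), L_nm, dg, r,
                                     hist.bin_edges_pn, f_start_pn, f_max_pn,
                                     refine_grid_step_pn, kbt)[0]
        per_speed[hist.speed_nm_s] = rmse(model, hist.weights)
    return FitResult(x_fwd_hat_nm=x_hat, k0_hat_per_s=k0_hat,
                     x_fwd_interval_nm=(x_lo, x_hi),
                     k0_interval_per_s=(k_lo, k_hi),
                     rmse_per_speed=per_speed, rmse_total=rmse_total,
                     boundary_warning=bool(boundary))
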