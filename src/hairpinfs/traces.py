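"""Event recovery and summary statistics from force traces.

Ruptures and refolds appear as sudden force jumps (drops on unfolding,
rises on folding) riding on the smooth elastic response; hopping traces at
constant extension show two force levels.  This module detects those
events, converts force jumps into transition lengths, builds Gaussian
force histograms (most probable forces), and extracts dwell-time
statistics with a Schmitt-trigger state assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.optimize import curve_fit

from .elasticity import ConstructModel, construct_extension, effective_stiffness
from .errors import (AssignmentError, DomainError, EmptyDataError,
                     StatisticsError)
from .simulate import FOLDED, Trace, UNFOLDED

#: FWHM of a Gaussian in units of its standard deviation.
FWHM_PER_SIGMA = 2.3548

#: Analysis defaults: the published force jumps are ~1 pN and the force
#: histograms ~2.5 pN FWHM, which set these scales.
DEFAULT_MIN_JUMP_PN = 0.5
DEFAULT_WINDOW_SAMPLES = 5
DEFAULT_BIN_WIDTH_PN = 0.5
DEFAULT_DEADBAND_PN = 0.3


@dataclass
class ForceHistogram:
    """Binned transition forces with a Gaussian least-squares fit."""

    bin_edges_pn: np.ndarray
    counts: np.ndarray
    gaussian_mu_pn: float
    gaussian_sigma_pn: float
    n_events: int

    @property
    def fwhm_pn(self) -> float:
        return FWHM_PER_SIGMA * self.gaussian_sigma_pn


@dataclass
class DwellSummary:
    """Dwell-time statistics of a constant-extension hopping trace."""

    separation_nm: float
    dwells_folded_s: list[float]
    dwells_unfolded_s: list[float]
    mean_folded_s: float
    mean_unfolded_s: float
    occupancy_folded: float
    level_folded_pn: float
    level_unfolded_pn: float


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def detect_events(trace: Trace, min_jump_pn: float = DEFAULT_MIN_JUMP_PN,
                  window: int = DEFAULT_WINDOW_SAMPLES,
                  first_event_only: bool = False) -> pd.DataFrame:
    """Detect sudden force jumps in a ramp trace.

    The force is median-filtered over ``window`` samples; an event is
    flagged where the filtered force changes by at least ``min_jump_pn``
    within at most ``window`` samples and the level shift is confirmed by
    comparing medians over 3·window samples on either side.  Drops are
    unfolding events, rises are folding events, in either ramp phase.  The
    event force is the pre-jump level.

    With ``first_event_only`` only the first unfolding on the stretch phase
    and the first folding on the release phase are kept — the convention
    used for flipping traces.

    Returns a DataFrame with columns index, time_s, phase, kind, force_pn.
    """
    n = len(trace.force_pn)
    if n == 0:
        raise EmptyDataError("empty trace")
    if n <= 8 * window:
        return _empty_events()
    filt = median_filter(trace.force_pn, size=window, mode="nearest")
    sep_slope = np.gradient(trace.separation_nm)
    phase = np.where(sep_slope >= 0, "stretch", "release")

    diff = filt[window:] - filt[:-window]  # change across `window` samples
    cand = np.flatnonzero(np.abs(diff) >= min_jump_pn)
    events = []
    w3 = 3 * window
    for cluster in _clusters(cand, gap=window):
        i = cluster[int(np.argmax(np.abs(diff[cluster])))]
        lo = max(0, i - w3)
        hi = min(n, i + window + w3)
        pre = float(np.median(filt[lo:i + 1]))
        post = float(np.median(filt[i + window:hi]))
        jump = post - pre
        if abs(jump) < min_jump_pn:
            continue
        kind = "unfold" if jump < 0 else "fold"
        events.append((i, float(trace.time_s[i]), str(phase[i]), kind,
                       pre, abs(jump)))
    df = pd.DataFrame(events, columns=["index", "time_s", "phase", "kind",
                                       "force_pn", "jump_pn"])
    if first_event_only and not df.empty:
        keep = []
        unfold = df[(df.kind == "unfold") & (df.phase == "stretch")]
        fold = df[(df.kind == "fold") & (df.phase == "release")]
        if not unfold.empty:
            keep.append(unfold.iloc[[0]])
        if not fold.empty:
            keep.append(fold.iloc[[0]])
        df = (pd.concat(keep, ignore_index=True) if keep else _empty_events())
    return df


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(columns=["index", "time_s", "phase", "kind",
                                 "force_pn", "jump_pn"])


def _clusters(indices: np.ndarray, gap: int) -> list[np.ndarray]:
    if indices.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(indices) > gap)
    return np.split(indices, breaks + 1)


def transition_length(trace: Trace, event_index: int,
                      construct: ConstructModel,
                      mode: str = "force_jump",
                      window: int = DEFAULT_WINDOW_SAMPLES,
                      per_nt_extension_nm: float | None = None) -> float:
    """Transition length L from one detected event, nm.

    ``mode="force_jump"``: L = |ΔF| / k_eff at the event force (folded
    branch).  ``mode="branch"``: separation-axis distance between the
    folded and unfolded branches at the event force — the released strand's
    extension minus the folded hairpin width; ``per_nt_extension_nm``
    overrides the freely-jointed-chain extension with a calibrated value.
    """
    filt = median_filter(trace.force_pn, size=window, mode="nearest")
    n = len(filt)
    i = int(event_index)
    lo, hi = max(0, i - 3 * window), min(n, i + 4 * window)
    # exclude the +/- window mixing zone of the median filter around i
    pre_idx = np.arange(lo, max(lo + 1, i - window + 1))
    post_idx = np.arange(min(i + window, n - 1), hi)
    pre = float(np.median(filt[pre_idx]))
    # remove the smooth ramp slope so only the discontinuity is measured
    if len(pre_idx) >= 3:
        slope = float(np.polyfit(pre_idx, filt[pre_idx], 1)[0])
    else:
        slope = 0.0
    post = float(np.median(filt[post_idx]))
    expected_post = pre + slope * (float(np.mean(post_idx)) -
                                   float(np.median(pre_idx)))
    jump = abs(post - expected_post)
    if jump < 1e-12:
        return 0.0
    if mode == "force_jump":
        k_eff = effective_stiffness(construct, pre, "folded")
        return jump / k_eff
    if mode == "branch":
        if per_nt_extension_nm is not None:
            released = construct.ss_released.n_nt * per_nt_extension_nm
        else:
            released = construct_extension(construct, pre, "unfolded")["hairpin"]
        return released - construct.folded_width_nm
    raise DomainError(f"unknown transition_length mode {mode!r}")


# ---------------------------------------------------------------------------
# Force histograms and transition force
# ---------------------------------------------------------------------------

def _gaussian(x, amplitude, mu, sigma):
    return amplitude * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_force_histogram(forces: np.ndarray,
                        bin_width_pn: float = DEFAULT_BIN_WIDTH_PN,
                        min_events: int = 10) -> ForceHistogram:
    """Bin forces and fit a Gaussian to the counts by least squares.

    The most probable force is the fitted mean; bins with zero counts are
    part of the fit.  Raises :class:`StatisticsError` below ``min_events``.
    """
    forces = np.asarray(forces, dtype=float)
    forces = forces[np.isfinite(forces)]
    if len(forces) < min_events:
        raise StatisticsError(
            f"need at least {min_events} events for a force histogram, "
            f"got {len(forces)}")
    lo = math.floor(forces.min() / bin_width_pn) - 1
    hi = math.ceil(forces.max() / bin_width_pn) + 1
    edges = bin_width_pn * np.arange(lo, hi + 1)
    counts, _ = np.histogram(forces, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mu0, sigma0 = float(forces.mean()), float(max(forces.std(), bin_width_pn / 2))
    if np.ptp(forces) < 1e-12:
        # degenerate: all events identical
        return ForceHistogram(edges, counts, mu0, 0.0, len(forces))
    p0 = [float(counts.max()), mu0, sigma0]
    popt, _ = curve_fit(_gaussian, centers, counts, p0=p0, maxfev=10000)
    return ForceHistogram(edges, counts, float(popt[1]), abs(float(popt[2])),
                          len(forces))


def most_probable_forces(events: pd.DataFrame, speed_nm_s: float,
                         bin_width_pn: float = DEFAULT_BIN_WIDTH_PN,
                         min_events: int = 10
                         ) -> tuple[ForceHistogram, ForceHistogram]:
    """Gaussian-fitted unfolding and folding force histograms at one speed."""
    sel = events[events["speed_nm_s"] == speed_nm_s]
    unfold = fit_force_histogram(sel["F_unfold_pN"].to_numpy(), bin_width_pn,
                                 min_events)
    fold = fit_force_histogram(sel["F_fold_pN"].to_numpy(), bin_width_pn,
                               min_events)
    return unfold, fold


def transition_force(unfold_mu_pn: float, fold_mu_pn: float) -> float:
    """Mean transition force F_t: average of most probable unfold/fold forces."""
    if not (math.isfinite(unfold_mu_pn) and math.isfinite(fold_mu_pn)):
        raise DomainError("both forces must be finite")
    return 0.5 * (unfold_mu_pn + fold_mu_pn)


# ---------------------------------------------------------------------------
# Dwell-time analysis
# ---------------------------------------------------------------------------

def dwell_analysis(trace: Trace, deadband_pn: float = DEFAULT_DEADBAND_PN,
                   min_dwell_samples: int = 3) -> DwellSummary:
    """Two-level dwell statistics of a constant-extension hopping trace.

    The two force levels are located by a 1-d two-means split of the force
    samples; they must be separated by at least 2·deadband.  States are
    assigned by a Schmitt trigger around the midpoint (±deadband), brief
    excursions shorter than ``min_dwell_samples`` are absorbed into the
    surrounding dwell, and the censored first and last dwells are excluded
    from the mean dwell times.  The folded state is the high-force level.
    """
    force = np.asarray(trace.force_pn, dtype=float)
    if len(force) == 0:
        raise EmptyDataError("empty trace")
    if float(np.ptp(trace.separation_nm)) > 1.0:
        raise DomainError("dwell_analysis requires a constant-separation trace")
    lo_level, hi_level = _two_means(force)
    if hi_level - lo_level < 2 * deadband_pn:
        raise AssignmentError(
            f"force levels {lo_level:.3g} and {hi_level:.3g} pN are not "
            f"separated by 2·deadband = {2 * deadband_pn:.3g} pN")
    mid = 0.5 * (lo_level + hi_level)
    assigned = _schmitt(force, mid - deadband_pn, mid + deadband_pn)
    assigned = _absorb_short_runs(assigned, min_dwell_samples)

    dt = float(trace.time_s[1] - trace.time_s[0]) if len(force) > 1 else 0.0
    runs = _runs(assigned)
    interior = runs[1:-1] if len(runs) > 2 else []
    dwells_folded = [r_len * dt for val, r_len in interior if val == FOLDED]
    dwells_unfolded = [r_len * dt for val, r_len in interior if val == UNFOLDED]
    occupancy = float(np.mean(assigned == FOLDED))
    return DwellSummary(
        separation_nm=float(trace.separation_nm[0]),
        dwells_folded_s=dwells_folded, dwells_unfolded_s=dwells_unfolded,
        mean_folded_s=float(np.mean(dwells_folded)) if dwells_folded else math.nan,
        mean_unfolded_s=float(np.mean(dwells_unfolded)) if dwells_unfolded else math.nan,
        occupancy_folded=occupancy,
        level_folded_pn=hi_level, level_unfolded_pn=lo_level)


def _two_means(force: np.ndarray, n_iter: int = 50) -> tuple[float, float]:
    """Lloyd iteration with two centroids on 1-d force samples."""
    lo, hi = float(np.percentile(force, 10)), float(np.percentile(force, 90))
    if hi - lo < 1e-12:
        return lo, hi
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        low_mask = force < mid
        if not low_mask.any() or low_mask.all():
            break
        new_lo = float(force[low_mask].mean())
        new_hi = float(force[~low_mask].mean())
        if abs(new_lo - lo) < 1e-9 and abs(new_hi - hi) < 1e-9:
            lo, hi = new_lo, new_hi
            break
        lo, hi = new_lo, new_hi
    return lo, hi


def _schmitt(force: np.ndarray, low_thresh: float, high_thresh: float
             ) -> np.ndarray:
    """Hysteretic two-state assignment; folded (0) is the high level."""
    marks = np.zeros(len(force), dtype=np.int8)
    marks[force > high_thresh] = 1   # decided folded (high force)
    marks[force < low_thresh] = -1   # decided unfolded
    decided = np.flatnonzero(marks)
    state = np.empty(len(force), dtype=np.int8)
    if decided.size == 0:
        state[:] = FOLDED
        return state
    # forward-fill decisions; before the first decision, use it backwards
    current = FOLDED if marks[decided[0]] == 1 else UNFOLDED
    state[:decided[0]] = current
    idx = decided[0]
    for j in decided:
        value = FOLDED if marks[j] == 1 else UNFOLDED
        state[idx:j] = current
        current = value
        idx = j
    state[idx:] = current
    return state


def _absorb_short_runs(state: np.ndarray, min_len: int) -> np.ndarray:
    out = state.copy()
    changed = True
    while changed:
        changed = False
        runs = _runs(out)
        pos = 0
        for k, (val, r_len) in enumerate(runs):
            if 0 < k < len(runs) - 1 and r_len < min_len:
                out[pos:pos + r_len] = runs[k - 1][0]
                changed = True
                break
            pos += r_len
    return out


def _runs(state: np.ndarray) -> list[tuple[int, int]]:
    """Run-length encoding: list of (value, length)."""
    if len(state) == 0:
        return []
    boundaries = np.flatnonzero(np.diff(state)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(state)]])
    return [(int(state[s]), int(e - s)) for s, e in zip(starts, ends)]
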