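"""Stochastic simulation of stretch/release cycles and constant-extension hopping.

This module stands in for the instrument: it produces force/extension traces
and event tables with exactly the statistical structure the inference
assumes — a two-state Markov chain with Bell rates driven by the
instantaneous state-dependent tension, an effective-stiffness mapping from
pulling speed to force loading rate, and additive Gaussian measurement
noise on the recorded force.

Two levels of fidelity are provided:

* event-level: the jump chain is sampled *exactly* in the force domain by
  analytic inversion of the time-integrated Bell hazard under a linear
  ramp (no step-size bias in first-passage forces); this is what
  :func:`generate_event_tables` uses and what the hysteresis fit consumes;
* trace-level: :func:`simulate_ramp_cycle` renders full sampled traces,
  with the latent state evolving by inverse-transform sampling on the
  cumulative hazard of the state-dependent branch forces along the actual
  triangular separation protocol.

Randomness: one independent stream per molecule, derived from the master
seed by a counter-based split, so per-molecule reproducibility survives
reordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import thermal_energy
from .elasticity import ConstructModel, effective_stiffness, force_vs_separation, \
    solve_force_balance
from .errors import ConfigurationError, DomainError
from .kinetics import (TwoStateParams, coexistence_force,
                       hopping_rates_at_separation, log_rate_fold, rate_unfold)

FOLDED, UNFOLDED = 0, 1


@dataclass
class Trace:
    """A sampled force/extension record with the latent state retained."""

    time_s: np.ndarray
    separation_nm: np.ndarray
    force_pn: np.ndarray
    state: np.ndarray  # 0 = folded, 1 = unfolded (latent truth)

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if not (len(self.separation_nm) == len(self.force_pn)
                == len(self.state) == n):
            raise DomainError("trace arrays must have equal lengths")
        if n > 1 and not np.all(np.diff(self.time_s) > 0):
            raise DomainError("trace time must be strictly increasing")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror the reference protocol: pulling speeds 50–450 nm/s,
    triangular ramps up to relative extension 1.4, 0.2 pN Gaussian force
    noise, 1 kHz sampling.  The seed is mandatory — no hidden global state.
    """

    params: TwoStateParams
    construct: ConstructModel
    seed: int
    speeds_nm_s: tuple[float, ...] = (50.0, 150.0, 300.0, 450.0)
    cycles_per_molecule: int = 4
    n_molecules: int = 10
    noise_sd_pn: float = 0.2
    sample_rate_hz: float = 1000.0
    f_start_pn: float = 0.0
    f_max_pn: float = 20.0
    rel_extension_start: float = 0.95
    rel_extension_max: float = 1.4

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.speeds_nm_s):
            raise ConfigurationError("all speeds must be > 0")
        if self.sample_rate_hz <= 0:
            raise ConfigurationError("sample_rate_hz must be > 0")
        if self.noise_sd_pn < 0:
            raise ConfigurationError("noise_sd_pn must be >= 0")
        if self.cycles_per_molecule < 0 or self.n_molecules < 0:
            raise ConfigurationError("counts must be >= 0")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed must be an explicit integer")

    def molecule_rng(self, molecule_index: int) -> np.random.Generator:
        """Independent, reorder-safe RNG stream for one molecule."""
        return np.random.default_rng(
            np.random.SeedSequence((self.seed, molecule_index)))


def loading_rate_pn_s(params: TwoStateParams, construct: ConstructModel,
                      speed_nm_s: float) -> float:
    """Loading rate r = k_eff·v with k_eff frozen at a reference force.

    The elasticities of traps, handles and construct are lumped into one
    effective stiffness evaluated (folded branch) at the coexistence force
    ΔG/L, the centre of the transition region; freezing k_eff makes the
    force ramp linear in time, the regime in which the first-transition
    densities have their closed form.
    """
    f_ref = coexistence_force(params)
    k_eff = effective_stiffness(construct, f_ref, "folded")
    return k_eff * speed_nm_s


# ---------------------------------------------------------------------------
# Exact force-domain jump chain under a linear ramp
# ---------------------------------------------------------------------------

def _next_stretch_event(params: TwoStateParams, state: int, f_now: float,
                        f_max: float, r: float, kbt: float,
                        rng: np.random.Generator) -> float | None:
    """Force of the next transition on a stretch leg, or None if censored."""
    e = rng.exponential()
    if state == FOLDED:
        a = params.x_fwd_nm / kbt
        f_next = np.logaddexp(a * f_now,
                              math.log(e * r * a / params.k0_per_s)) / a
        return float(f_next) if f_next <= f_max else None
    b = params.x_rev_nm / kbt
    log_k1 = math.log(params.k0_per_s) + params.dG_pn_nm() / kbt
    t = math.exp(math.log(e * r * b) - log_k1)
    rhs = math.exp(-b * f_now) - t
    if rhs <= math.exp(-b * f_max) or rhs <= 0.0:
        return None
    return -math.log(rhs) / b


def _next_release_event(params: TwoStateParams, state: int, f_now: float,
                        f_end: float, r: float, kbt: float,
                        rng: np.random.Generator) -> float | None:
    """Force of the next transition on a release leg, or None if censored."""
    e = rng.exponential()
    if state == UNFOLDED:
        b = params.x_rev_nm / kbt
        log_k1 = math.log(params.k0_per_s) + params.dG_pn_nm() / kbt
        f_next = -np.logaddexp(-b * f_now,
                               math.log(e * r * b) - log_k1) / b
        return float(f_next) if f_next >= f_end else None
    a = params.x_fwd_nm / kbt
    rhs = math.exp(a * f_now) - e * r * a / params.k0_per_s
    if rhs <= math.exp(a * f_end) or rhs <= 0.0:
        return None
    return math.log(rhs) / a


def simulate_cycle_events(params: TwoStateParams, loading_rate: float,
                          f_start: float, f_max: float,
                          rng: np.random.Generator,
                          temperature_k: float,
                          initial_state: int = FOLDED
                          ) -> tuple[list[tuple[float, int]], list[tuple[float, int]]]:
    """Exact transition forces over one stretch+release cycle.

    Returns two lists of ``(force, new_state)``: transitions on the stretch
    leg (force rising from f_start to f_max) and on the release leg (force
    falling from f_max back to f_start).
    """
    kbt = thermal_energy(temperature_k)
    state, f_now = initial_state, f_start
    stretch: list[tuple[float, int]] = []
    while True:
        nxt = _next_stretch_event(params, state, f_now, f_max, loading_rate,
                                  kbt, rng)
        if nxt is None:
            break
        state = UNFOLDED if state == FOLDED else FOLDED
        stretch.append((nxt, state))
        f_now = nxt
    release: list[tuple[float, int]] = []
    f_now = f_max
    while True:
        nxt = _next_release_event(params, state, f_now, f_start, loading_rate,
                                  kbt, rng)
        if nxt is None:
            break
        state = UNFOLDED if state == FOLDED else FOLDED
        release.append((nxt, state))
        f_now = nxt
    return stretch, release


def generate_event_tables(config: SimulationConfig) -> pd.DataFrame:
    """Run all molecules × speeds × cycles and extract per-cycle event forces.

    Per cycle the *first* unfolding force on the stretch leg and the *first*
    folding force on the release leg are recorded (the convention used for
    flipping traces); recorded forces carry the configured Gaussian
    measurement noise.  Missing events (no transition before the leg ended)
    are NaN.  Columns: molecule_id, speed_nm_s, cycle, F_unfold_pN,
    F_fold_pN, n_flips, first_event_only.
    """
    t = config.construct.temperature_k
    rows = []
    for mol in range(config.n_molecules):
        rng = config.molecule_rng(mol)
        for speed in config.speeds_nm_s:
            r = loading_rate_pn_s(config.params, config.construct, speed)
            for cyc in range(config.cycles_per_molecule):
                stretch, release = simulate_cycle_events(
                    config.params, r, config.f_start_pn, config.f_max_pn,
                    rng, t)
                f_unfold = next((f for f, s in stretch if s == UNFOLDED),
                                math.nan)
                f_fold = next((f for f, s in release if s == FOLDED),
                              math.nan)
                if config.noise_sd_pn > 0:
                    if not math.isnan(f_unfold):
                        f_unfold += config.noise_sd_pn * rng.standard_normal()
                    if not math.isnan(f_fold):
                        f_fold += config.noise_sd_pn * rng.standard_normal()
                rows.append((mol, speed, cyc, f_unfold, f_fold,
                             len(stretch) + len(release), True))
    return pd.DataFrame(rows, columns=[
        "molecule_id", "speed_nm_s", "cycle", "F_unfold_pN", "F_fold_pN",
        "n_flips", "first_event_only"])


# ---------------------------------------------------------------------------
# Trace-level simulation
# ---------------------------------------------------------------------------

def _branch_force_tables(config: SimulationConfig, s_lo: float, s_hi: float,
                         n: int = 256) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    grid = np.linspace(s_lo, s_hi, n)
    f_folded = force_vs_separation(config.construct, grid, "folded")
    f_unfolded = force_vs_separation(config.construct, grid, "unfolded")
    return grid, f_folded, f_unfolded


def simulate_ramp_cycle(config: SimulationConfig, speed_nm_s: float,
                        rng: np.random.Generator | None = None,
                        oversample: int = 10) -> Trace:
    """One triangular stretch/release cycle as a sampled trace.

    The trap separation rises at constant speed from ``rel_extension_start``
    to ``rel_extension_max`` times the crystallographic length and returns.
    The latent state evolves as a time-inhomogeneous two-state Markov chain
    whose rates follow the instantaneous state-dependent branch force;
    transitions are drawn by inverse-transform sampling on the cumulative
    hazard evaluated on a grid ``oversample`` times finer than the sample
    rate.  Measured force = branch force + Gaussian noise.
    """
    if rng is None:
        rng = config.molecule_rng(0)
    model = config.construct
    lc = model.crystallographic_length_nm
    s_lo = config.rel_extension_start * lc
    s_hi = config.rel_extension_max * lc
    t_leg = (s_hi - s_lo) / speed_nm_s
    dt = 1.0 / config.sample_rate_hz
    n_leg = max(int(round(t_leg / dt)), 2)
    time = dt * np.arange(2 * n_leg)
    sep = np.concatenate([s_lo + speed_nm_s * time[:n_leg],
                          s_hi - speed_nm_s * (time[n_leg:] - time[n_leg - 1])])
    sep = np.clip(sep, s_lo, s_hi)

    grid, f_folded_tab, f_unfolded_tab = _branch_force_tables(config, s_lo, s_hi)

    # fine grid for hazard integration
    dt_f = dt / oversample
    time_f = dt_f * np.arange(2 * n_leg * oversample)
    sep_f = np.interp(time_f, time, sep)
    f_folded_f = np.interp(sep_f, grid, f_folded_tab)
    f_unfolded_f = np.interp(sep_f, grid, f_unfolded_tab)
    t_k = model.temperature_k
    k_unf = rate_unfold(config.params, f_folded_f, t_k)
    k_fold = np.exp(np.minimum(log_rate_fold(config.params, f_unfolded_f, t_k),
                               700.0))
    cum_u = np.cumsum(k_unf) * dt_f
    cum_f = np.cumsum(k_fold) * dt_f

    switches: list[float] = []
    state = FOLDED
    idx = 0
    n_f = len(time_f)
    while idx < n_f:
        cum = cum_u if state == FOLDED else cum_f
        base = cum[idx - 1] if idx > 0 else 0.0
        target = base + rng.exponential()
        j = int(np.searchsorted(cum, target))
        if j >= n_f:
            break
        switches.append(time_f[j])
        state = UNFOLDED if state == FOLDED else FOLDED
        idx = j + 1

    state_arr = np.zeros(len(time), dtype=np.int8)
    if switches:
        s = FOLDED
        start = 0
        for b in list(np.searchsorted(time, switches)) + [len(time)]:
            state_arr[start:b] = s
            s = UNFOLDED if s == FOLDED else FOLDED
            start = b
    f_folded_s = np.interp(sep, grid, f_folded_tab)
    f_unfolded_s = np.interp(sep, grid, f_unfolded_tab)
    force = np.where(state_arr == FOLDED, f_folded_s, f_unfolded_s)
    if config.noise_sd_pn > 0:
        force = force + config.noise_sd_pn * rng.standard_normal(len(force))
    return Trace(time_s=time, separation_nm=sep, force_pn=force,
                 state=state_arr)


def simulate_constant_extension(config: SimulationConfig, separation_nm: float,
                                duration_s: float,
                                rng: np.random.Generator | None = None,
                                initial_state: int | None = None,
                                correction: str = "none") -> Trace:
    """Two-state hopping at fixed trap separation.

    Dwell times are exponential with the constant rates of
    :func:`hopping_rates_at_separation`; the recorded force alternates
    between the two branch levels plus measurement noise.
    """
    if duration_s <= 0:
        raise DomainError("duration_s must be > 0")
    if rng is None:
        rng = config.molecule_rng(0)
    k_u, k_f, occupancy = hopping_rates_at_separation(
        config.params, config.construct, separation_nm, correction)
    f_folded, _ = solve_force_balance(config.construct, separation_nm, "folded")
    f_unfolded, _ = solve_force_balance(config.construct, separation_nm,
                                        "unfolded")
    if initial_state is None:
        initial_state = FOLDED if rng.random() < occupancy else UNFOLDED
    switch_times = []
    t_now, state = 0.0, initial_state
    while t_now < duration_s:
        rate = k_u if state == FOLDED else k_f
        t_now += rng.exponential(1.0 / rate) if rate > 0 else math.inf
        if t_now >= duration_s:
            break
        switch_times.append(t_now)
        state = UNFOLDED if state == FOLDED else FOLDED

    dt = 1.0 / config.sample_rate_hz
    time = dt * np.arange(int(math.ceil(duration_s / dt)))
    state_arr = np.full(len(time), initial_state, dtype=np.int8)
    s = initial_state
    start = 0
    for b in np.searchsorted(time, switch_times):
        state_arr[start:b] = s
        s = UNFOLDED if s == FOLDED else FOLDED
        start = b
    state_arr[start:] = s
    force = np.where(state_arr == FOLDED, f_folded, f_unfolded)
    if config.noise_sd_pn > 0:
        force = force + config.noise_sd_pn * rng.standard_normal(len(force))
    return Trace(time_s=time, separation_nm=np.full(len(time), separation_nm),
                 force_pn=force, state=state_arr)
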