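"""Sequence-based unfolding free-energy landscapes and energy bookkeeping.

The hairpin stem opens sequentially from the bottom; the landscape
G(n_open) accumulates the nearest-neighbour cost of each opened base pair,
releases the loop on the final step, and — under force — subtracts the
stretching free energy ∫_0^F x_ss(f) df of the released single strand
(two nucleotides per opened pair, plus the loop at full opening).  The model
is deliberately non-cooperative: each pair opens independently at its
sequence-determined cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np

from .constants import (DEFAULT_TEMPERATURE_K, kj_per_mol_to_pn_nm,
                        pn_nm_to_kj_per_mol)
from .elasticity import FJCParams, SS_DEFAULTS, fjc_extension, fjc_stretch_free_energy
from .errors import DomainError, SequenceError
from . import nn_tables

#: Default 13-mer stem, 5'→3' bottom to top: ~50% GC with three G·C pairs at
#: the bottom of the stem (T replaced by U for RNA hairpins).
DEFAULT_STEM_5P = "GCGATACTAGTAC"


@dataclass(frozen=True)
class HairpinSpec:
    """A stem-loop hairpin: stem sequence, loop length, chemistry.

    ``per_bp_energies_kj_mol`` optionally overrides the built-in
    nearest-neighbour opening energies (one value per base pair, bottom to
    top; the last entry is the pairing cost of the terminal pair before loop
    release).  ``loop_init_energy_kj_mol`` optionally overrides the net
    free-energy change of the final opening step (loop entropy regained
    minus duplex-end initiation); by default it is computed from the tables.
    """

    stem_seq_5p: str = DEFAULT_STEM_5P
    loop_length: int = 10
    chemistry: str = "DNA"
    per_bp_energies_kj_mol: tuple[float, ...] | None = None
    loop_init_energy_kj_mol: float | None = None

    def __post_init__(self) -> None:
        if len(self.stem_seq_5p) < 1:
            raise SequenceError("stem must contain at least one base pair")
        if self.loop_length < 3:
            raise SequenceError("loop_length must be >= 3")
        if self.chemistry.upper() not in ("DNA", "RNA"):
            raise SequenceError(f"unknown chemistry {self.chemistry!r}")
        alphabet = "ACGU" if self.chemistry.upper() == "RNA" else "ACGT"
        bad = sorted(set(self.stem_seq_5p.upper()) - set(alphabet))
        if bad:
            raise SequenceError(
                f"bases {bad} not allowed in a {self.chemistry} stem")
        if (self.per_bp_energies_kj_mol is not None
                and len(self.per_bp_energies_kj_mol) != self.n_bp):
            raise SequenceError(
                f"per_bp_energies_kj_mol must have {self.n_bp} entries")

    @property
    def n_bp(self) -> int:
        return len(self.stem_seq_5p)

    @property
    def n_nt_released(self) -> int:
        """Nucleotides under tension once fully unfolded: 2·stem + loop."""
        return 2 * self.n_bp + self.loop_length

    def ss_elasticity(self) -> FJCParams:
        """Chemistry-default single-strand elasticity, n_nt = 0 placeholder."""
        return SS_DEFAULTS[self.chemistry.upper()]


def per_bp_opening_energies(spec: HairpinSpec,
                            temperature_k: float = DEFAULT_TEMPERATURE_K
                            ) -> np.ndarray:
    """Opening cost of each base pair (bottom to top), kJ/mol, positive.

    Pair i (i < N) carries the stack free energy between pairs i and i+1;
    the terminal pair carries no stack (its loop-release bookkeeping lives
    in the loop/initiation term).
    """
    if spec.per_bp_energies_kj_mol is not None:
        return np.asarray(spec.per_bp_energies_kj_mol, dtype=float)
    stacks = nn_tables.stack_free_energies_kj(
        spec.stem_seq_5p, spec.chemistry, temperature_k)
    return np.array([-g for g in stacks] + [0.0])


def loop_init_energy(spec: HairpinSpec,
                     temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Net free-energy change of the final opening step, kJ/mol (negative).

    Releasing the loop returns its closure penalty and removes the
    duplex-end initiation term.
    """
    if spec.loop_init_energy_kj_mol is not None:
        return spec.loop_init_energy_kj_mol
    return -(nn_tables.loop_penalty_kj(spec.loop_length, spec.chemistry,
                                       temperature_k)
             + nn_tables.terminal_init_kj(spec.stem_seq_5p, spec.chemistry,
                                          temperature_k))


def delta_g_mfold(spec: HairpinSpec,
                  temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Zero-force unfolding free energy of the full hairpin, kJ/mol."""
    return float(per_bp_opening_energies(spec, temperature_k).sum()
                 + loop_init_energy(spec, temperature_k))


@dataclass
class LandscapeProfile:
    """Free energy versus number of opened base pairs.

    ``G_zero_force_kj_mol`` is the sequence landscape at zero force
    (G(0) = 0); ``G_tilted_kj_mol`` subtracts the single-strand stretching
    free energy of the released nucleotides at ``force_pn``.
    """

    n_open: np.ndarray
    G_zero_force_kj_mol: np.ndarray
    G_tilted_kj_mol: np.ndarray
    force_pn: float
    barrier_index: int
    barrier_height_kj_mol: float

    def to_columns(self) -> np.ndarray:
        return np.column_stack([self.n_open, self.G_zero_force_kj_mol,
                                self.G_tilted_kj_mol])


def build_landscape(spec: HairpinSpec, force_pn: float = 0.0,
                    elasticity: FJCParams | None = None,
                    temperature_k: float = DEFAULT_TEMPERATURE_K,
                    frozen_extension_force_pn: float | None = None
                    ) -> LandscapeProfile:
    """Unfolding free-energy landscape of a hairpin, optionally tilted by force.

    Each opened base pair releases two nucleotides whose stretching free
    energy ∫_0^F x_ss(f) df is subtracted from the sequence landscape; the
    final step additionally releases the loop.  With
    ``frozen_extension_force_pn`` set, the per-nucleotide extension is frozen
    at that force so the tilt is exactly linear in F (useful for analysis).
    """
    if force_pn < 0:
        raise DomainError("force_pn must be >= 0")
    base = elasticity if elasticity is not None else spec.ss_elasticity()
    n_bp = spec.n_bp
    n_open = np.arange(n_bp + 1)

    g_zero = np.concatenate([[0.0],
                             np.cumsum(per_bp_opening_energies(spec, temperature_k))])
    g_zero[-1] += loop_init_energy(spec, temperature_k)

    released = 2 * n_open
    released[-1] = spec.n_nt_released

    if frozen_extension_force_pn is not None:
        per_nt = fjc_extension(base.with_n_nt(1), frozen_extension_force_pn,
                               temperature_k)
        stretch_pn_nm = released * per_nt * force_pn
    else:
        stretch_pn_nm = np.array([
            fjc_stretch_free_energy(base.with_n_nt(int(n)), force_pn,
                                    temperature_k)
            for n in released])
    g_tilted = g_zero - pn_nm_to_kj_per_mol(1.0) * stretch_pn_nm

    barrier_index = int(np.argmax(g_tilted))
    barrier_height = max(float(g_tilted[barrier_index] - g_tilted[0]), 0.0)
    return LandscapeProfile(n_open=n_open, G_zero_force_kj_mol=g_zero,
                            G_tilted_kj_mol=g_tilted, force_pn=force_pn,
                            barrier_index=barrier_index,
                            barrier_height_kj_mol=barrier_height)


def total_free_energy(spec: HairpinSpec, transition_force_pn: float,
                      dG_stretch_kj_mol: float | None = None,
                      elasticity: FJCParams | None = None,
                      temperature_k: float = DEFAULT_TEMPERATURE_K
                      ) -> tuple[float, float, float]:
    """Zero-force, stretching and total unfolding free energies, kJ/mol.

    ΔG_total = ΔG_mfold + ΔG_stretch.  ΔG_stretch is the elastic free energy
    stored in the released single strand at the transition force,
    ∫_0^{x(F_t)} F dx (supplied directly via ``dG_stretch_kj_mol`` when a
    measured/published value is to be combined with the sequence term).
    """
    if transition_force_pn <= 0:
        raise DomainError("transition_force_pn must be > 0")
    dg_mfold = delta_g_mfold(spec, temperature_k)
    if dG_stretch_kj_mol is None:
        base = elasticity if elasticity is not None else spec.ss_elasticity()
        chain = base.with_n_nt(spec.n_nt_released)
        x_at_f = fjc_extension(chain, transition_force_pn, temperature_k)
        work = (transition_force_pn * x_at_f
                - fjc_stretch_free_energy(chain, transition_force_pn,
                                          temperature_k))
        dG_stretch_kj_mol = pn_nm_to_kj_per_mol(work)
    return dg_mfold, dG_stretch_kj_mol, dg_mfold + dG_stretch_kj_mol


def equilibrium_force_estimate(dG_total_kj_mol: float, L_nm: float) -> float:
    """Equilibrium opening-force estimate F = ΔG_tot/L, pN."""
    if L_nm <= 0:
        raise DomainError("L_nm must be > 0")
    return kj_per_mol_to_pn_nm(dG_total_kj_mol) / L_nm


def x_to_nucleotides(x_fwd_nm: float, transition_force_pn: float | None = None,
                     elasticity: FJCParams | None = None,
                     per_nt_extension_nm: float | None = None,
                     folded_width_nm: float = 0.0,
                     temperature_k: float = DEFAULT_TEMPERATURE_K) -> int:
    """Convert a transition-state distance to a number of unfolded nucleotides.

    Returns the smallest integer n such that n·(extension per nucleotide at
    the transition force) + ``folded_width_nm`` covers ``x_fwd_nm``; exact
    equality resolves to the smaller n.  The per-nucleotide extension is
    either given directly (``per_nt_extension_nm``, the calibrated route) or
    evaluated from the freely-jointed-chain model at the transition force.
    """
    if x_fwd_nm < 0:
        raise DomainError("x_fwd_nm must be >= 0")
    if x_fwd_nm == 0:
        return 0
    if per_nt_extension_nm is None:
        if transition_force_pn is None or elasticity is None:
            raise DomainError(
                "either per_nt_extension_nm or (transition_force_pn and "
                "elasticity) must be provided")
        per_nt_extension_nm = fjc_extension(elasticity.with_n_nt(1),
                                            transition_force_pn, temperature_k)
    if per_nt_extension_nm <= 0:
        raise DomainError("per-nucleotide extension must be > 0")
    remaining = x_fwd_nm - folded_width_nm
    if remaining <= 0:
        return 0
    return int(math.ceil(remaining / per_nt_extension_nm - 1e-9))
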