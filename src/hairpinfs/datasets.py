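"""Published reference values for the four benchmark hairpins.

Two DNA and two RNA hairpins sharing a 13-bp stem with loops of 10 or 18
nucleotides (DNA10, DNA18, RNA10, RNA18).  The tables below collect the
published measurement summaries used as inputs throughout the package:
most probable unfolding/folding forces at 50 nm/s, transition lengths,
free-energy bookkeeping, fitted Bell-Evans parameters, and the size of the
hysteresis data sets (stretch/release cycles and molecules per hairpin).

These are *inputs* (measured or fitted quantities from the reference
experiment), not values computed by this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .elasticity import (ConstructModel, DEFAULT_TRAP_STIFFNESS_PN_NM,
                         default_construct)
from .kinetics import TwoStateParams
from .landscape import DEFAULT_STEM_5P, HairpinSpec

#: Pulling speeds of the stretch/release protocol, nm/s.
STUDY_SPEEDS_NM_S = (50.0, 150.0, 300.0, 450.0)


@dataclass(frozen=True)
class HairpinRecord:
    """Published summary for one hairpin."""

    name: str
    chemistry: str
    loop_length: int
    unfold_force_pn: float        # most probable, 50 nm/s
    fold_force_pn: float          # most probable, 50 nm/s
    transition_force_pn: float    # F_t, mean of the two above
    transition_length_nm: float   # L
    dG_mfold_kj_mol: float
    dG_stretch_kj_mol: float
    dG_total_kj_mol: float
    x_fwd_nm: float               # fitted transition-state distance
    x_fwd_over_L: float           # published rounded ratio
    k0_range_per_s: tuple[float, float]  # fitted zero-force rate interval
    n_cycles: int                 # hysteresis data set size (cycles)
    n_molecules: int

    @property
    def k0_mid_per_s(self) -> float:
        """Geometric midpoint of the published k0 interval."""
        return math.sqrt(self.k0_range_per_s[0] * self.k0_range_per_s[1])

    @property
    def n_nt(self) -> int:
        return 2 * 13 + self.loop_length

    @property
    def ramp_F_max_pn(self) -> float:
        """Default upper force of the ramp protocol (release start)."""
        return 25.0 if self.chemistry == "RNA" else 20.0


PUBLISHED: dict[str, HairpinRecord] = {
    "DNA10": HairpinRecord(
        name="DNA10", chemistry="DNA", loop_length=10,
        unfold_force_pn=6.4, fold_force_pn=6.2, transition_force_pn=6.3,
        transition_length_nm=14.8, dG_mfold_kj_mol=63.0,
        dG_stretch_kj_mol=20.0, dG_total_kj_mol=83.0,
        x_fwd_nm=4.4, x_fwd_over_L=0.30, k0_range_per_s=(1.0e-4, 3.0e-4),
        n_cycles=46, n_molecules=12),
    "DNA18": HairpinRecord(
        name="DNA18", chemistry="DNA", loop_length=18,
        unfold_force_pn=6.1, fold_force_pn=3.6, transition_force_pn=4.85,
        transition_length_nm=16.6, dG_mfold_kj_mol=60.0,
        dG_stretch_kj_mol=18.0, dG_total_kj_mol=78.0,
        x_fwd_nm=4.7, x_fwd_over_L=0.28, k0_range_per_s=(3.8e-5, 8.5e-5),
        n_cycles=95, n_molecules=13),
    "RNA10": HairpinRecord(
        name="RNA10", chemistry="RNA", loop_length=10,
        unfold_force_pn=13.6, fold_force_pn=8.8, transition_force_pn=11.2,
        transition_length_nm=17.7, dG_mfold_kj_mol=89.0,
        dG_stretch_kj_mol=32.0, dG_total_kj_mol=121.0,
        x_fwd_nm=3.0, x_fwd_over_L=0.17, k0_range_per_s=(2.9e-5, 5.5e-5),
        n_cycles=152, n_molecules=44),
    "RNA18": HairpinRecord(
        name="RNA18", chemistry="RNA", loop_length=18,
        unfold_force_pn=14.1, fold_force_pn=5.8, transition_force_pn=9.95,
        transition_length_nm=18.4, dG_mfold_kj_mol=87.0,
        dG_stretch_kj_mol=35.0, dG_total_kj_mol=122.0,
        x_fwd_nm=3.1, x_fwd_over_L=0.17, k0_range_per_s=(3.0e-6, 1.0e-5),
        n_cycles=150, n_molecules=21),
}


def reference_two_state_params(name: str,
                               k0_per_s: float | None = None) -> TwoStateParams:
    """Bell-Evans parameters of a reference hairpin.

    L and ΔG come from the measured transition length and the total
    free-energy bookkeeping; x_fwd from the hysteresis fit; k0 defaults to
    the geometric midpoint of the published interval.
    """
    rec = PUBLISHED[name]
    return TwoStateParams(
        L_nm=rec.transition_length_nm, x_fwd_nm=rec.x_fwd_nm,
        dG_kj_mol=rec.dG_total_kj_mol,
        k0_per_s=k0_per_s if k0_per_s is not None else rec.k0_mid_per_s)


def reference_hairpin_spec(name: str) -> HairpinSpec:
    """Default-stem hairpin spec matching a reference hairpin's geometry."""
    rec = PUBLISHED[name]
    stem = DEFAULT_STEM_5P
    if rec.chemistry == "RNA":
        stem = stem.replace("T", "U")
    return HairpinSpec(stem_seq_5p=stem, loop_length=rec.loop_length,
                       chemistry=rec.chemistry)


def reference_construct(name: str,
                        trap_stiffness_total_pn_nm: float = DEFAULT_TRAP_STIFFNESS_PN_NM
                        ) -> ConstructModel:
    """Default construct (handles + traps + released strand) for a hairpin."""
    rec = PUBLISHED[name]
    return default_construct(rec.chemistry, rec.n_nt,
                             trap_stiffness_total_pn_nm=trap_stiffness_total_pn_nm)


def study_simulation_config(name: str, seed: int,
                            noise_sd_pn: float = 0.2):
    """Simulation config reproducing the scale of a reference hysteresis study.

    Molecules and total stretch/release cycle counts follow the published
    data-set sizes, spread evenly over the four pulling speeds.
    """
    from .simulate import SimulationConfig

    rec = PUBLISHED[name]
    cycles_per_speed = max(1, round(rec.n_cycles / rec.n_molecules))
    return SimulationConfig(
        params=reference_two_state_params(name),
        construct=reference_construct(name),
        seed=seed, speeds_nm_s=STUDY_SPEEDS_NM_S,
        cycles_per_molecule=cycles_per_speed,
        n_molecules=rec.n_molecules, noise_sd_pn=noise_sd_pn,
        f_max_pn=rec.ramp_F_max_pn)
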