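"""Physical constants and unit conversions used throughout the package.

Mechanical quantities are kept in single-molecule "natural" units: forces in
pN, lengths in nm, single-molecule energies in pN·nm, molar energies in
kJ/mol, times in s.  The measurement temperature inside the flow chamber is
29 °C, so the default thermal energy is k_B·T ≈ 4.172 pN·nm.
"""

from __future__ import annotations

#: Boltzmann constant in pN·nm per kelvin.
BOLTZMANN_PN_NM_PER_K = 1.380649e-2

#: Default temperature (29 °C, the measured in-chamber value), in kelvin.
DEFAULT_TEMPERATURE_K = 302.15

#: 1 kJ/mol expressed per molecule in pN·nm (1e21/N_A).
KJ_PER_MOL_IN_PN_NM = 1.6606

#: 1 kcal/mol in kJ/mol (thermochemical calorie), used by the
#: nearest-neighbour tables which are published in kcal/mol.
KCAL_IN_KJ = 4.184


def thermal_energy(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Return k_B·T in pN·nm (≈ 4.172 pN·nm at the default 302.15 K)."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k} K")
    return BOLTZMANN_PN_NM_PER_K * temperature_k


def kj_per_mol_to_pn_nm(energy_kj_mol: float) -> float:
    """Convert a molar energy in kJ/mol to a per-molecule energy in pN·nm."""
    return energy_kj_mol * KJ_PER_MOL_IN_PN_NM


def pn_nm_to_kj_per_mol(energy_pn_nm: float) -> float:
    """Convert a per-molecule energy in pN·nm to a molar energy in kJ/mol."""
    return energy_pn_nm / KJ_PER_MOL_IN_PN_NM
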