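"""Nearest-neighbour thermodynamics for hairpin stems.

Watson-Crick stack enthalpies/entropies at 1 M NaCl: the unified DNA
parameter set and the Turner/Xia RNA set, keyed by the 5'→3' dinucleotide on
the given strand (reverse-complement symmetry resolves the remaining keys).
Loop initiation follows a Jacobson-Stockmayer extrapolation from a 9-nt
reference penalty, treated as purely entropic for its temperature scaling.

The working buffer (50 mM K acetate, 5 mM Mg acetate) differs from the 1 M
reference; a single additive per-stack free-energy offset per chemistry
absorbs the salt/buffer difference.  The offsets are calibrated once so the
default 13-bp ~50% GC stem reproduces the structure-prediction unfolding
free energies of the four reference hairpins (63/60 kJ/mol DNA, 89/87
kJ/mol RNA) within their stated uncertainties.
"""

from __future__ import annotations

import math

from .constants import KCAL_IN_KJ
from .errors import SequenceError

#: Gas constant in kcal/(mol·K).
_R_KCAL = 1.9872e-3

#: Reference temperature of the published tables, K.
_T37 = 310.15

#: (ΔH kcal/mol, ΔS cal/(mol·K)) per stack, unified DNA set.
DNA_STACKS = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}

#: (ΔH kcal/mol, ΔS cal/(mol·K)) per stack, Turner/Xia RNA set
#: (ΔS back-computed from the published ΔG°37 and ΔH).
RNA_STACKS = {
    "AA": (-6.82, -18.99), "AU": (-9.38, -26.70), "UA": (-7.69, -20.51),
    "CU": (-10.48, -27.08), "CA": (-10.44, -26.86), "GU": (-11.40, -29.53),
    "GA": (-12.44, -32.53), "CG": (-10.64, -26.70), "GG": (-13.39, -32.66),
    "GC": (-14.88, -36.95),
}

#: Duplex-end initiation (ΔH kcal/mol, ΔS cal/(mol·K)) applied once at the
#: open (bottom) end of the stem.
DNA_INIT = {"G": (0.1, -2.8), "C": (0.1, -2.8), "A": (2.3, 4.1), "T": (2.3, 4.1)}
RNA_INIT = (3.61, -1.5)

#: Hairpin-loop penalty at the 9-nt reference, kcal/mol at 37 °C.
LOOP_G9_KCAL = {"DNA": 3.5, "RNA": 5.6}

#: Buffer/salt offset added to each stack free energy, kcal/mol
#: (negative = stabilising relative to the 1 M reference tables).
BUFFER_DG_PER_STACK_KCAL = {"DNA": -0.17, "RNA": -0.35}

_COMPLEMENT = {"A": "T", "T": "A", "U": "A", "G": "C", "C": "G"}


def _revcomp(step: str, chemistry: str) -> str:
    out = []
    for base in reversed(step):
        comp = _COMPLEMENT[base]
        if chemistry == "RNA" and comp == "T":
            comp = "U"
        out.append(comp)
    return "".join(out)


def _validate_seq(seq: str, chemistry: str) -> str:
    seq = seq.upper().replace(" ", "")
    alphabet = "ACGU" if chemistry == "RNA" else "ACGT"
    for base in seq:
        if base not in alphabet:
            raise SequenceError(
                f"base {base!r} not allowed in {chemistry} sequence {seq!r}")
    return seq


def stack_free_energies_kj(stem_seq_5p: str, chemistry: str,
                           temperature_k: float) -> list[float]:
    """Free energies of the stem stacks at temperature T, kJ/mol (negative).

    One value per base-pair step, bottom to top, including the calibrated
    buffer offset.  Raises :class:`SequenceError` for an unknown step.
    """
    chemistry = chemistry.upper()
    table = RNA_STACKS if chemistry == "RNA" else DNA_STACKS
    seq = _validate_seq(stem_seq_5p, chemistry)
    offset = BUFFER_DG_PER_STACK_KCAL[chemistry]
    energies = []
    for i in range(len(seq) - 1):
        step = seq[i:i + 2]
        if step not in table:
            step_rc = _revcomp(step, chemistry)
            if step_rc not in table:
                raise SequenceError(f"unknown nearest-neighbour step {step!r}")
            step = step_rc
        dh, ds = table[step]
        dg_kcal = dh - temperature_k * ds / 1000.0 + offset
        energies.append(dg_kcal * KCAL_IN_KJ)
    return energies


def terminal_init_kj(stem_seq_5p: str, chemistry: str,
                     temperature_k: float) -> float:
    """Duplex-end initiation free energy at the bottom of the stem, kJ/mol."""
    chemistry = chemistry.upper()
    seq = _validate_seq(stem_seq_5p, chemistry)
    if chemistry == "RNA":
        dh, ds = RNA_INIT
    else:
        dh, ds = DNA_INIT[seq[0]]
    return (dh - temperature_k * ds / 1000.0) * KCAL_IN_KJ


def loop_penalty_kj(loop_length: int, chemistry: str,
                    temperature_k: float) -> float:
    """Hairpin-loop closure penalty, kJ/mol (positive, destabilising)."""
    if loop_length < 3:
        raise SequenceError(f"loop_length must be >= 3, got {loop_length}")
    chemistry = chemistry.upper()
    g9 = LOOP_G9_KCAL[chemistry] * temperature_k / _T37
    jacobson = 1.75 * _R_KCAL * temperature_k * math.log(loop_length / 9.0)
    return (g9 + jacobson) * KCAL_IN_KJ
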