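"""Polymer elasticity of the molecular construct and the force-balance solver.

The construct is a mechanical series: two optical traps (lumped into one
linear spring), two double-stranded handles described by the Marko–Siggia
worm-like chain (WLC) interpolation with an optional enthalpic stretch
modulus, and — depending on the hairpin state — either the folded hairpin
(a rigid element of roughly one helix diameter) or the released single
strand, described by a freely jointed chain (FJC).

At a given trap separation every element carries the same tension; the
common force is found by bracketed root finding.  The series compliance at
the operating force defines the effective stiffness k_eff that converts a
pulling velocity into a force loading rate r = k_eff·v.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .constants import DEFAULT_TEMPERATURE_K, thermal_energy
from .errors import ConfigurationError, DomainError

HairpinState = Literal["folded", "unfolded"]

#: Upper force bracket for all root finding, pN.
FORCE_BRACKET_PN = 200.0


@dataclass(frozen=True)
class WLCParams:
    """Worm-like chain parameters for a double-stranded handle.

    Parameters
    ----------
    persistence_length_nm : float
        Bending persistence length L_p.
    contour_length_nm : float
        Crystallographic contour length L_c.
    stretch_modulus_pn : float or None
        Enthalpic stretch modulus K; ``None`` selects the inextensible
        Marko–Siggia form.
    """

    persistence_length_nm: float
    contour_length_nm: float
    stretch_modulus_pn: float | None = None

    def __post_init__(self) -> None:
        if self.persistence_length_nm <= 0:
            raise DomainError("persistence_length_nm must be > 0")
        if self.contour_length_nm <= 0:
            raise DomainError("contour_length_nm must be > 0")
        if self.stretch_modulus_pn is not None and self.stretch_modulus_pn <= 0:
            raise DomainError("stretch_modulus_pn must be > 0 when set")


@dataclass(frozen=True)
class FJCParams:
    """Freely jointed chain parameters for released single-stranded nucleic acid.

    ``n_nt`` is the number of released nucleotides; ``contour_per_nt_nm``
    the contour length gained per nucleotide; ``kuhn_length_nm`` the Kuhn
    segment length b.
    """

    kuhn_length_nm: float
    contour_per_nt_nm: float
    n_nt: int

    def __post_init__(self) -> None:
        if self.kuhn_length_nm <= 0:
            raise DomainError("kuhn_length_nm must be > 0")
        if self.contour_per_nt_nm <= 0:
            raise DomainError("contour_per_nt_nm must be > 0")
        if self.n_nt < 0:
            raise DomainError("n_nt must be >= 0")

    def with_n_nt(self, n_nt: int) -> "FJCParams":
        return FJCParams(self.kuhn_length_nm, self.contour_per_nt_nm, n_nt)


#: Literature-style single-strand elasticity defaults per chemistry.
SS_DEFAULTS = {
    "DNA": FJCParams(kuhn_length_nm=1.5, contour_per_nt_nm=0.56, n_nt=0),
    "RNA": FJCParams(kuhn_length_nm=1.5, contour_per_nt_nm=0.59, n_nt=0),
}

#: Handle defaults: dsDNA handles for DNA constructs, RNA/DNA hybrid handles
#: for RNA constructs; contour lengths follow the ~0.5 μm / ~0.4 μm
#: crystallographic handle lengths of the two construct types.
HANDLE_DEFAULTS = {
    "DNA": WLCParams(persistence_length_nm=45.0, contour_length_nm=500.0,
                     stretch_modulus_pn=1200.0),
    "RNA": WLCParams(persistence_length_nm=50.0, contour_length_nm=400.0,
                     stretch_modulus_pn=1000.0),
}

#: Combined (series) stiffness of the two optical traps, pN/nm.  Chosen so
#: that the 50–450 nm/s pulling speeds map into loading rates of a few to
#: ~20 pN/s and the ~10 nm unfolding length change produces a force jump
#: comfortably above the 0.2 pN instrument-noise floor.
DEFAULT_TRAP_STIFFNESS_PN_NM = 0.08

#: Width of the folded hairpin along the pulling axis (helix diameter), nm.
DEFAULT_FOLDED_WIDTH_NM = 2.0


@dataclass(frozen=True)
class ConstructModel:
    """Series mechanical model of trap + handles + hairpin.

    ``ss_released`` carries the single-strand elasticity with ``n_nt`` equal
    to the *full* number of nucleotides released when the hairpin unfolds
    (stem·2 + loop); in the folded state zero nucleotides are released and
    the folded hairpin contributes ``folded_width_nm`` of rigid length.
    """

    handle1: WLCParams
    handle2: WLCParams
    ss_released: FJCParams
    trap_stiffness_total_pn_nm: float = DEFAULT_TRAP_STIFFNESS_PN_NM
    folded_width_nm: float = DEFAULT_FOLDED_WIDTH_NM
    temperature_k: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.trap_stiffness_total_pn_nm <= 0:
            raise DomainError("trap_stiffness_total_pn_nm must be > 0")
        if self.temperature_k <= 0:
            raise DomainError("temperature_k must be > 0")
        if self.folded_width_nm < 0:
            raise DomainError("folded_width_nm must be >= 0")

    @property
    def crystallographic_length_nm(self) -> float:
        """Zero-force reference length: handle contours plus folded hairpin."""
        return (self.handle1.contour_length_nm + self.handle2.contour_length_nm
                + self.folded_width_nm)


def default_construct(chemistry: str, n_nt_released: int,
                      trap_stiffness_total_pn_nm: float = DEFAULT_TRAP_STIFFNESS_PN_NM,
                      temperature_k: float = DEFAULT_TEMPERATURE_K) -> ConstructModel:
    """Build the default construct for a chemistry ("DNA" or "RNA")."""
    chemistry = chemistry.upper()
    if chemistry not in HANDLE_DEFAULTS:
        raise ConfigurationError(f"unknown chemistry {chemistry!r}; use DNA or RNA")
    handle = HANDLE_DEFAULTS[chemistry]
    ss = SS_DEFAULTS[chemistry].with_n_nt(n_nt_released)
    return ConstructModel(handle1=handle, handle2=handle, ss_released=ss,
                          trap_stiffness_total_pn_nm=trap_stiffness_total_pn_nm,
                          temperature_k=temperature_k)


# ---------------------------------------------------------------------------
# Worm-like chain
# ---------------------------------------------------------------------------

def _marko_siggia(z: float, persistence_length_nm: float, kbt: float) -> float:
    """Marko–Siggia interpolation force at fractional extension z."""
    return (kbt / persistence_length_nm) * (0.25 / (1.0 - z) ** 2 - 0.25 + z)


def _marko_siggia_dz(z: float, persistence_length_nm: float, kbt: float) -> float:
    """dF/dz of the Marko–Siggia interpolation."""
    return (kbt / persistence_length_nm) * (0.5 / (1.0 - z) ** 3 + 1.0)


def wlc_force(params: WLCParams, extension_nm: float,
              temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Tension of a worm-like chain at a given end-to-end extension.

    Uses the Marko–Siggia interpolation; when ``stretch_modulus_pn`` is set,
    the enthalpic correction replaces the fractional extension by
    x/L_c − F/K and the force is obtained by root finding.

    Raises
    ------
    DomainError
        If the extension is negative, or reaches the contour length in the
        inextensible form.
    """
    kbt = thermal_energy(temperature_k)
    lc = params.contour_length_nm
    if extension_nm < 0:
        raise DomainError(f"extension {extension_nm} nm < 0")
    if params.stretch_modulus_pn is None:
        if extension_nm >= lc:
            raise DomainError(
                f"extension {extension_nm} nm >= contour length {lc} nm "
                "(inextensible WLC requires extension < contour_length)")
        return _marko_siggia(extension_nm / lc, params.persistence_length_nm, kbt)
    if extension_nm == 0.0:
        return 0.0
    big_k = params.stretch_modulus_pn

    def residual(force: float) -> float:
        z = extension_nm / lc - force / big_k
        if z >= 1.0:
            # force too small to pull z below 1; residual positive
            return math.inf
        return _marko_siggia(z, params.persistence_length_nm, kbt) - force

    hi = FORCE_BRACKET_PN
    while residual(hi) > 0:
        hi *= 2.0
        if hi > 1e7:
            raise DomainError(
                f"extension {extension_nm} nm exceeds the extensible WLC "
                f"domain for contour length {lc} nm")
    return brentq(residual, 0.0, hi, xtol=1e-12, rtol=1e-14)


def wlc_extension(params: WLCParams, force_pn: float,
                  temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """End-to-end extension of a worm-like chain at a given tension."""
    if force_pn < 0:
        raise DomainError(f"force {force_pn} pN < 0")
    if force_pn == 0.0:
        return 0.0
    kbt = thermal_energy(temperature_k)

    def residual(z: float) -> float:
        return _marko_siggia(z, params.persistence_length_nm, kbt) - force_pn

    z = brentq(residual, 0.0, 1.0 - 1e-14, xtol=1e-15, rtol=1e-15)
    x = z * params.contour_length_nm
    if params.stretch_modulus_pn is not None:
        x += params.contour_length_nm * force_pn / params.stretch_modulus_pn
    return x


def wlc_compliance(params: WLCParams, force_pn: float,
                   temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """dx/dF of a worm-like chain at the operating force, nm/pN."""
    kbt = thermal_energy(temperature_k)

    def residual(z: float) -> float:
        return _marko_siggia(z, params.persistence_length_nm, kbt) - force_pn

    z = brentq(residual, 0.0, 1.0 - 1e-14, xtol=1e-15, rtol=1e-15)
    dx_df = params.contour_length_nm / _marko_siggia_dz(
        z, params.persistence_length_nm, kbt)
    if params.stretch_modulus_pn is not None:
        dx_df += params.contour_length_nm / params.stretch_modulus_pn
    return dx_df


# ---------------------------------------------------------------------------
# Freely jointed chain
# ---------------------------------------------------------------------------

def _langevin(u):
    """coth(u) − 1/u, stable near zero (series) and for large u."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = np.abs(u) < 1e-4
    us = u[small]
    out[small] = us / 3.0 - us ** 3 / 45.0
    ub = u[~small]
    out[~small] = 1.0 / np.tanh(ub) - 1.0 / ub
    return out


def fjc_extension(params: FJCParams, force_pn,
                  temperature_k: float = DEFAULT_TEMPERATURE_K):
    """Extension of a freely jointed chain at a given tension.

    x(F) = n·l·(coth(Fb/k_BT) − k_BT/(Fb)); the F → 0 limit is handled by a
    series expansion, so the function is defined for all F ≥ 0.  Accepts
    scalars or numpy arrays.
    """
    force = np.asarray(force_pn, dtype=float)
    if np.any(force < 0):
        raise DomainError("force must be >= 0")
    kbt = thermal_energy(temperature_k)
    u = force * params.kuhn_length_nm / kbt
    x = params.n_nt * params.contour_per_nt_nm * _langevin(u)
    return float(x) if np.isscalar(force_pn) else x


def fjc_compliance(params: FJCParams, force_pn: float,
                   temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """dx/dF of a freely jointed chain at the operating force, nm/pN."""
    kbt = thermal_energy(temperature_k)
    b = params.kuhn_length_nm
    u = force_pn * b / kbt
    lc = params.n_nt * params.contour_per_nt_nm
    if u < 1e-4:
        dldu = 1.0 / 3.0 - u * u / 15.0
    else:
        dldu = 1.0 / u ** 2 - 1.0 / math.sinh(u) ** 2 if u < 300 else 1.0 / u ** 2
    return lc * (b / kbt) * dldu


def fjc_stretch_free_energy(params: FJCParams, force_pn: float,
                            temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """∫_0^F x(f) df for a freely jointed chain, in pN·nm.

    Closed form n·l·(k_BT/b)·ln(sinh(u)/u) with u = F·b/k_BT.  This is the
    work conjugate used to tilt landscapes (the Gibbs-like potential of the
    released strand at constant force).
    """
    if force_pn < 0:
        raise DomainError("force must be >= 0")
    if force_pn == 0.0:
        return 0.0
    kbt = thermal_energy(temperature_k)
    b = params.kuhn_length_nm
    u = force_pn * b / kbt
    if u < 1e-4:
        log_term = u * u / 6.0
    else:
        # log(sinh u / u) computed overflow-safe
        log_term = u + math.log1p(-math.exp(-2.0 * u)) - math.log(2.0 * u)
    return params.n_nt * params.contour_per_nt_nm * (kbt / b) * log_term


# ---------------------------------------------------------------------------
# Force balance and effective stiffness
# ---------------------------------------------------------------------------

def construct_extension(model: ConstructModel, force_pn: float,
                        hairpin_state: HairpinState) -> dict[str, float]:
    """Extension of every series element at a common tension, nm."""
    t = model.temperature_k
    parts = {
        "trap": force_pn / model.trap_stiffness_total_pn_nm,
        "handle1": wlc_extension(model.handle1, force_pn, t),
        "handle2": wlc_extension(model.handle2, force_pn, t),
    }
    if hairpin_state == "folded":
        parts["hairpin"] = model.folded_width_nm
    else:
        parts["hairpin"] = fjc_extension(model.ss_released, force_pn, t)
    return parts


def solve_force_balance(model: ConstructModel, trap_separation_nm: float,
                        hairpin_state: HairpinState) -> tuple[float, dict[str, float]]:
    """Common tension of the series construct at a given trap separation.

    Returns the unique force at which the element extensions sum to the trap
    separation, together with the per-element extension partition.  Below the
    slack length (zero-force total extension) the tension is zero — beads at
    rest, construct not yet taut.
    """
    if trap_separation_nm < 0:
        raise DomainError("trap_separation_nm must be >= 0")
    if hairpin_state not in ("folded", "unfolded"):
        raise ConfigurationError(f"unknown hairpin state {hairpin_state!r}")

    def total(force: float) -> float:
        return sum(construct_extension(model, force, hairpin_state).values())

    if total(0.0) >= trap_separation_nm:
        return 0.0, construct_extension(model, 0.0, hairpin_state)
    lo, hi = 0.0, FORCE_BRACKET_PN
    if total(hi) < trap_separation_nm:
        raise ConfigurationError(
            f"no force in [0, {FORCE_BRACKET_PN}] pN reaches separation "
            f"{trap_separation_nm} nm in state {hairpin_state!r}")
    force = brentq(lambda f: total(f) - trap_separation_nm, lo, hi,
                   xtol=1e-10, rtol=8.9e-16)
    return force, construct_extension(model, force, hairpin_state)


def effective_stiffness(model: ConstructModel, force_pn: float,
                        hairpin_state: HairpinState) -> float:
    """Series stiffness k_eff of trap + construct at the operating force.

    1/k_eff = 1/k_trap + Σ 1/k_element, with each element stiffness the
    local dF/dx.  The folded hairpin is rigid and contributes no compliance.
    """
    t = model.temperature_k
    compliance = 1.0 / model.trap_stiffness_total_pn_nm
    compliance += wlc_compliance(model.handle1, force_pn, t)
    compliance += wlc_compliance(model.handle2, force_pn, t)
    if hairpin_state == "unfolded" and model.ss_released.n_nt > 0:
        compliance += fjc_compliance(model.ss_released, force_pn, t)
    return 1.0 / compliance


def force_vs_separation(model: ConstructModel, separations_nm: np.ndarray,
                        hairpin_state: HairpinState) -> np.ndarray:
    """Vector of equilibrium forces over a separation grid (one root solve each)."""
    return np.array([solve_force_balance(model, float(s), hairpin_state)[0]
                     for s in np.asarray(separations_nm, dtype=float)])
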