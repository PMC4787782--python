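"""Flat key-value run configuration.

The config file is a YAML mapping of flat, dot-separated keys with units
stated in the key names (e.g. ``handle1.persistence_length_nm: 45``), no
nested structures or expressions.  Unknown keys are rejected.  The
:class:`RunConfig` bundles everything a pipeline run needs: hairpin,
construct, kinetic parameters, simulation protocol, analysis thresholds,
fit search space, output directory and master seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .elasticity import (ConstructModel, FJCParams, WLCParams,
                         DEFAULT_FOLDED_WIDTH_NM, DEFAULT_TRAP_STIFFNESS_PN_NM,
                         HANDLE_DEFAULTS, SS_DEFAULTS)
from .constants import DEFAULT_TEMPERATURE_K
from .errors import ConfigurationError
from .kinetics import TwoStateParams
from .landscape import DEFAULT_STEM_5P, HairpinSpec
from .simulate import SimulationConfig

#: Every recognised key with its default (None = derived or required).
DEFAULTS: dict[str, object] = {
    "seed": 0,
    "output_dir": "hairpinfs_out",
    "temperature_K": DEFAULT_TEMPERATURE_K,
    # hairpin
    "hairpin.stem_seq_5p": DEFAULT_STEM_5P,
    "hairpin.loop_length": 10,
    "hairpin.chemistry": "DNA",
    # two-state parameters
    "two_state.L_nm": 14.8,
    "two_state.x_fwd_nm": 4.4,
    "two_state.dG_kj_mol": 83.0,
    "two_state.k0_per_s": 1.7e-4,
    # construct elasticity (None = chemistry default)
    "handle1.persistence_length_nm": None,
    "handle1.contour_length_nm": None,
    "handle1.stretch_modulus_pN": None,
    "handle2.persistence_length_nm": None,
    "handle2.contour_length_nm": None,
    "handle2.stretch_modulus_pN": None,
    "ss.kuhn_length_nm": None,
    "ss.contour_per_nt_nm": None,
    "trap.stiffness_total_pN_nm": DEFAULT_TRAP_STIFFNESS_PN_NM,
    "construct.folded_width_nm": DEFAULT_FOLDED_WIDTH_NM,
    # simulation protocol
    "simulate.speeds_nm_s": "50,150,300,450",
    "simulate.cycles_per_molecule": 4,
    "simulate.n_molecules": 10,
    "simulate.noise_sd_pN": 0.2,
    "simulate.sample_rate_Hz": 1000.0,
    "simulate.f_max_pN": 20.0,
    # analysis thresholds
    "detect.min_jump_pN": 0.5,
    "detect.window_samples": 5,
    "histogram.bin_width_pN": 0.5,
    "histogram.weighting": "cycles",
    "dwell.deadband_pN": 0.3,
    # fit search space
    "fit.x_min_nm": 1.0,
    "fit.x_max_nm": 10.0,
    "fit.log10_k0_min": -7.0,
    "fit.log10_k0_max": -1.0,
}


@dataclass
class RunConfig:
    """Validated bundle of all pipeline inputs."""

    raw: dict[str, object]
    seed: int
    output_dir: Path
    hairpin: HairpinSpec
    params: TwoStateParams
    construct: ConstructModel
    simulation: SimulationConfig
    min_jump_pn: float
    window_samples: int
    bin_width_pn: float
    weighting: str
    deadband_pn: float
    x_range_nm: tuple[float, float]
    log10_k0_range: tuple[float, float]


def load_config(path: str | Path | None = None,
                overrides: dict[str, object] | None = None) -> RunConfig:
    """Load a flat key-value YAML config, apply overrides, build the bundle."""
    values = dict(DEFAULTS)
    if path is not None:
        with Path(path).open() as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigurationError(f"{path}: config must be a flat mapping")
        unknown = sorted(set(user) - set(DEFAULTS))
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {unknown}")
        values.update(user)
    if overrides:
        unknown = sorted(set(overrides) - set(DEFAULTS))
        if unknown:
            raise ConfigurationError(f"unknown config keys {unknown}")
        values.update(overrides)
    return _build(values)


def _wlc(values: dict, prefix: str, chemistry: str) -> WLCParams:
    default = HANDLE_DEFAULTS[chemistry]
    return WLCParams(
        persistence_length_nm=_num(values, f"{prefix}.persistence_length_nm",
                                   default.persistence_length_nm),
        contour_length_nm=_num(values, f"{prefix}.contour_length_nm",
                               default.contour_length_nm),
        stretch_modulus_pn=_num(values, f"{prefix}.stretch_modulus_pN",
                                default.stretch_modulus_pn))


def _num(values: dict, key: str, fallback: float | None = None) -> float | None:
    v = values.get(key)
    if v is None:
        return fallback
    return float(v)


def _build(values: dict[str, object]) -> RunConfig:
    chemistry = str(values["hairpin.chemistry"]).upper()
    stem = str(values["hairpin.stem_seq_5p"]).upper()
    if chemistry == "RNA":
        stem = stem.replace("T", "U")  # accept DNA-style input for RNA stems
    hairpin = HairpinSpec(
        stem_seq_5p=stem,
        loop_length=int(values["hairpin.loop_length"]),
        chemistry=chemistry)
    params = TwoStateParams(
        L_nm=float(values["two_state.L_nm"]),
        x_fwd_nm=float(values["two_state.x_fwd_nm"]),
        dG_kj_mol=float(values["two_state.dG_kj_mol"]),
        k0_per_s=float(values["two_state.k0_per_s"]))
    ss_default = SS_DEFAULTS[chemistry]
    ss = FJCParams(
        kuhn_length_nm=_num(values, "ss.kuhn_length_nm",
                            ss_default.kuhn_length_nm),
        contour_per_nt_nm=_num(values, "ss.contour_per_nt_nm",
                               ss_default.contour_per_nt_nm),
        n_nt=hairpin.n_nt_released)
    construct = ConstructModel(
        handle1=_wlc(values, "handle1", chemistry),
        handle2=_wlc(values, "handle2", chemistry),
        ss_released=ss,
        trap_stiffness_total_pn_nm=float(values["trap.stiffness_total_pN_nm"]),
        folded_width_nm=float(values["construct.folded_width_nm"]),
        temperature_k=float(values["temperature_K"]))
    speeds_raw = values["simulate.speeds_nm_s"]
    if isinstance(speeds_raw, str):
        speeds = tuple(float(v) for v in speeds_raw.split(","))
    else:
        speeds = tuple(float(v) for v in speeds_raw)  # type: ignore[union-attr]
    simulation = SimulationConfig(
        params=params, construct=construct, seed=int(values["seed"]),
        speeds_nm_s=speeds,
        cycles_per_molecule=int(values["simulate.cycles_per_molecule"]),
        n_molecules=int(values["simulate.n_molecules"]),
        noise_sd_pn=float(values["simulate.noise_sd_pN"]),
        sample_rate_hz=float(values["simulate.sample_rate_Hz"]),
        f_max_pn=float(values["simulate.f_max_pN"]))
    return RunConfig(
        raw=values, seed=int(values["seed"]),
        output_dir=Path(str(values["output_dir"])),
        hairpin=hairpin, params=params, construct=construct,
        simulation=simulation,
        min_jump_pn=float(values["detect.min_jump_pN"]),
        window_samples=int(values["detect.window_samples"]),
        bin_width_pn=float(values["histogram.bin_width_pN"]),
        weighting=str(values["histogram.weighting"]),
        deadband_pn=float(values["dwell.deadband_pN"]),
        x_range_nm=(float(values["fit.x_min_nm"]),
                    float(values["fit.x_max_nm"])),
        log10_k0_range=(float(values["fit.log10_k0_min"]),
                        float(values["fit.log10_k0_max"])))
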