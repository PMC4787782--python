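"""End-to-end pipeline: simulate → histograms → fit → landscape → dwell.

Each stage writes its artifacts under the configured output directory with
a provenance header (package version, seed, config hash); a rerun with the
same config is byte-identical.  Stages run in dependency order; a stage
whose upstream artifact is missing raises :class:`DependencyError` naming
the stage that would produce it.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import io as hio
from .config import RunConfig
from .errors import DependencyError
from .inference import build_hysteresis_histogram, global_fit, model_histogram
from .kinetics import coexistence_force
from .landscape import build_landscape
from .simulate import (generate_event_tables, loading_rate_pn_s,
                       simulate_constant_extension, simulate_ramp_cycle)
from .kinetics import equal_occupancy_separation
from .traces import dwell_analysis

ALL_STAGES = ("simulate", "histogram", "fit", "landscape", "dwell")


def run_pipeline(config: RunConfig, stages: set[str] | None = None,
                 log=lambda msg: None) -> dict[str, Path]:
    """Run the selected stages; returns a mapping of artifact names to paths."""
    stages = set(ALL_STAGES) if stages is None else set(stages)
    unknown = stages - set(ALL_STAGES)
    if unknown:
        raise DependencyError(f"unknown stages {sorted(unknown)}")
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    chash = hio.hash_mapping({k: str(v) for k, v in config.raw.items()})
    artifacts: dict[str, Path] = {}
    events_path = out / "events.tsv"

    if "simulate" in stages:
        log("simulate: generating event tables")
        events = generate_event_tables(config.simulation)
        hio.write_events(events_path, events, seed=config.seed,
                         config_hash=chash)
        artifacts["events"] = events_path
        speed = config.simulation.speeds_nm_s[0]
        trace = simulate_ramp_cycle(config.simulation, speed,
                                    config.simulation.molecule_rng(0))
        trace_path = out / f"trace_{speed:g}nm_s.tsv"
        hio.write_trace(trace_path, trace, seed=config.seed, config_hash=chash)
        artifacts["trace"] = trace_path

    k_eff = {v: loading_rate_pn_s(config.params, config.construct, v) / v
             for v in config.simulation.speeds_nm_s}

    hists = None
    if "histogram" in stages or "fit" in stages:
        if not events_path.exists():
            raise DependencyError(
                "events.tsv missing: run the 'simulate' stage first (or place "
                "an event table in the output directory)")
        events = hio.read_events(events_path)
        hists = [build_hysteresis_histogram(events, v, config.bin_width_pn,
                                            config.weighting)
                 for v in config.simulation.speeds_nm_s]

    if "histogram" in stages:
        log("histogram: building weighted hysteresis histograms")
        for hist in hists:
            path = out / f"hysteresis_{hist.speed_nm_s:g}nm_s.tsv"
            model = model_histogram(config.params, hist.speed_nm_s,
                                    k_eff[hist.speed_nm_s], hist.bin_edges_pn,
                                    f_max_pn=config.simulation.f_max_pn)
            hio.write_histogram(path, hist, model)
            artifacts[f"hysteresis_{hist.speed_nm_s:g}"] = path

    if "fit" in stages:
        log("fit: global fit of x_fwd and k0 across speeds")
        fit = global_fit(hists, config.params.L_nm, config.params.dG_kj_mol,
                         k_eff, x_range_nm=config.x_range_nm,
                         log10_k0_range=config.log10_k0_range,
                         f_max_pn=config.simulation.f_max_pn)
        fit_path = out / "fit.json"
        fit_path.write_text(json.dumps({
            "x_fwd_hat_nm": fit.x_fwd_hat_nm,
            "k0_hat_per_s": fit.k0_hat_per_s,
            "x_fwd_interval_nm": list(fit.x_fwd_interval_nm),
            "k0_interval_per_s": list(fit.k0_interval_per_s),
            "rmse_per_speed": {str(k): v for k, v in fit.rmse_per_speed.items()},
            "rmse_total": fit.rmse_total,
            "boundary_warning": fit.boundary_warning,
            "seed": config.seed, "config_hash": chash,
        }, indent=2) + "\n")
        artifacts["fit"] = fit_path

    if "landscape" in stages:
        log("landscape: free-energy profile at the coexistence force")
        force = coexistence_force(config.params)
        profile = build_landscape(config.hairpin, force)
        path = out / "landscape.tsv"
        hio.write_landscape(path, profile)
        artifacts["landscape"] = path

    if "dwell" in stages:
        log("dwell: hopping trace at the equal-occupancy separation")
        sep = equal_occupancy_separation(config.params, config.construct)
        trace = simulate_constant_extension(config.simulation, sep, 120.0,
                                            config.simulation.molecule_rng(1))
        trace_path = out / "hopping_trace.tsv"
        hio.write_trace(trace_path, trace, seed=config.seed, config_hash=chash)
        artifacts["hopping_trace"] = trace_path
        try:
            summary = dwell_analysis(trace, config.deadband_pn)
            dwell_path = out / "dwell.tsv"
            dwell_path.write_text(
                "# dwell summary; times in s, separation in nm\n"
                "separation_nm\tmean_folded_s\tmean_unfolded_s\t"
                "occupancy_folded\tn_folded\tn_unfolded\n"
                f"{summary.separation_nm:.6g}\t{summary.mean_folded_s:.6g}\t"
                f"{summary.mean_unfolded_s:.6g}\t"
                f"{summary.occupancy_folded:.6g}\t"
                f"{len(summary.dwells_folded_s)}\t"
                f"{len(summary.dwells_unfolded_s)}\n")
            artifacts["dwell"] = dwell_path
        except Exception as exc:  # hopping may be unobservable (too few flips)
            log(f"dwell: no usable dwells ({exc})")
    return artifacts
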