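"""Text-file round-tripping for traces, event tables, histograms and landscapes.

All files are TSV with ``#``-prefixed comment headers stating the column
units (forces in pN, lengths in nm, energies in kJ/mol, times in s) and,
for pipeline outputs, the provenance (seed, config hash, package version).
Absent events are written as ``NA``.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .inference import HysteresisHistogram
from .landscape import LandscapeProfile
from .simulate import Trace

TRACE_COLUMNS = ("time_s", "separation_nm", "force_pN", "state")
EVENT_COLUMNS = ("molecule_id", "speed_nm_s", "cycle", "F_unfold_pN",
                 "F_fold_pN", "n_flips", "first_event_only")


def provenance_header(seed: int | None = None,
                      config_hash: str | None = None) -> list[str]:
    from . import __version__

    lines = [f"# hairpinfs v{__version__}"]
    if seed is not None:
        lines.append(f"# seed = {seed}")
    if config_hash is not None:
        lines.append(f"# config_hash = {config_hash}")
    return lines


def hash_mapping(mapping: dict) -> str:
    """Stable short hash of a flat config mapping, for provenance headers."""
    text = "\n".join(f"{k}={mapping[k]}" for k in sorted(mapping))
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_trace(path: str | Path, trace: Trace, seed: int | None = None,
                config_hash: str | None = None) -> None:
    """Write a trace as 4-column TSV (time_s, separation_nm, force_pN, state)."""
    path = Path(path)
    with path.open("w") as fh:
        for line in provenance_header(seed, config_hash):
            fh.write(line + "\n")
        fh.write("# columns: time_s\tseparation_nm\tforce_pN\tstate\n")
        fh.write("# state: 0 = folded, 1 = unfolded\n")
        np.savetxt(fh, np.column_stack([
            trace.time_s, trace.separation_nm, trace.force_pn,
            trace.state.astype(float)]),
            fmt=("%.9g", "%.9g", "%.9g", "%d"), delimiter="\t")


def read_trace(path: str | Path) -> Trace:
    """Read a 4-column trace TSV; validates column count and time monotonicity."""
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, "
                    f"got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise FormatError(f"{path}: no data rows")
    arr = np.asarray(rows)
    if len(arr) > 1 and not np.all(np.diff(arr[:, 0]) > 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    return Trace(time_s=arr[:, 0], separation_nm=arr[:, 1],
                 force_pn=arr[:, 2], state=arr[:, 3].astype(np.int8))


def write_events(path: str | Path, events: pd.DataFrame,
                 seed: int | None = None, config_hash: str | None = None) -> None:
    """Write an event table as TSV with NA for absent events."""
    path = Path(path)
    with path.open("w") as fh:
        for line in provenance_header(seed, config_hash):
            fh.write(line + "\n")
        fh.write("# forces in pN, speeds in nm/s\n")
        events.to_csv(fh, sep="\t", index=False, na_rep="NA",
                      float_format="%.12g")


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an event-table TSV; NA round-trips as NaN."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in ("molecule_id", "speed_nm_s", "F_unfold_pN",
                           "F_fold_pN") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def write_histogram(path: str | Path, hist: HysteresisHistogram,
                    model_weights: np.ndarray | None = None) -> None:
    """Write a hysteresis histogram (and optional model weights) as TSV."""
    path = Path(path)
    centers = 0.5 * (hist.bin_edges_pn[:-1] + hist.bin_edges_pn[1:])
    cols = {"delta_F_pN": centers, "weight": hist.weights}
    if model_weights is not None:
        cols["model_weight"] = model_weights
    with path.open("w") as fh:
        fh.write(f"# speed_nm_s = {hist.speed_nm_s}\n")
        fh.write(f"# n_molecules = {hist.n_molecules}, "
                 f"n_cycles = {hist.n_cycles}\n")
        pd.DataFrame(cols).to_csv(fh, sep="\t", index=False,
                                  float_format="%.9g")


def write_landscape(path: str | Path, profile: LandscapeProfile) -> None:
    """Write a landscape as (n_open, G_zero, G_tilted) TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# tilting force = {profile.force_pn} pN; "
                 "energies in kJ/mol\n")
        fh.write("# columns: n_open\tG_zero_force_kJ_mol\tG_tilted_kJ_mol\n")
        np.savetxt(fh, profile.to_columns(), fmt=("%d", "%.6g", "%.6g"),
                   delimiter="\t")


def write_density(path: str | Path, grid_pn: np.ndarray,
                  density_per_pn: np.ndarray) -> None:
    """Write a force density as two-column text (force_pN, density_per_pN)."""
    with Path(path).open("w") as fh:
        fh.write("# columns: force_pN\tdensity_per_pN\n")
        np.savetxt(fh, np.column_stack([grid_pn, density_per_pn]),
                   fmt="%.9g", delimiter="\t")
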