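"""Readers and writers for strain-trace exports and simulation outputs.

Observed strain traces come as delimited text files (the plain-text export
of speckle-tracking software): a header row naming the time column and the
segments, one row per sample, possibly followed by trailing metadata lines.
The reader tolerates tab/comma/whitespace delimiters, normalizes segment
names to the canonical AHA spelling, auto-detects seconds vs milliseconds
by magnitude, and drops non-numeric trailing lines. The writer emits the
same dialect (tab-separated, ``time_ms`` first) so traces round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import HemodynamicSummary, SimulationResult
from .errors import ValidationError
from .segments import normalize_segment_name
from .strain import StrainTrace


def write_strain_export(trace: StrainTrace, path) -> None:
    df = trace.strain.copy()
    df.insert(0, "time_ms", trace.time)
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_strain_export(path) -> StrainTrace:
    """Parse a delimited strain export into a StrainTrace.

    Raises a validation error naming the accepted AHA names if a segment
    column cannot be resolved.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"strain export not found: {path}")
    lines = path.read_text().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) < 2:
        raise ValidationError(f"strain export {path} has no data rows")
    delim = "\t" if "\t" in lines[0] else ("," if "," in lines[0] else None)
    header = [h.strip() for h in lines[0].split(delim) if h.strip()]
    rows = []
    for ln in lines[1:]:
        parts = [p.strip() for p in ln.split(delim) if p.strip()]
        if len(parts) != len(header):
            continue  # trailing metadata
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            continue  # trailing metadata
    if not rows:
        raise ValidationError(f"strain export {path}: no numeric rows parsed")
    data = np.asarray(rows, dtype=float)

    time_aliases = {"time", "time_ms", "time_s", "t", "t_ms", "t_s"}
    if header[0].lower() not in time_aliases:
        raise ValidationError(
            f"strain export {path}: first column {header[0]!r} is not a time "
            f"column (accepted: {sorted(time_aliases)})"
        )
    t = data[:, 0]
    explicit_s = header[0].lower().endswith("_s")
    explicit_ms = header[0].lower().endswith("ms")
    if explicit_s or (not explicit_ms and np.nanmax(np.abs(t)) < 50.0):
        t = t * 1000.0  # seconds -> ms

    seg_cols = {}
    for j, name in enumerate(header[1:], start=1):
        try:
            canon = normalize_segment_name(name)
        except KeyError as e:
            raise ValidationError(f"strain export {path}: {e.args[0]}") from None
        seg_cols[canon] = data[:, j]
    return StrainTrace(time=t, strain=pd.DataFrame(seg_cols))


# ---------------------------------------------------------------------------
# Simulation output writers
# ---------------------------------------------------------------------------


def write_hemodynamics_csv(result: SimulationResult, path) -> None:
    """Tidy CSV: time plus cavity pressures, volumes and valve flows."""
    cols = {"time_ms": result.time}
    for k, v in result.pressures.items():
        cols[f"p_{k}_mmHg"] = v
    for k in ("lv", "rv", "ra", "la"):
        cols[f"v_{k}_mL"] = result.volumes[k]
    for k in ("mitral", "aortic", "tricuspid", "pulmonary"):
        cols[f"q_{k}_mL_s"] = result.flows[k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.4f")


def write_strain_csv(result: SimulationResult, path) -> None:
    result.strain.to_csv(path, index=False, float_format="%.4f")


def write_summary_json(summary: HemodynamicSummary, path) -> None:
    Path(path).write_text(json.dumps(vars(summary), indent=2) + "\n")


def write_activation_csv(result: SimulationResult, path) -> None:
    """Per-cycle activation-onset map (ms relative to cycle start)."""
    rows = []
    for k, amap in enumerate(result.activation):
        for node, t in sorted(amap.items()):
            rows.append({"cycle": k, "node": node, "onset_ms": round(t, 3)})
    pd.DataFrame(rows).to_csv(path, index=False)
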