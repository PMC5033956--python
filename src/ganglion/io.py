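"""CSV/JSON persistence for traces and sweep results.

All text outputs carry ``#``-prefixed provenance header lines so any
file can be traced back to the model, protocol and solver settings
that produced it.  Grids are written as a CSV matrix (amplitude rows x
frequency columns) plus a JSON sidecar holding the run metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .experiments import SweepResult
from .forcing import StimulusProtocol
from .integrate import Trace

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_sweep",
    "read_sweep",
    "write_protocol_manifest",
    "write_spike_trains",
]


def _header_lines(meta: dict) -> list[str]:
    lines = [f"# ganglion {_version}"]
    for k, v in meta.items():
        lines.append(f"# {k}: {v}")
    return lines


def write_trace_csv(trace: Trace, path: str | Path) -> Path:
    """Write a trace as CSV (time_ms, V_mV, I_uAcm2) with provenance."""
    path = Path(path)
    meta = {
        "model": trace.model_id,
        "dt_ms": trace.dt,
        **{f"protocol.{k}": v for k, v in trace.protocol.to_dict().items()},
    }
    df = pd.DataFrame(
        {"time_ms": trace.times, "V_mV": trace.V, "I_uAcm2": trace.applied_current}
    )
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(meta)) + "\n")
        df.to_csv(fh, index=False)
    return path


def read_trace_csv(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a trace CSV; returns (dataframe, provenance dict)."""
    path = Path(path)
    meta: dict = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, skiprows=skip)
    return df, meta


def write_protocol_manifest(protocols, path: str | Path) -> Path:
    """Write a list of stimulus protocols as a CSV manifest, one
    protocol per row."""
    path = Path(path)
    rows = [p.to_dict() for p in protocols]
    pd.DataFrame(rows).to_csv(path, index_label="protocol_id")
    return path


def write_spike_trains(trains, path: str | Path) -> Path:
    """Write spike trains as two-column CSV (trial_id, spike_time_ms)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("trial_id,spike_time_ms\n")
        for trial, train in enumerate(trains):
            for t in train.times:
                fh.write(f"{trial},{float(t)!r}\n")
    return path


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_sweep(result: SweepResult, path: str | Path) -> Path:
    """Write a sweep/grid as CSV plus a JSON metadata sidecar.

    1-D sweeps: columns amp, value, defined.  2-D grids: one row per
    amplitude, one column per frequency (NaN for undefined cells).
    """
    path = Path(path)
    if result.freqs is None:
        df = pd.DataFrame(
            {"amp": result.amps, "value": result.values, "defined": result.defined}
        )
    else:
        df = pd.DataFrame(
            result.values,
            index=pd.Index(result.amps, name="amp"),
            columns=pd.Index(result.freqs, name="f_Hz"),
        )
    with open(path, "w") as fh:
        fh.write(
            "\n".join(
                _header_lines({"model": result.model_id, "measure": result.measure})
            )
            + "\n"
        )
        df.to_csv(fh, index=result.freqs is not None)
    sidecar = {
        "model": result.model_id,
        "measure": result.measure,
        "amps": list(map(float, result.amps)),
        "freqs": None if result.freqs is None else list(map(float, result.freqs)),
        "timing": result.timing,
        "errors": result.errors,
        "version": _version,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2) + "\n")
    return path


def read_sweep(path: str | Path) -> SweepResult:
    """Reconstruct a SweepResult from a CSV written by :func:`write_sweep`
    (requires the JSON sidecar next to it)."""
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    skip = sum(1 for line in open(path) if line.startswith("#"))
    if meta["freqs"] is None:
        df = pd.read_csv(path, skiprows=skip)
        values = df["value"].to_numpy()
        defined = df["defined"].to_numpy(dtype=bool)
        freqs = None
    else:
        df = pd.read_csv(path, skiprows=skip, index_col=0)
        values = df.to_numpy(dtype=float)
        defined = ~np.isnan(values)
        freqs = np.asarray(meta["freqs"], dtype=float)
    return SweepResult(
        model_id=meta["model"],
        measure=meta["measure"],
        amps=np.asarray(meta["amps"], dtype=float),
        values=values,
        defined=defined,
        freqs=freqs,
        timing=meta["timing"],
        errors=[tuple(e) for e in meta.get("errors", [])],
    )
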