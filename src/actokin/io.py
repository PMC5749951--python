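"""Delimited-text input/output for traces, series, curves and trajectories.

All files are plain text. Provenance travels in ``# key = value`` comment
lines above the data, so synthetic fixtures are self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .observables import SignalTrace
from .scheme import OccupancyTrajectory
from .steady_state import AtpaseCurve
from .transient import KobsSeries

__all__ = [
    "write_trace", "read_trace",
    "write_series", "read_series",
    "write_atpase", "read_atpase",
    "write_occupancies",
]


def _write_meta(fh, meta: dict) -> None:
    for k, v in meta.items():
        if isinstance(v, (dict, list, tuple)):
            v = json.dumps(v)
        fh.write(f"# {k} = {v}\n")


def _read_meta(path: str) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" not in body:
                continue
            k, v = body.split("=", 1)
            v = v.strip()
            try:
                meta[k.strip()] = json.loads(v)
            except (json.JSONDecodeError, ValueError):
                meta[k.strip()] = v
    return meta


def write_trace(trace: SignalTrace, path: str | Path) -> None:
    """Two-column (time s, signal) delimited text with provenance header."""
    with open(path, "w") as fh:
        _write_meta(fh, {"kind": trace.kind, **trace.meta})
        fh.write("time_s\tsignal\n")
        for t, y in zip(trace.times, trace.signal):
            fh.write(f"{t:.9g}\t{y:.9g}\n")


def read_trace(path: str | Path) -> SignalTrace:
    meta = _read_meta(str(path))
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, signal)")
    t, y = df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
    kind = str(meta.pop("kind", ""))
    return SignalTrace(t, y, kind=kind, meta=meta)


def write_series(series: KobsSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        _write_meta(fh, {"ligand": series.ligand, **series.meta})
        cols = "conc_uM\tkobs_per_s" + ("\tsd" if series.sd is not None else "")
        fh.write(cols + "\n")
        for i in range(len(series.concentrations)):
            row = f"{series.concentrations[i]:.9g}\t{series.k_obs[i]:.9g}"
            if series.sd is not None:
                row += f"\t{series.sd[i]:.9g}"
            fh.write(row + "\n")


def read_series(path: str | Path) -> KobsSeries:
    meta = _read_meta(str(path))
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    sd = df.iloc[:, 2].to_numpy(float) if df.shape[1] > 2 else None
    return KobsSeries(
        ligand=str(meta.pop("ligand", "")),
        concentrations=df.iloc[:, 0].to_numpy(float),
        k_obs=df.iloc[:, 1].to_numpy(float),
        sd=sd,
        meta=meta,
    )


def write_atpase(curve: AtpaseCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        _write_meta(fh, {"buffer": curve.buffer, **curve.meta})
        fh.write("actin_uM\trate_per_s\n")
        for a, v in zip(curve.actin, curve.rate):
            fh.write(f"{a:.9g}\t{v:.9g}\n")


def read_atpase(path: str | Path) -> AtpaseCurve:
    meta = _read_meta(str(path))
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    return AtpaseCurve(
        actin=df.iloc[:, 0].to_numpy(float),
        rate=df.iloc[:, 1].to_numpy(float),
        buffer=str(meta.pop("buffer", "")),
        meta=meta,
    )


def write_occupancies(traj: OccupancyTrajectory, path: str | Path) -> None:
    """Trajectory as delimited text: time column plus one column per species."""
    traj.to_frame().to_csv(path, sep="\t", float_format="%.9g")
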