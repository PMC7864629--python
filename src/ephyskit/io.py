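"""Readers and writers for the pipeline's interchange formats.

All tabular interchange is CSV (traces, rasters, sweeps, Ct tables,
feature tables), with a JSON sidecar carrying acquisition metadata where a
bare table is not self-describing.  Round-trips preserve values to double
precision as formatted (spike times to 1e-9 s); malformed rows raise with
the offending detail.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ephyskit.types import SpikeRaster, VCSweepSet, VoltageTrace

__all__ = [
    "write_trace", "read_trace", "write_raster", "read_raster",
    "write_sweepset", "read_sweepset", "read_ct_table",
]

log = logging.getLogger(__name__)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trace(trace: VoltageTrace, path: str | Path) -> None:
    """Trace CSV: time_s, voltage_mV, stimulus_pA + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.time_s(),
                       "voltage_mV": trace.voltage_mv,
                       "stimulus_pA": trace.stimulus_pa})
    df.to_csv(path, index=False, float_format="%.9g")
    meta = {"sampling_rate_hz": trace.sampling_rate_hz,
            "holding_potential_mv": trace.holding_potential_mv,
            "ljp_corrected": trace.ljp_corrected,
            "ljp_mv": trace.ljp_mv,
            "series_resistance_mohm": trace.series_resistance_mohm,
            "meta": {k: v for k, v in trace.meta.items()
                     if isinstance(v, (int, float, str, bool))}}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_trace(path: str | Path) -> VoltageTrace:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "voltage_mV"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = float(meta["sampling_rate_hz"])
    else:
        dt = np.diff(df["time_s"].to_numpy())
        if dt.size == 0 or not np.allclose(dt, dt[0]):
            raise ValueError(f"{path}: cannot infer sampling rate")
        fs = 1.0 / dt[0]
        meta = {}
    stim = df["stimulus_pA"].to_numpy() if "stimulus_pA" in df.columns \
        else np.zeros(len(df))
    return VoltageTrace(
        sampling_rate_hz=fs,
        voltage_mv=df["voltage_mV"].to_numpy(),
        stimulus_pa=stim,
        holding_potential_mv=float(meta.get("holding_potential_mv", -65.0)),
        ljp_corrected=bool(meta.get("ljp_corrected", False)),
        ljp_mv=float(meta.get("ljp_mv", 0.0)),
        series_resistance_mohm=meta.get("series_resistance_mohm"),
        meta=meta.get("meta", {}))


def write_raster(raster: SpikeRaster, path: str | Path) -> None:
    """Raster CSV: well, electrode, time_s (one row per spike)."""
    rows = [(raster.well_id, e, t)
            for e, times in sorted(raster.electrodes.items())
            for t in times]
    pd.DataFrame(rows, columns=["well", "electrode", "time_s"]).to_csv(
        Path(path), index=False, float_format="%.9f")


def read_raster(path: str | Path, duration_s: float = 300.0
                ) -> list[SpikeRaster]:
    """Read one or more wells from a raster CSV.

    Unsorted spike times are accepted and sorted with a warning.
    """
    df = pd.read_csv(Path(path))
    for col in ("well", "electrode", "time_s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    if df["time_s"].isna().any():
        bad = int(df.index[df["time_s"].isna()][0]) + 2
        raise ValueError(f"{path}: malformed spike time at line {bad}")
    out = []
    for well, sub in df.groupby("well", sort=True):
        electrodes = {}
        for e, esub in sub.groupby("electrode", sort=True):
            t = esub["time_s"].to_numpy(dtype=float)
            if t.size > 1 and np.any(np.diff(t) < 0):
                log.warning("%s / %s: spike times unsorted; sorting",
                            well, e)
                t = np.sort(t)
            electrodes[str(e)] = t
        out.append(SpikeRaster(str(well), electrodes, duration_s))
    return out


def write_sweepset(sweeps: VCSweepSet, path: str | Path) -> None:
    """Sweep-family CSV (one column per step) + JSON sidecar."""
    path = Path(path)
    n = sweeps.currents_pa.shape[1]
    data = {"time_s": np.arange(n) / sweeps.sampling_rate_hz}
    for i, v in enumerate(sweeps.step_mv):
        data[f"step_{v:+.0f}mV_pA"] = sweeps.currents_pa[i]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")
    meta = {"cell_id": sweeps.cell_id, "condition": sweeps.condition,
            "capacitance_pf": sweeps.capacitance_pf,
            "step_mv": list(map(float, sweeps.step_mv)),
            "sampling_rate_hz": sweeps.sampling_rate_hz,
            "seal_resistance_gohm": sweeps.seal_resistance_gohm,
            "series_resistance_mohm": sweeps.series_resistance_mohm,
            "protocol": sweeps.protocol}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_sweepset(path: str | Path) -> VCSweepSet:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"{path}: missing JSON sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path)
    steps = meta["step_mv"]
    cols = [c for c in df.columns if c.startswith("step_")]
    if len(cols) != len(steps):
        raise ValueError(f"{path}: {len(cols)} step columns but "
                         f"{len(steps)} steps in sidecar")
    currents = np.vstack([df[c].to_numpy() for c in cols])
    return VCSweepSet(
        cell_id=meta["cell_id"], condition=meta["condition"],
        capacitance_pf=float(meta["capacitance_pf"]),
        step_mv=np.asarray(steps, dtype=float), currents_pa=currents,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        seal_resistance_gohm=meta.get("seal_resistance_gohm"),
        series_resistance_mohm=meta.get("series_resistance_mohm"),
        protocol=meta.get("protocol", {}))


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Long-format Ct CSV with columns sample_id (or sample), gene,
    replicate, ct."""
    df = pd.read_csv(Path(path))
    if "sample" in df.columns and "sample_id" not in df.columns:
        df = df.rename(columns={"sample": "sample_id"})
    missing = {"sample_id", "gene", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
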