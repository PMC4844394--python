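"""Readers/writers for trajectories, luminometer exports and configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import LuminescenceTrace
from .core_model import ModelParameters, Trajectory
from .stimulus import StimulusProtocol

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_luminometer_csv",
    "read_luminometer_csv",
    "save_parameters",
    "load_parameters",
]

_TOTAL_FLAG = "total"


def write_trajectory(
    traj: Trajectory, path: str | Path, protocol: StimulusProtocol | None = None
) -> None:
    """Trajectory to CSV (time_s, ci_uM, h, ipx [, fluxes]) + JSON sidecar.

    The sidecar (same stem, .json) records the full parameter set and the
    stimulus protocol for provenance.
    """
    path = Path(path)
    cols = {
        "time_s": traj.times,
        "ci_uM": traj.ci,
        "h": traj.h,
        "ipx": traj.stimulus,
    }
    if traj.fluxes:
        cols.update(traj.fluxes)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")
    sidecar = {
        "params": traj.params.to_dict() if traj.params else None,
        "stimulus": protocol.to_dicts() if protocol else None,
        "ramp_s": protocol.ramp if protocol else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path)
    params = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("params"):
            params = ModelParameters.from_dict(meta["params"])
    flux_cols = [c for c in ("j_chan", "j_leak", "j_pump", "j_in") if c in df]
    return Trajectory(
        times=df["time_s"].to_numpy(),
        ci=df["ci_uM"].to_numpy(),
        h=df["h"].to_numpy(),
        stimulus=df["ipx"].to_numpy(),
        fluxes={c: df[c].to_numpy() for c in flux_cols} or None,
        params=params,
    )


def write_luminometer_csv(trace: LuminescenceTrace, path: str | Path) -> None:
    """Luminometer dialect: time_s,counts rows, then a trailing total row.

    The discharge total ``l_tot`` is written as a final row whose time_s
    field is the flag ``"total"``.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time_s,counts\n")
        for t, c in zip(trace.times, trace.counts):
            fh.write(f"{t:g},{c:.6f}\n")
        fh.write(f"{_TOTAL_FLAG},{trace.l_tot:.6f}\n")


def read_luminometer_csv(path: str | Path, l_tot: float | None = None) -> LuminescenceTrace:
    """Read the luminometer dialect; ``l_tot`` overrides the trailing row."""
    df = pd.read_csv(path, dtype={"time_s": str})
    flag = df["time_s"].str.lower() == _TOTAL_FLAG
    if l_tot is None:
        if not flag.any():
            raise ValueError(f"{path}: no trailing '{_TOTAL_FLAG}' row and no l_tot given")
        l_tot = float(df.loc[flag, "counts"].iloc[-1])
    data = df.loc[~flag]
    times = data["time_s"].astype(float).to_numpy()
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    return LuminescenceTrace(
        times=times, counts=data["counts"].astype(float).to_numpy(),
        l_tot=l_tot, dt=dt,
    )


def save_parameters(
    params: ModelParameters, path: str | Path,
    protocol: StimulusProtocol | None = None,
) -> None:
    """Model parameters (and optional protocol) to YAML/JSON by extension."""
    path = Path(path)
    doc: dict = {"params": params.to_dict()}
    if protocol is not None:
        doc["stimulus"] = {"pulses": protocol.to_dicts(), "ramp_s": protocol.ramp}
    text = (
        json.dumps(doc, indent=2)
        if path.suffix == ".json"
        else yaml.safe_dump(doc, sort_keys=False)
    )
    path.write_text(text)


def load_parameters(path: str | Path) -> tuple[ModelParameters, StimulusProtocol | None]:
    path = Path(path)
    doc = (
        json.loads(path.read_text())
        if path.suffix == ".json"
        else yaml.safe_load(path.read_text())
    )
    params = ModelParameters.from_dict(doc["params"])
    protocol = None
    if "stimulus" in doc:
        protocol = StimulusProtocol.from_dicts(
            doc["stimulus"]["pulses"], ramp=doc["stimulus"].get("ramp_s", 0.0)
        )
    return params, protocol
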