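"""Readers and writers for the toolkit's plain-text interchange formats.

Sweeps travel as one CSV per cell (``time_s`` then ``dirXXX_trialY``
columns) with a JSON sidecar holding sampling metadata; pose markers use the
pose-estimation CSV dialect (three header rows: scorer / bodyparts / coord,
per-marker x, y, likelihood columns); tabular results are flat CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .traces import PeakTable, SweepSet


def write_sweepset(sweeps: SweepSet, csv_path: str | Path) -> Path:
    """Write a SweepSet as CSV plus a ``.json`` sidecar next to it."""
    csv_path = Path(csv_path)
    cols = {"time_s": sweeps.time}
    for i, d in enumerate(sweeps.directions):
        for j in range(sweeps.n_trials):
            cols[f"dir{int(round(d)):03d}_trial{j + 1}"] = sweeps.traces[i, j]
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    sidecar = {
        "sampling_rate_hz": sweeps.sampling_rate,
        "recording_mode": sweeps.recording_mode,
        "holding_mv": sweeps.holding_mv,
        "units": sweeps.units,
        "directions_deg": [float(d) for d in sweeps.directions],
        "n_trials": sweeps.n_trials,
    }
    json_path = csv_path.with_suffix(".json")
    json_path.write_text(json.dumps(sidecar, indent=1))
    return json_path


def read_sweepset(csv_path: str | Path) -> SweepSet:
    """Read a SweepSet written by :func:`write_sweepset`."""
    csv_path = Path(csv_path)
    sidecar_path = csv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise InvalidInputError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    df = pd.read_csv(csv_path)
    directions = meta["directions_deg"]
    n_trials = meta["n_trials"]
    traces = np.stack(
        [
            np.stack(
                [df[f"dir{int(round(d)):03d}_trial{j + 1}"].to_numpy() for j in range(n_trials)]
            )
            for d in directions
        ]
    )
    return SweepSet(
        directions=np.asarray(directions, dtype=float),
        traces=traces,
        sampling_rate=meta["sampling_rate_hz"],
        recording_mode=meta["recording_mode"],
        units=meta.get("units", "pA"),
        holding_mv=meta.get("holding_mv"),
    )


def write_markers(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a pose-marker table in the three-header-row CSV dialect."""
    path = Path(path)
    df.to_csv(path, index=True, index_label="frame")
    return path


def read_markers(path: str | Path) -> pd.DataFrame:
    """Read a three-header-row pose-marker CSV."""
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    df.columns = df.columns.set_names(["scorer", "bodyparts", "coords"])
    return df


def write_peak_table(table: PeakTable, path: str | Path, cell_id: str = "cell") -> Path:
    path = Path(path)
    out = table.table.copy()
    out.insert(0, "cell_id", cell_id)
    out.to_csv(path, index=False)
    return path


def read_peak_table(path: str | Path) -> PeakTable:
    df = pd.read_csv(path)
    return PeakTable(df.drop(columns=[c for c in ("cell_id",) if c in df.columns]))


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
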