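"""Plain-text table formats: trajectory TSV, tracking TSV, summary CSV.

Both TSV dialects are UTF-8, tab-separated, '.' decimal, with a mandatory
header line and a leading ``#``-comment carrying the schema version.

* trajectory TSV (simulator output, step units):
  ``agent_id  event_index  t_s  x  y  phi_deg``
* tracking TSV (synthetic/real video exports, mm):
  ``animal_id  frame  t_s  x_mm  y_mm  [heading_deg]``
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "TRAJECTORY_COLUMNS",
    "TRACKING_COLUMNS",
    "write_trajectories",
    "read_trajectories",
    "write_tracking",
    "read_tracking",
]

TRAJECTORY_SCHEMA = "# planotaxis trajectory v1"
TRACKING_SCHEMA = "# planotaxis tracking v1"
TRAJECTORY_COLUMNS = ["agent_id", "event_index", "t_s", "x", "y", "phi_deg"]
TRACKING_COLUMNS = ["animal_id", "frame", "t_s", "x_mm", "y_mm"]


class SchemaError(ValueError):
    """Raised for malformed or out-of-contract tables."""


def _write_tsv(df: pd.DataFrame, path, schema_line: str) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(schema_line + "\n")
        df.to_csv(fh, sep="\t", index=False)
    os.replace(tmp, path)


def _read_tsv(path, required: Iterable[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"unreadable TSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def write_trajectories(trajectories, path) -> None:
    """Write a cohort of simulator trajectories as long-format TSV."""
    frames = [
        tr.to_dataframe(agent_id=tr.metadata.get("agent_id", i))
        for i, tr in enumerate(trajectories)
    ]
    _write_tsv(pd.concat(frames, ignore_index=True), path, TRAJECTORY_SCHEMA)


def read_trajectories(path) -> pd.DataFrame:
    """Read a trajectory TSV into a long-format DataFrame."""
    df = _read_tsv(path, TRAJECTORY_COLUMNS)
    if len(df) == 0:
        raise SchemaError(f"{path}: trajectory table contains no data rows")
    return df


def trajectories_from_frame(df: pd.DataFrame):
    """Rebuild ``Trajectory`` objects from a long-format trajectory table."""
    from .simulator import Trajectory

    out = []
    for agent_id, group in df.groupby("agent_id", sort=True):
        g = group.sort_values("event_index")
        out.append(
            Trajectory(
                t=g["t_s"].to_numpy(float),
                x=g["x"].to_numpy(float),
                y=g["y"].to_numpy(float),
                phi=g["phi_deg"].to_numpy(float),
                metadata={"agent_id": int(agent_id)},
            )
        )
    return out


def write_tracking(df: pd.DataFrame, path) -> None:
    """Write a tracking table as TSV with the schema comment line."""
    missing = [c for c in TRACKING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write tracking table missing {missing}")
    _write_tsv(df, path, TRACKING_SCHEMA)


def read_tracking(path) -> pd.DataFrame:
    """Read and validate a tracking TSV (frames consecutive per animal)."""
    df = _read_tsv(path, TRACKING_COLUMNS)
    if len(df) == 0:
        raise SchemaError(f"{path}: tracking table contains no data rows")
    for animal, group in df.groupby("animal_id"):
        frames = group["frame"].to_numpy()
        if frames.size > 1 and not np.all(np.diff(frames) == 1):
            raise SchemaError(
                f"{path}: frames not consecutive for animal {animal}"
            )
    return df
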