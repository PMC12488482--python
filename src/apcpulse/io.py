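"""Tidy delimited-text formats for trace tables and trajectories.

The on-disk trace format is a plain CSV with the exact header
``cell_id,scenario,time_h,channel,value`` (UTF-8, comma separator, dot
decimal, no quoting of numerics).  Ground-truth cell metadata travels in a
sidecar CSV named ``<stem>.meta.csv`` next to the trace file.  The dialect
is pinned so that write -> read is an exact round-trip, including row
order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synth import TRACE_COLUMNS, TraceTable

__all__ = ["write_traces", "read_traces", "write_trajectory", "meta_path"]

# repr-round-trip float format: shortest string that parses back exactly
_FLOAT_FMT = "%.17g"


def meta_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix(".meta.csv") if path.suffix == ".csv" else Path(
        str(path) + ".meta.csv"
    )


def write_traces(table: TraceTable, path: str | Path) -> Path:
    """Write a trace table (and its metadata sidecar) as pinned-dialect CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = table.data[TRACE_COLUMNS]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    if len(table.cell_meta):
        table.cell_meta.to_csv(meta_path(path), index=False, float_format=_FLOAT_FMT)
    return path


def read_traces(path: str | Path) -> TraceTable:
    """Read a trace table written by :func:`write_traces`.

    The header must match the pinned column order exactly; non-numeric
    ``time_h``/``value`` fields are reported with their line number.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    if header.split(",") != TRACE_COLUMNS:
        raise ValueError(
            f"{path}: malformed header {header!r}; "
            f"expected {','.join(TRACE_COLUMNS)!r}"
        )
    df = pd.read_csv(
        path,
        dtype={"cell_id": str, "scenario": str, "channel": str},
        float_precision="round_trip",
    )
    for col in ("time_h", "value"):
        if len(df) and not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            # +2: one for the header line, one for 1-based numbering
            raise ValueError(f"{path}: non-numeric {col} at line {bad + 2}")
    mp = meta_path(path)
    meta = (
        pd.read_csv(mp, float_precision="round_trip") if mp.exists() else pd.DataFrame()
    )
    if len(df) == 0:
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            TRACE_COLUMNS, [str, str, float, str, float])})
    return TraceTable(data=df, cell_meta=meta)


def write_trajectory(traj, path: str | Path) -> Path:
    """Export a model trajectory as tidy CSV (time_h, variable, value)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    traj.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path
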