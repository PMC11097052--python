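"""Plain-text readers and writers for the package's file dialects.

Time series: CSV with header ``time_s,acc_x_g,acc_y_g,acc_z_g``.
Gait-sequence intervals: CSV with header ``start_s,end_s``, 3 decimals.
Metric panels and leaderboards: one row per record, 6 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GaitSequence, GSList, Recording
from .evaluation import MetricPanel

__all__ = [
    "read_recording",
    "write_recording",
    "read_gs",
    "write_gs",
    "write_panels",
    "read_panels",
]

TIME_COLUMNS = ["time_s", "acc_x_g", "acc_y_g", "acc_z_g"]


class DataError(ValueError):
    """Raised for malformed input files."""


def read_recording(path: str | Path, subject_id: str = "", group: str = "") -> Recording:
    """Read a triaxial time-series CSV; fs is inferred from the median dt."""
    df = pd.read_csv(path)
    missing = [c for c in TIME_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    values = df[TIME_COLUMNS].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values).all(axis=1))
    if bad.size:
        raise DataError(f"{path}: non-finite value in data row {bad[0]}")
    t = values[:, 0]
    if t.size < 2:
        raise DataError(f"{path}: need at least 2 samples to infer fs")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise DataError(f"{path}: time not strictly increasing at data row {row}")
    med = float(np.median(dt))
    if np.any(dt > 2 * med):
        row = int(np.flatnonzero(dt > 2 * med)[0]) + 1
        raise DataError(f"{path}: sampling gap at data row {row}")
    return Recording(fs=1.0 / med, acc=values[:, 1:4], subject_id=subject_id, group=group)


def write_recording(recording: Recording, path: str | Path) -> None:
    df = pd.DataFrame(
        np.column_stack([recording.time, recording.acc]), columns=TIME_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_gs(path: str | Path, source: str = "") -> GSList:
    df = pd.read_csv(path)
    for col in ("start_s", "end_s"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    try:
        return GSList(
            tuple(
                GaitSequence(float(a), float(b))
                for a, b in zip(df["start_s"], df["end_s"])
            ),
            source=source,
        )
    except ValueError as exc:
        raise DataError(f"{path}: {exc}") from exc


def write_gs(gs: GSList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("start_s,end_s\n")
        for seq in gs:
            fh.write(f"{seq.start_s:.3f},{seq.end_s:.3f}\n")


def write_panels(panels: list[MetricPanel], path: str | Path, json_mirror: bool = True) -> None:
    """One row per recording; optional JSON mirror next to the CSV."""
    rows = [p.as_dict() for p in panels]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")
    if json_mirror:
        Path(path).with_suffix(".json").write_text(json.dumps(rows, indent=2))


def read_panels(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
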