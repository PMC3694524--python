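"""Waveform and table I/O.

The on-disk waveform format is plain delimited text (CSV/TSV) with a header;
default columns ``time_s``, ``pressure_cmH2O``, ``flow_Lps``, remappable via
:class:`~breathmech.config.RunConfig`.  Internally flow is always stored
inspiration-positive and time is rebased to start at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import DataError, FormatError, SamplingError

__all__ = ["VentilationRecord", "read_waveform", "write_waveform",
           "write_mechanics_table", "read_mechanics_table"]

_TABLE_PRECISION = "%.12g"   # >= 9 significant digits round-trip


@dataclass
class VentilationRecord:
    """Uniformly sampled airway pressure / flow traces.

    Units: time s, pressure cmH2O, flow L/s (inspiration positive,
    expiration negative).
    """

    time: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        n = self.time.size
        if not (n >= 2 and self.pressure.size == n and self.flow.size == n):
            raise DataError("time/pressure/flow must have equal length >= 2")
        if self.fs <= 0:
            raise DataError("sampling rate must be positive")
        for name, arr in (("time", self.time), ("pressure", self.pressure),
                          ("flow", self.flow)):
            if not np.all(np.isfinite(arr)):
                row = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise DataError(f"non-finite value in {name} at row {row}")
        dt = 1.0 / self.fs
        if np.max(np.abs(np.diff(self.time) - dt)) >= 1e-6:
            raise SamplingError(
                f"time axis not uniform at fs={self.fs:g} Hz within 1e-6 s")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


def read_waveform(path: str | Path, config: RunConfig | None = None) -> VentilationRecord:
    """Read a delimited-text waveform file into a validated record.

    Applies the configured sign convention so expiration is negative flow
    and rebases time to start at 0.
    """
    config = config or RunConfig()
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    cols = (config.time_col, config.pressure_col, config.flow_col)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing column(s) {missing}; found {list(df.columns)}")
    arrs = {}
    for c in cols:
        a = pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(a))
        if bad.size:
            raise DataError(f"{path.name}: non-finite value in column "
                            f"{c!r} at data row {int(bad[0])}")
        arrs[c] = a
    t = arrs[config.time_col]
    if t.size < 2:
        raise DataError(f"{path.name}: need at least 2 samples")
    steps = np.diff(t)
    dt = float(np.median(steps))
    if dt <= 0:
        raise SamplingError(f"{path.name}: time not strictly increasing")
    if np.max(np.abs(steps - dt)) >= config.sampling_tol:
        raise SamplingError(
            f"{path.name}: non-uniform sampling (median step {dt:g} s, "
            f"max deviation {np.max(np.abs(steps - dt)):g} s)")
    flow = arrs[config.flow_col]
    if config.expiration_positive:
        flow = -flow
    return VentilationRecord(
        time=t - t[0],
        pressure=arrs[config.pressure_col],
        flow=flow,
        fs=1.0 / dt,
        meta={"source": str(path)},
    )


def write_waveform(record: VentilationRecord, path: str | Path,
                   config: RunConfig | None = None) -> None:
    """Write a record back to delimited text (inspiration-positive flow)."""
    config = config or RunConfig()
    df = pd.DataFrame({
        config.time_col: record.time,
        config.pressure_col: record.pressure,
        config.flow_col: record.flow,
    })
    df.to_csv(path, index=False, float_format=_TABLE_PRECISION)


def write_mechanics_table(rows: Sequence | pd.DataFrame, path: str | Path) -> None:
    """Write one row per breath of fitted mechanics to CSV.

    ``rows`` is either a DataFrame or a sequence of per-breath mappings /
    dataclasses with a ``to_row()`` method.  Values round-trip to at least
    9 significant digits.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        if len(rows) == 0:
            raise DataError("no breaths to write")
        recs = [r.to_row() if hasattr(r, "to_row") else dict(r) for r in rows]
        df = pd.DataFrame(recs)
    if df.empty:
        raise DataError("no breaths to write")
    df.to_csv(path, index=False, float_format=_TABLE_PRECISION)


def read_mechanics_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
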