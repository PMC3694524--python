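"""Fitting-error summaries and trend comparison statistics.

Per-breath fitting quality is the median over samples of the absolute
percentage error between modelled and measured signal; groups of breaths
are summarised as median [IQR] over breaths, one row per (method, phase)
plus a pooled Overall row.  Trend agreement between the time-constant K and
an elastance series is the squared Pearson correlation; for overlay plots K
can additionally be least-squares scaled onto the elastance axis (the scale
is cosmetic and never enters the statistics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["FitError", "ErrorSummary", "fitting_error", "summarize_errors",
           "trend_r2", "scale_for_trend"]


@dataclass
class FitError:
    """Absolute percentage fitting error of one breath."""

    per_sample: np.ndarray   # percentages over the valid samples
    median: float
    q25: float
    q75: float
    n_used: int

    def to_tuple(self) -> tuple[float, float, float]:
        return self.median, self.q25, self.q75


@dataclass
class ErrorSummary:
    """Median [IQR] absolute percentage fitting error for a group of breaths."""

    method: str
    phase: str
    median: float
    q25: float
    q75: float
    n_breaths: int


def fitting_error(measured: np.ndarray, modeled: np.ndarray,
                  mode: str = "relative",
                  floor_frac: float = 0.01) -> FitError | None:
    """Per-sample absolute percentage error and its median/IQR.

    ``relative`` mode normalises each sample by |measured_i|, excluding
    samples with |measured_i| below ``floor_frac`` of the window peak
    (prevents blow-ups near zero flow at the truncated tail); ``peak`` mode
    normalises by the window peak.  Returns None when no sample survives the
    floor (the breath is flagged by the caller).
    """
    m = np.asarray(measured, dtype=float)
    f = np.asarray(modeled, dtype=float)
    if m.shape != f.shape or m.size < 1:
        raise DataError("measured/modeled must be equal-length, non-empty")
    peak = float(np.max(np.abs(m)))
    if mode == "peak":
        if peak == 0.0:
            return None
        pct = 100.0 * np.abs(f - m) / peak
    elif mode == "relative":
        keep = np.abs(m) >= floor_frac * peak
        if peak == 0.0 or not np.any(keep):
            return None
        pct = 100.0 * np.abs(f[keep] - m[keep]) / np.abs(m[keep])
    else:
        raise DataError(f"unknown error mode {mode!r}")
    q25, med, q75 = np.percentile(pct, [25.0, 50.0, 75.0])
    return FitError(per_sample=pct, median=float(med), q25=float(q25),
                    q75=float(q75), n_used=int(pct.size))


def summarize_errors(per_breath: pd.DataFrame,
                     error_col: str = "error",
                     method_col: str = "method",
                     phase_col: str = "phase") -> pd.DataFrame:
    """Median [IQR] over breaths per (method, phase) plus an Overall row.

    Input: one row per breath with its scalar fitting error; rows with NaN
    error (flagged breaths) are dropped.  Quantiles use linear interpolation
    so results are bit-reproducible.
    """
    df = per_breath.dropna(subset=[error_col])
    rows = []
    for method, sub in df.groupby(method_col, sort=False):
        groups = [(str(ph), g) for ph, g in sub.groupby(phase_col, sort=False)]
        groups.append(("Overall", sub))
        for phase, g in groups:
            if g.empty:
                continue
            e = g[error_col].to_numpy(dtype=float)
            q25, med, q75 = np.percentile(e, [25.0, 50.0, 75.0])
            rows.append(ErrorSummary(method=str(method), phase=phase,
                                     median=float(med), q25=float(q25),
                                     q75=float(q75), n_breaths=int(e.size)))
    return pd.DataFrame([vars(r) for r in rows])


def _paired_finite(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("paired series must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def trend_r2(k_series, e_series) -> float:
    """Squared Pearson correlation of paired per-breath values.

    Flagged breaths are excluded pairwise (NaN in either series drops the
    pair).  Returns NaN when fewer than 3 pairs remain or either series has
    zero variance.
    """
    x, y = _paired_finite(k_series, e_series)
    if x.size < 3 or np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def scale_for_trend(k_series, e_series) -> tuple[np.ndarray, float]:
    """Least-squares scaling of K onto the elastance axis (through origin).

    Returns (c * K, c) with c = sum(K*E) / sum(K^2).  Used only for overlay
    plots and exports; never in statistics.  NaN pairs do not contribute to
    c but the full (scaled) series is returned.
    """
    k = np.asarray(k_series, dtype=float)
    x, y = _paired_finite(k_series, e_series)
    denom = float(np.sum(x * x))
    if denom == 0.0:
        raise DataError("cannot scale an all-zero K series")
    c = float(np.sum(x * y) / denom)
    return c * k, c
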