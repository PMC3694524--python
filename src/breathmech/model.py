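"""Model/Results interface tying the per-breath estimators together.

``RespiratoryMechanics`` is constructed from a :class:`VentilationRecord`
(or a waveform file) and a :class:`RunConfig`; ``fit()`` segments the
record into breaths, fits the expiratory time-constant model to every
breath and, where available, the static (EIP) and integral-based
inspiratory estimators, and returns a ``RespiratoryMechanicsResults``
carrying the per-breath table, QC accounting, error summaries, trend
statistics and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .config import RunConfig
from .errors import DataError, EstimatorError
from .expiratory import fit_time_constant, truncate_to_equilibrium
from .inspiratory import integral_based_fit, static_mechanics
from .io import VentilationRecord, read_waveform, write_mechanics_table
from .metrics import scale_for_trend, summarize_errors, trend_r2
from .segmentation import segment_breaths

__all__ = ["RespiratoryMechanics", "RespiratoryMechanicsResults",
           "RunReport", "TrendResult"]

_METHOD_LABELS = {"exp": "time-constant", "static": "eip", "ib": "integral-based"}


@dataclass
class RunReport:
    """Bookkeeping for one analysis run; counts always reconcile."""

    n_detected: int = 0
    n_fitted: int = 0
    flag_counts: dict = field(default_factory=dict)
    seed: int | None = None
    software_version: str = _version
    config: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    @property
    def n_flagged(self) -> int:
        return self.n_detected - self.n_fitted


@dataclass
class TrendResult:
    pair: str
    r2: float
    scale: float
    n: int
    n_excluded: int


class RespiratoryMechanics:
    """Breath-by-breath respiratory mechanics model for one record."""

    def __init__(self, record: VentilationRecord,
                 config: RunConfig | None = None) -> None:
        self.record = record
        self.config = config or RunConfig()

    @classmethod
    def from_csv(cls, path: str | Path,
                 config: RunConfig | None = None) -> "RespiratoryMechanics":
        config = config or RunConfig()
        return cls(read_waveform(path, config), config)

    @classmethod
    def from_arrays(cls, time, pressure, flow, fs,
                    config: RunConfig | None = None) -> "RespiratoryMechanics":
        rec = VentilationRecord(time=np.asarray(time), pressure=np.asarray(pressure),
                                flow=np.asarray(flow), fs=fs)
        return cls(rec, config)

    # -- fitting ------------------------------------------------------------

    def _fit_breath(self, breath) -> dict:
        rec, cfg = self.record, self.config
        t = rec.time
        row: dict = {
            "insp_start": breath.insp_start,
            "t_start": float(t[breath.insp_start]),
            "peep": breath.peep_estimate,
            "has_eip": breath.has_eip,
        }
        flags = list(breath.flags)

        # expiratory time-constant
        exp_span = slice(breath.exp_start, breath.exp_end)
        flow_mag = -rec.flow[exp_span]
        n_win, ok = truncate_to_equilibrium(
            flow_mag, cfg.truncation_fraction, cfg.equilibrium_tail_frac,
            cfg.min_samples)
        if ok and "short_exp" not in flags:
            tt = t[exp_span][:n_win] - t[breath.exp_start]
            fit = fit_time_constant(tt, flow_mag[:n_win], cfg)
            flags += list(fit.flags)
            row.update(K=fit.K if fit.converged else np.nan,
                       Q0=fit.Q0 if fit.converged else np.nan,
                       tau=fit.tau if fit.converged else np.nan,
                       n_fit=fit.n_fit, exp_err_median=fit.error_median,
                       exp_err_q25=fit.error_q25, exp_err_q75=fit.error_q75,
                       exp_ok=fit.converged)
        else:
            flags.append("exp_unfittable")
            row.update(K=np.nan, Q0=np.nan, tau=np.nan, n_fit=n_win,
                       exp_err_median=np.nan, exp_err_q25=np.nan,
                       exp_err_q75=np.nan, exp_ok=False)

        # static (EIP) mechanics
        if breath.has_eip:
            try:
                sm = static_mechanics(breath, rec, cfg)
                flags += list(sm.flags)
                row.update(PIP=sm.PIP, Pplat=sm.Pplat, Vt=sm.Vt,
                           Q_insp=sm.Q_insp, E_static=sm.E_static,
                           R_static=sm.R_static,
                           static_err_median=sm.error_median,
                           static_err_q25=sm.error_q25,
                           static_err_q75=sm.error_q75,
                           static_ok="nonphysical_static" not in sm.flags)
            except (DataError, EstimatorError) as exc:
                flags.append(f"static_error:{exc}")
                row.update(static_ok=False)
        else:
            row.update(static_ok=False)
        row.setdefault("E_static", np.nan)
        row.setdefault("R_static", np.nan)
        for c in ("PIP", "Pplat", "Vt", "Q_insp", "static_err_median",
                  "static_err_q25", "static_err_q75"):
            row.setdefault(c, np.nan)

        # integral-based identification
        try:
            ib = integral_based_fit(breath, rec, cfg)
            flags += list(ib.flags)
            bad = {"ill_conditioned", "e_out_of_range", "r_out_of_range"}
            row.update(E_rsIB=ib.E_rsIB, R_rsIB=ib.R_rsIB, P0=ib.P0,
                       ib_condition=ib.condition,
                       ib_err_median=ib.error_median,
                       ib_err_q25=ib.error_q25, ib_err_q75=ib.error_q75,
                       ib_ok=not (bad & set(ib.flags)))
        except (DataError, EstimatorError) as exc:
            flags.append(f"ib_error:{exc}")
            row.update(E_rsIB=np.nan, R_rsIB=np.nan, P0=np.nan,
                       ib_condition=np.nan, ib_err_median=np.nan,
                       ib_err_q25=np.nan, ib_err_q75=np.nan, ib_ok=False)

        row["flags"] = ";".join(flags)
        return row

    def fit(self) -> "RespiratoryMechanicsResults":
        breaths = segment_breaths(self.record, self.config)
        rows = [self._fit_breath(b) for b in breaths]
        mech = pd.DataFrame(rows)
        mech.insert(0, "breath", np.arange(len(mech)))
        mech["phase"] = self.record.meta.get("phase", "run")

        flag_counts: dict[str, int] = {}
        for s in mech["flags"]:
            for f in filter(None, str(s).split(";")):
                flag_counts[f] = flag_counts.get(f, 0) + 1
        clean = mech["flags"].astype(str).isin(("", "nan"))
        report = RunReport(n_detected=len(mech), n_fitted=int(clean.sum()),
                           flag_counts=flag_counts, seed=self.config.seed,
                           config=self.config.to_dict())
        return RespiratoryMechanicsResults(self, breaths, mech, report)


class RespiratoryMechanicsResults:
    """Per-breath estimates, diagnostics and summaries for one record."""

    def __init__(self, model: RespiratoryMechanics, breaths, mechanics, report):
        self.model = model
        self.breaths = breaths
        self.mechanics = mechanics
        self.report = report

    @property
    def n_breaths(self) -> int:
        return len(self.mechanics)

    # -- metrics ------------------------------------------------------------

    def error_summary(self) -> pd.DataFrame:
        """Median [IQR] absolute percentage fitting error per method/phase."""
        m = self.mechanics
        parts = []
        for key, label in _METHOD_LABELS.items():
            ok = m[f"{key}_ok"].fillna(False).astype(bool)
            parts.append(pd.DataFrame({
                "method": label, "phase": m["phase"],
                "error": m[f"{key}_err_median"].where(ok)}))
        return summarize_errors(pd.concat(parts, ignore_index=True))

    def _pair(self, ycol: str, y=None):
        m = self.mechanics
        k = m["K"].where(m["exp_ok"].astype(bool))
        if y is None:
            okcol = "static_ok" if ycol == "E_static" else "ib_ok"
            y = m[ycol].where(m[okcol].astype(bool))
        y = np.asarray(y, dtype=float)
        return np.asarray(k, dtype=float), y

    def trend_r2(self, ycol: str = "E_rsIB", y=None) -> TrendResult:
        """R^2 between K and an elastance series (flagged breaths excluded
        pairwise); ``y`` may be an external series, e.g. simulated truth."""
        k, yv = self._pair(ycol, y)
        keep = np.isfinite(k) & np.isfinite(yv)
        r2 = trend_r2(k, yv)
        scale = np.nan
        if keep.sum() >= 3 and np.any(k[keep] != 0):
            _, scale = scale_for_trend(k[keep], yv[keep])
        return TrendResult(pair=f"K~{ycol}", r2=r2, scale=scale,
                           n=int(keep.sum()),
                           n_excluded=int((~keep).sum()))

    def trend_table(self) -> pd.DataFrame:
        rows = [self.trend_r2("E_static"), self.trend_r2("E_rsIB")]
        return pd.DataFrame([vars(r) for r in rows])

    def validate_against(self, truth: pd.DataFrame) -> dict:
        """Recovery statistics against a simulator truth table.

        Breaths are matched on start time (nearest within half a period).
        """
        m = self.mechanics.sort_values("t_start")
        t = truth.sort_values("t_start").rename(
            columns={"E": "E_true", "R": "R_true", "K": "K_true",
                     "peep": "peep_set"})
        period = np.median(np.diff(t["t_start"])) if len(t) > 1 else 1.0
        merged = pd.merge_asof(m, t, on="t_start", direction="nearest",
                               tolerance=period / 2)
        merged = merged.dropna(subset=["K_true"])

        def med_rel(est, true):
            ok = np.isfinite(est) & np.isfinite(true) & (true != 0)
            if not np.any(ok):
                return float("nan")
            return float(np.median(np.abs(est[ok] - true[ok]) / np.abs(true[ok])))

        stats = {
            "n_matched": int(len(merged)),
            "k_med_rel_err": med_rel(merged["K"], merged["K_true"]),
            "e_ib_med_rel_err": med_rel(merged["E_rsIB"], merged["E_true"]),
            "r_ib_med_rel_err": med_rel(merged["R_rsIB"], merged["R_true"]),
            "e_static_med_rel_err": med_rel(merged["E_static"], merged["E_true"]),
            "r_static_med_rel_err": med_rel(merged["R_static"], merged["R_true"]),
            "r2_k_vs_e_true": trend_r2(
                merged["K"].where(merged["exp_ok"].astype(bool)), merged["E_true"]),
        }
        return stats

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        m = self.mechanics
        rep = self.report
        lines = [
            "Respiratory mechanics results",
            "=" * 64,
            f"breaths detected: {rep.n_detected}   fully clean: {rep.n_fitted}"
            f"   flagged: {rep.n_flagged}",
            f"record: {self.model.record.n_samples} samples @ "
            f"{self.model.record.fs:g} Hz "
            f"({self.model.record.duration:.1f} s)",
            "",
            "per-breath medians (unflagged breaths)",
            "-" * 64,
        ]
        for col, unit in (("K", "1/s"), ("tau", "s"), ("E_static", "cmH2O/L"),
                          ("R_static", "cmH2O.s/L"), ("E_rsIB", "cmH2O/L"),
                          ("R_rsIB", "cmH2O.s/L"), ("peep", "cmH2O")):
            v = pd.to_numeric(m[col], errors="coerce").dropna()
            if len(v):
                lines.append(f"  {col:>9}: {v.median():10.4g} {unit}"
                             f"   (IQR {v.quantile(.25):.4g}-{v.quantile(.75):.4g},"
                             f" n={len(v)})")
        es = self.error_summary()
        lines += ["", "fitting error, median [IQR] % (Overall)", "-" * 64]
        for _, r in es[es["phase"] == "Overall"].iterrows():
            lines.append(f"  {r['method']:>15}: {r['median']:6.2f} "
                         f"[{r['q25']:.2f}-{r['q75']:.2f}]  n={r['n_breaths']}")
        tt = self.trend_table()
        lines += ["", "trend correlation", "-" * 64]
        for _, r in tt.iterrows():
            lines.append(f"  {r['pair']:>12}: R^2 = {r['r2']:.4f}  "
                         f"(n={r['n']}, scale={r['scale']:.3g})")
        if rep.flag_counts:
            lines += ["", "QC flags", "-" * 64]
            for f, c in sorted(rep.flag_counts.items()):
                lines.append(f"  {f}: {c}")
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> None:
        write_mechanics_table(self.mechanics, path)

    def plot_trends(self, truth: pd.DataFrame | None = None, ax=None):
        """Overlay of scaled K with the elastance estimates per breath.

        K is least-squares scaled onto the elastance axis for display only.
        Requires matplotlib (optional dependency).
        """
        import matplotlib.pyplot as plt  # lazy: plotting is optional

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        m = self.mechanics
        k = m["K"].where(m["exp_ok"].astype(bool)).to_numpy(dtype=float)
        for col, style in (("E_rsIB", "-"), ("E_static", "--")):
            ax.plot(m["breath"], m[col], style, lw=0.8, label=col)
        e_ref = m["E_rsIB"].to_numpy(dtype=float)
        keep = np.isfinite(k) & np.isfinite(e_ref)
        if keep.sum() >= 3:
            scaled, c = scale_for_trend(np.nan_to_num(k), np.nan_to_num(e_ref))
            ax.plot(m["breath"], np.where(np.isfinite(k), scaled, np.nan),
                    ":", lw=1.2, label=f"{c:.2g} x K (scaled for display)")
        if truth is not None:
            ax.plot(truth["breath"], truth["E"], "k-", alpha=0.4, label="E true")
        ax.set_xlabel("breath")
        ax.set_ylabel("elastance (cmH2O/L)")
        ax.legend(fontsize=8)
        return ax
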