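"""Inspiratory validation estimators: static (EIP) and integral-based.

Static mechanics use the two-point relations
``E_static = (Pplat - PEEP) / Vt`` and ``R_static = (PIP - Pplat) / Q``
enabled by the ventilator's automated end-inspiratory pause; Q is the mean
delivered flow (equal to the set flow for a square profile).

The integral-based method integrates the single-compartment equation
P_aw = R*Q + E*V + P0 sample-by-sample over the inspiratory span and solves
the stacked linear system for (R, E, P0) by least squares; working with
running integrals instead of point values is what buys noise robustness
over a point-wise regression on the same equation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid as _cumtrapz

from .config import RunConfig
from .errors import DataError, EstimatorError
from .io import VentilationRecord
from .metrics import FitError, fitting_error
from .segmentation import Breath, _noise_scale

__all__ = ["StaticMechanics", "IntegralFit", "static_mechanics",
           "integral_based_fit", "pointwise_fit", "cumulative_trapezoid",
           "cumulative_volume"]


@dataclass
class StaticMechanics:
    """End-inspiratory-pause (static) mechanics of one breath."""

    PIP: float        # peak inspiratory pressure, cmH2O
    Pplat: float      # plateau pressure after the pause, cmH2O
    PEEP: float       # end-expiratory pressure, cmH2O
    Vt: float         # inspired tidal volume, L
    Q_insp: float     # mean delivered inspiratory flow, L/s
    E_static: float   # cmH2O/L
    R_static: float   # cmH2O.s/L
    error_median: float = float("nan")
    error_q25: float = float("nan")
    error_q75: float = float("nan")
    flags: tuple[str, ...] = ()


@dataclass
class IntegralFit:
    """Integral-based identification of one breath's inspiration."""

    E_rsIB: float     # cmH2O/L
    R_rsIB: float     # cmH2O.s/L
    P0: float         # offset pressure, cmH2O
    condition: float  # condition number of the design matrix
    error_median: float = float("nan")
    error_q25: float = float("nan")
    error_q75: float = float("nan")
    flags: tuple[str, ...] = ()


def cumulative_trapezoid(series: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Running trapezoidal integral, first element 0."""
    y = np.asarray(series, dtype=float)
    x = np.asarray(times, dtype=float)
    if y.size != x.size or y.size < 2:
        raise DataError("series/times must be equal length >= 2")
    return _cumtrapz(y, x, initial=0.0)


def cumulative_volume(flow: np.ndarray, dt: float,
                      rule: str = "rectangle") -> np.ndarray:
    """Breath-wise volume V(t) = integral of flow, rebased to 0 at onset.

    ``rectangle`` is the backward-rectangle rule, exact for square-flow
    profiles whose valve transitions fall on sample instants (the trapezoid
    rule smears each step by half a sample); ``trapezoid`` is the standard
    trapezoidal rule.
    """
    q = np.asarray(flow, dtype=float)
    if rule == "rectangle":
        v = np.empty_like(q)
        v[0] = 0.0
        np.cumsum(q[1:] * dt, out=v[1:])
        return v
    if rule == "trapezoid":
        return _cumtrapz(q, dx=dt, initial=0.0)
    raise DataError(f"unknown volume rule {rule!r}")


def _insp_volume(record: VentilationRecord, breath: Breath,
                 config: RunConfig) -> np.ndarray:
    span = slice(breath.insp_start, breath.pause_end)
    return cumulative_volume(record.flow[span], record.dt, config.volume_rule)


def static_mechanics(breath: Breath, record: VentilationRecord,
                     config: RunConfig | None = None) -> StaticMechanics:
    """Two-point static elastance/resistance from the EIP plateau.

    PIP is the raw inspiratory maximum (no smoothing, matching
    ventilator-display conventions); Pplat is the median over the final
    third of the pause, letting pressure settle; Vt is the trapezoidal
    integral of flow over inspiration.  A drift between the early and late
    pause pressure beyond ``pplat_settle_tol`` raises the
    ``pplat_unsettled`` flag (a too-short EIP overestimates elastance).
    """
    config = config or RunConfig()
    if not breath.has_eip:
        raise EstimatorError("breath has no end-inspiratory pause")
    P = record.pressure
    Q = record.flow
    insp = slice(breath.insp_start, breath.insp_end)
    n_pause = breath.pause_end - breath.pause_start
    third = max(1, n_pause // 3)
    late = slice(breath.pause_end - third, breath.pause_end)
    early = slice(breath.pause_start, breath.pause_start + third)

    PIP = float(np.max(P[insp]))
    Pplat = float(np.median(P[late]))
    PEEP = float(breath.peep_estimate)
    t = record.time
    Vt = float(np.trapezoid(Q[insp], t[insp]))
    if Vt <= 0:
        raise DataError("non-positive inspired tidal volume")
    duration = float(t[breath.insp_end - 1] - t[breath.insp_start])
    if duration <= 0:
        raise DataError("degenerate inspiration duration")
    Q_insp = Vt / duration
    E = (Pplat - PEEP) / Vt
    R = (PIP - Pplat) / Q_insp

    flags: list[str] = []
    tol = 1e-9 * max(1.0, abs(PIP))
    if not (PIP >= Pplat - tol and Pplat >= PEEP - tol):
        flags.append("nonphysical_static")
    # a plateau that is still decaying means the EIP was too short and
    # E_static overestimates the true elastance; the drift threshold adapts
    # to the pressure channel's noise so quiet records are held to the floor
    settle_thresh = max(config.pplat_settle_tol,
                        3.0 * _noise_scale(P) / np.sqrt(third))
    if float(np.median(P[early])) - Pplat > settle_thresh:
        flags.append("pplat_unsettled")

    sm = StaticMechanics(PIP=PIP, Pplat=Pplat, PEEP=PEEP, Vt=Vt,
                         Q_insp=Q_insp, E_static=E, R_static=R,
                         flags=tuple(flags))
    # reconstruction error: model pressure over inspiration+pause
    span = slice(breath.insp_start, breath.pause_end)
    V = _insp_volume(record, breath, config)
    modeled = R * Q[span] + E * V + PEEP
    err = fitting_error(P[span], modeled, mode=config.error_mode,
                        floor_frac=config.error_floor_frac)
    if isinstance(err, FitError):
        sm.error_median, sm.error_q25, sm.error_q75 = err.to_tuple()
    return sm


def _integral_design(record: VentilationRecord, breath: Breath,
                     config: RunConfig) -> tuple[np.ndarray, np.ndarray, slice]:
    stop = breath.pause_end if config.integral_span == "inspiration+pause" \
        else breath.insp_end
    span = slice(breath.insp_start, stop)
    t = record.time[span] - record.time[breath.insp_start]
    Q = record.flow[span]
    P = record.pressure[span]
    V = cumulative_volume(Q, record.dt, config.volume_rule)
    A = np.column_stack([
        cumulative_trapezoid(Q, t),
        cumulative_trapezoid(V, t),
        t,
    ])[1:]  # first row is identically zero
    b = cumulative_trapezoid(P, t)[1:]
    return A, b, span


def integral_based_fit(breath: Breath, record: VentilationRecord,
                       config: RunConfig | None = None) -> IntegralFit:
    """Solve int(P) = R*int(Q) + E*int(V) + P0*t for (R, E, P0).

    The system is stacked over every sample of the inspiratory span
    (including the pause by default: its zero-flow rows are what make R and
    P0 separately identifiable under exactly constant square flow).  The
    per-breath error compares pressure reconstructed from the identified
    parameters with the measured inspiratory pressure.
    """
    config = config or RunConfig()
    A, b, span = _integral_design(record, breath, config)
    if A.shape[0] < 10:
        raise EstimatorError("inspiratory span has fewer than 10 samples")
    coef, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise EstimatorError("rank-deficient design (zero or constant flow?)")
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
    R, E, P0 = (float(c) for c in coef)
    flags: list[str] = []
    if cond > config.cond_limit:
        flags.append("ill_conditioned")
    lo_e, hi_e = config.e_range
    lo_r, hi_r = config.r_range
    if not (lo_e < E <= hi_e):
        flags.append("e_out_of_range")
    if not (lo_r < R <= hi_r):
        flags.append("r_out_of_range")
    fit = IntegralFit(E_rsIB=E, R_rsIB=R, P0=P0, condition=cond,
                      flags=tuple(flags))
    Q = record.flow[span]
    V = cumulative_volume(Q, record.dt, config.volume_rule)
    modeled = R * Q + E * V + P0
    err = fitting_error(record.pressure[span], modeled,
                        mode=config.error_mode,
                        floor_frac=config.error_floor_frac)
    if isinstance(err, FitError):
        fit.error_median, fit.error_q25, fit.error_q75 = err.to_tuple()
    return fit


def pointwise_fit(breath: Breath, record: VentilationRecord,
                  config: RunConfig | None = None) -> IntegralFit:
    """Point-wise regression of P on (Q, V, 1) over the same span.

    The non-integrated counterpart of :func:`integral_based_fit`; kept as
    the reference against which the integral formulation's noise robustness
    is demonstrated.
    """
    config = config or RunConfig()
    stop = breath.pause_end if config.integral_span == "inspiration+pause" \
        else breath.insp_end
    span = slice(breath.insp_start, stop)
    Q = record.flow[span]
    P = record.pressure[span]
    if Q.size < 10:
        raise EstimatorError("inspiratory span has fewer than 10 samples")
    V = cumulative_volume(Q, record.dt, config.volume_rule)
    A = np.column_stack([Q, V, np.ones_like(Q)])
    coef, _, rank, sv = np.linalg.lstsq(A, P, rcond=None)
    if rank < 3:
        raise EstimatorError("rank-deficient design")
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
    R, E, P0 = (float(c) for c in coef)
    fit = IntegralFit(E_rsIB=E, R_rsIB=R, P0=P0, condition=cond)
    err = fitting_error(P, R * Q + E * V + P0, mode=config.error_mode,
                        floor_frac=config.error_floor_frac)
    if isinstance(err, FitError):
        fit.error_median, fit.error_q25, fit.error_q75 = err.to_tuple()
    return fit
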