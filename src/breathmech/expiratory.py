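"""Expiratory time-constant identification.

During passive expiration the single-compartment relation
P_aw = R_rs*Q + E_rs*V + P0 with P_aw held at PEEP reduces to a first-order
decay of flow, Q(t) = Q0 * exp(-K t) with K = E_rs/R_rs = 1/tau.  K and Q0
are fitted simultaneously by nonlinear least squares to the expiratory flow
magnitude, starting at the sample of peak expiratory flow; fitting both
parameters damps the influence of the valve-opening transient.  The fit
window is truncated where flow has covered 95% of the distance from its
peak to the end-expiratory equilibrium value, which excludes the
near-constant tail produced by the ventilator's expiratory-valve
resistance.  Expiratory *pressure* is never used: downstream of the
expiratory valve it carries no information about the lung.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .config import RunConfig
from .metrics import FitError, fitting_error

__all__ = ["ExpiratoryFit", "truncate_to_equilibrium", "fit_time_constant",
           "predict_expiratory_flow", "loglinear_decay_rate"]


@dataclass
class ExpiratoryFit:
    """Result of fitting Q(t) = Q0 exp(-K t) to one breath's expiration."""

    K: float            # decay rate, 1/s  (= E_rs/R_rs under constant R)
    Q0: float           # peak expiratory flow magnitude, L/s
    tau: float          # 1/K, s
    n_fit: int          # samples in the truncated window
    fit_span: tuple[int, int]   # window indices, local to the expiratory span
    error_median: float = float("nan")
    error_q25: float = float("nan")
    error_q75: float = float("nan")
    converged: bool = False
    flags: tuple[str, ...] = ()


def truncate_to_equilibrium(flow_mag: np.ndarray,
                            fraction: float = 0.95,
                            tail_frac: float = 0.10,
                            min_samples: int = 5) -> tuple[int, bool]:
    """Length of the fit window reaching ``fraction`` of equilibrium.

    ``flow_mag`` is the expiratory flow magnitude starting at its peak.  The
    equilibrium value Q_eq is the median over the final ``tail_frac`` of the
    span (accommodating the near-constant valve tail).  Returns
    ``(n_window, ok)``: the first sample where |Q - Q_eq| has shrunk to
    (1 - fraction) of |Q_peak - Q_eq| closes the window; if no sample
    qualifies the full span is used.  ``ok`` is False for degenerate input
    (window shorter than ``min_samples``, padded up to it).
    """
    q = np.asarray(flow_mag, dtype=float)
    n = q.size
    if n < 2:
        return n, False
    n_tail = max(1, int(round(tail_frac * n)))
    q_eq = float(np.median(q[-n_tail:]))
    span = q[0] - q_eq
    if span <= 0.0:
        return min(min_samples, n), False
    thresh = (1.0 - fraction) * span
    hit = np.flatnonzero(np.abs(q - q_eq) <= thresh)
    n_win = int(hit[0]) + 1 if hit.size else n
    if n_win < min_samples:
        return min(min_samples, n), False
    return n_win, True


def loglinear_decay_rate(times: np.ndarray, flow_mag: np.ndarray,
                         floor: float = 1e-4) -> tuple[float, float]:
    """Ordinary least-squares line through (t, ln Q): returns (K, Q0).

    Serves both as the optimizer's initial guess and as an independent
    cross-check of the nonlinear fit on clean data.  Samples are clipped at
    ``floor`` to avoid log(0); the clip affects only this estimate, never
    the main objective.
    """
    y = np.log(np.maximum(np.asarray(flow_mag, dtype=float), floor))
    t = np.asarray(times, dtype=float)
    slope, intercept = np.polyfit(t, y, 1)
    return -float(slope), float(np.exp(intercept))


def fit_time_constant(times: np.ndarray, flow_mag: np.ndarray,
                      config: RunConfig | None = None,
                      init: tuple[float, float] | None = None) -> ExpiratoryFit:
    """Least-squares fit of Q0*exp(-K t) to expiratory flow magnitude.

    Both parameters are free; the objective is in the flow domain (a
    log-domain fit would reweight residuals toward the small flows at the
    end of expiration).  ``times`` are seconds since the window start
    (peak-flow sample).  A fit with K <= 0 or a failed optimizer is
    returned with ``converged=False`` and excluded from trend statistics by
    the caller.
    """
    config = config or RunConfig()
    t = np.asarray(times, dtype=float)
    q = np.asarray(flow_mag, dtype=float)
    n = t.size
    if n < config.min_samples:
        return ExpiratoryFit(K=np.nan, Q0=np.nan, tau=np.nan, n_fit=n,
                             fit_span=(0, n), converged=False,
                             flags=("unfittable",))
    if init is None:
        init = loglinear_decay_rate(t, q, config.flow_floor)
        k0, q0 = max(init[0], 1e-3), max(init[1], config.flow_floor)
    else:
        k0, q0 = init

    def resid(p):
        # clip the exponent: trial steps can wander to extreme K
        return p[0] * np.exp(-np.clip(p[1] * t, -700.0, 700.0)) - q

    def jac(p):
        e = np.exp(-np.clip(p[1] * t, -700.0, 700.0))
        return np.column_stack([e, -p[0] * t * e])

    sol = least_squares(resid, x0=[q0, k0], jac=jac, method="lm",
                        xtol=config.fit_tol, ftol=config.fit_tol,
                        gtol=config.fit_tol, max_nfev=config.max_nfev)
    Q0, K = float(sol.x[0]), float(sol.x[1])
    ok = bool(sol.success) and K > 0.0 and Q0 > 0.0
    flags = () if ok else ("fit_failed",)
    fit = ExpiratoryFit(K=K, Q0=Q0, tau=1.0 / K if K > 0 else np.nan,
                        n_fit=n, fit_span=(0, n), converged=ok, flags=flags)
    if ok:
        err = fitting_error(q, predict_expiratory_flow(fit, t),
                            mode=config.error_mode,
                            floor_frac=config.error_floor_frac)
        if isinstance(err, FitError):
            fit.error_median, fit.error_q25, fit.error_q75 = err.to_tuple()
        else:
            fit.flags = fit.flags + ("error_undefined",)
    return fit


def predict_expiratory_flow(fit: ExpiratoryFit, times: np.ndarray) -> np.ndarray:
    """Model flow magnitude Q0*exp(-K t) at the given times."""
    t = np.asarray(times, dtype=float)
    return fit.Q0 * np.exp(-fit.K * t)
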