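"""Run configuration for waveform ingestion, segmentation and fitting."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Declarative knobs for the whole analysis pipeline.

    Thresholds expressed as ``*_frac`` are fractions of a per-record flow
    peak (taken separately for the positive/inspiratory and the
    negative/expiratory lobe, since peak expiratory flow E*Vt/R can exceed
    the set inspiratory flow several-fold).
    """

    # --- input column mapping -------------------------------------------------
    time_col: str = "time_s"
    pressure_col: str = "pressure_cmH2O"
    flow_col: str = "flow_Lps"
    #: set True when the file stores expiratory flow as positive; internally
    #: flow is always inspiration-positive.
    expiration_positive: bool = False
    #: tolerated jitter of the sample interval, seconds
    sampling_tol: float = 1e-6

    # --- segmentation ---------------------------------------------------------
    q_on_frac: float = 0.05      # hysteresis: onset when flow rises through this
    q_off_frac: float = 0.02     # ...after having been below this
    q_zero_frac: float = 0.01    # |flow| below this counts as zero-flow (EIP)
    smooth_window: int = 7       # boxcar width (samples) for boundary detection
    min_breath_period_s: float = 0.5
    min_samples: int = 5         # per phase, for a phase to be usable downstream
    min_pause_samples: int = 3   # to accept an end-inspiratory pause

    # --- expiratory time-constant fit -----------------------------------------
    truncation_fraction: float = 0.95   # fit up to 95% of equilibrium
    equilibrium_tail_frac: float = 0.10  # Q_eq = median of this final fraction
    flow_floor: float = 1e-4            # L/s, clip for the log-domain initializer
    max_nfev: int = 200
    fit_tol: float = 1e-10

    # --- inspiratory estimators -----------------------------------------------
    #: span of the integral-based fit; the pause is load-bearing for
    #: identifiability under exactly constant square flow
    integral_span: str = "inspiration+pause"   # or "inspiration"
    #: cumulative volume rule: "rectangle" (backward, exact for square flow
    #: with step transitions at sample instants) or "trapezoid"
    volume_rule: str = "rectangle"
    cond_limit: float = 1e8
    e_range: tuple[float, float] = (0.0, 200.0)   # cmH2O/L physiological flags
    r_range: tuple[float, float] = (0.0, 100.0)   # cmH2O.s/L
    pplat_settle_tol: float = 0.3   # cmH2O drift across the pause -> unsettled
                                    # flag (floor; raised adaptively with noise)

    # --- fitting-error metric -------------------------------------------------
    error_mode: str = "relative"     # or "peak"
    error_floor_frac: float = 0.01   # relative mode excludes |m| < frac*peak

    # --- misc -----------------------------------------------------------------
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.truncation_fraction < 1.0:
            raise ConfigError("truncation_fraction must be in (0, 1)")
        for name in ("q_on_frac", "q_off_frac", "q_zero_frac",
                     "min_breath_period_s", "error_floor_frac",
                     "equilibrium_tail_frac"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.q_off_frac >= self.q_on_frac:
            raise ConfigError("q_off_frac must be below q_on_frac (hysteresis)")
        if self.error_mode not in ("relative", "peak"):
            raise ConfigError(f"unknown error_mode {self.error_mode!r}")
        if self.integral_span not in ("inspiration+pause", "inspiration"):
            raise ConfigError(f"unknown integral_span {self.integral_span!r}")
        if self.volume_rule not in ("rectangle", "trapezoid"):
            raise ConfigError(f"unknown volume_rule {self.volume_rule!r}")
        if self.smooth_window < 1 or self.min_samples < 2:
            raise ConfigError("smooth_window >= 1 and min_samples >= 2 required")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML key-value file; unknown keys are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config file must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    if "e_range" in raw:
        raw["e_range"] = tuple(raw["e_range"])
    if "r_range" in raw:
        raw["r_range"] = tuple(raw["r_range"])
    try:
        return RunConfig(**raw)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc
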