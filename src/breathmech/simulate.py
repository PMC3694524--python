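"""Forward simulation of single-compartment, volume-controlled ventilation.

Each breath obeys P_aw = R*Q + E*V + PEEP with a square inspiratory flow
profile, an automated end-inspiratory pause, and a passive exponential
expiration Q(t) = (E*Vt/R) * exp(-(E/R) t).  Valve transitions fall exactly
on sample instants and per-breath volume is rebased to zero at inspiratory
onset, so the emitted discrete waveform satisfies the model identities
exactly and every estimator in the package can be checked against known
ground truth.  Measurement artefacts are additive and configurable: a slow
exponential valve tail on expiratory flow, an expiratory pressure trace
that collapses to just above PEEP, optional first-order plateau settling
(to exercise the short-pause failure mode of static mechanics), and white
Gaussian noise per channel scaled to each breath's peak.

Scenario factories reproduce the three experimental phases: a healthy-state
staircase recruitment manoeuvre (PEEP 5-10-15-20-15-10-5 cmH2O), disease
progression at constant PEEP 5 with a slow-then-rapid elastance rise (with
a variable-resistance variant in which rising airway resistance decouples K
from elastance), and the same staircase in the diseased state with a
convex E(PEEP) relation and recruitment hysteresis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import VentilationRecord

__all__ = ["Trajectory", "Recruitment", "Artefacts", "SimScenario",
           "SimulationTruth", "simulate_breath", "disease_trajectory",
           "recruitment_model", "simulate_protocol",
           "phase1_scenario", "phase2_scenario", "phase3_scenario",
           "paper_scale_suite", "scenario_from_dict"]


@dataclass
class Trajectory:
    """Smooth parameter trajectory over scenario time.

    ``constant``: value everywhere.  ``sigmoid``: logistic transition from
    ``start`` to ``end`` with midpoint ``t_mid`` (s) and width ``width``
    (s; the 12%-88% transition takes about 4*width).
    """

    kind: str = "constant"
    value: float = 0.0
    start: float = 0.0
    end: float = 0.0
    t_mid: float = 0.0
    width: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sigmoid"):
            raise ConfigError(f"unknown trajectory kind {self.kind!r}")
        if self.kind == "sigmoid" and self.width <= 0:
            raise ConfigError("sigmoid width must be positive")

    def __call__(self, t: float) -> float:
        if self.kind == "constant":
            return self.value
        z = (t - self.t_mid) / self.width
        return self.start + (self.end - self.start) / (1.0 + math.exp(-z))


@dataclass
class Recruitment:
    """Convex PEEP dependence of elastance with optional hysteresis.

    E gains ``curvature * (PEEP - peep_star)**2`` so elastance is minimal at
    PEEP* ; on the descending limb of a staircase the whole elastance is
    multiplied by ``hysteresis`` <= 1 (the lung stays more compliant after
    recruitment).
    """

    curvature: float = 0.1     # cmH2O/L per (cmH2O)^2
    peep_star: float = 15.0
    hysteresis: float = 1.0

    def __post_init__(self) -> None:
        if self.curvature < 0 or not (0.0 < self.hysteresis <= 1.0):
            raise ConfigError("need curvature >= 0 and 0 < hysteresis <= 1")


@dataclass
class Artefacts:
    """Additive measurement artefacts; all default magnitudes are small."""

    tail_amp: float = 0.02      # L/s, slow expiratory valve-tail flow
    tail_tau: float = 5.0       # s, valve-tail time constant (>> R/E)
    pressure_delta: float = 1.0  # cmH2O above PEEP at valve opening
    pressure_tau: float = 0.3   # s, decay of the expiratory pressure trace
    settle_tau: float = 0.0     # s, first-order plateau settling (0 = ideal)


@dataclass
class SimScenario:
    """Full description of a simulated ventilation run."""

    fs: float = 50.0
    resp_rate: float = 20.0     # breaths/min
    t_insp: float = 1.0         # s
    t_pause: float = 0.3        # s (0 disables the EIP)
    vt: float = 0.4             # L
    peep_protocol: tuple = ((5.0, 30),)   # (level cmH2O, breath count)
    elastance: Trajectory = field(
        default_factory=lambda: Trajectory(kind="constant", value=20.0))
    resistance: Trajectory = field(
        default_factory=lambda: Trajectory(kind="constant", value=5.0))
    recruitment: Recruitment | None = None
    artefacts: Artefacts = field(default_factory=Artefacts)
    noise_flow: float = 0.05       # sigma as fraction of per-breath peak |flow|
    noise_pressure: float = 0.05   # sigma as fraction of per-breath peak |P|
    lead_in_s: float = 0.2
    seed: int | None = None
    label: str = "scenario"

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.resp_rate <= 0 or self.vt <= 0:
            raise ConfigError("fs, resp_rate and vt must be positive")
        if self.t_insp <= 0 or self.t_pause < 0:
            raise ConfigError("t_insp must be positive, t_pause >= 0")
        if not self.peep_protocol:
            raise ConfigError("peep_protocol must be non-empty")
        if self.t_exp <= 0:
            raise ConfigError("breath period leaves no time for expiration")

    @property
    def t_exp(self) -> float:
        return 60.0 / self.resp_rate - self.t_insp - self.t_pause

    @property
    def n_breaths(self) -> int:
        return int(sum(c for _, c in self.peep_protocol))


@dataclass
class SimulationTruth:
    """Per-breath ground truth aligned one-to-one with emitted breaths."""

    table: pd.DataFrame   # breath, t_start, E, R, K, peep, phase, direction

    def __len__(self) -> int:
        return len(self.table)


def _phase_samples(duration: float, fs: float, what: str) -> int:
    n = int(round(duration * fs))
    if duration > 0 and n < 2:
        raise ConfigError(f"{what} duration {duration:g} s shorter than "
                          f"2 samples at fs={fs:g} Hz")
    return n


def simulate_breath(E: float, R: float, peep: float, fs: float,
                    t_insp: float, t_pause: float, t_exp: float, vt: float,
                    artefacts: Artefacts | None = None,
                    ) -> tuple[np.ndarray, np.ndarray, dict]:
    """One noise-free breath; returns (pressure, flow, truth).

    The delivered tidal volume is ``Q * (n_insp - 1) * dt`` with
    Q = vt / t_insp (the valve closes exactly at the last inspiratory
    sample), so the trapezoidal integral of the emitted inspiratory flow
    reproduces it exactly.
    """
    if min(E, R) <= 0:
        raise ConfigError("E and R must be positive")
    art = artefacts or Artefacts()
    dt = 1.0 / fs
    n_i = _phase_samples(t_insp, fs, "inspiration")
    n_p = _phase_samples(t_pause, fs, "pause")
    n_e = _phase_samples(t_exp, fs, "expiration")
    if n_i < 2 or n_e < 2:
        raise ConfigError("inspiration and expiration need >= 2 samples")

    Q = vt / t_insp
    vt_d = Q * (n_i - 1) * dt         # delivered volume at valve closure
    j = np.arange(n_i)
    v_insp = Q * j * dt
    p_insp = R * Q + E * v_insp + peep
    q_insp = np.full(n_i, Q)

    pplat = E * vt_d + peep
    pip = R * Q + E * vt_d + peep
    if n_p:
        tp = (np.arange(n_p) + 1) * dt
        if art.settle_tau > 0:
            p_pause = pplat + (pip - pplat) * np.exp(-tp / art.settle_tau)
        else:
            p_pause = np.full(n_p, pplat)
        q_pause = np.zeros(n_p)
    else:
        p_pause = np.empty(0)
        q_pause = np.empty(0)

    K = E / R
    te = np.arange(n_e) * dt
    q_ideal = (E * vt_d / R) * np.exp(-K * te)
    q_exp = -(q_ideal + art.tail_amp * np.exp(-te / art.tail_tau))
    p_exp = peep + art.pressure_delta * np.exp(-te / art.pressure_tau)

    pressure = np.concatenate([p_insp, p_pause, p_exp])
    flow = np.concatenate([q_insp, q_pause, q_exp])
    truth = {"E": E, "R": R, "K": K, "peep": peep, "vt_delivered": vt_d,
             "n_insp": n_i, "n_pause": n_p, "n_exp": n_e}
    return pressure, flow, truth


def disease_trajectory(kind: str, *, duration: float,
                       e_healthy: float = 20.0, e_ards: float = 60.0,
                       r_healthy: float = 5.0, r_ards: float = 10.0,
                       e_mid_frac: float = 0.6, e_width_frac: float = 0.08,
                       r_mid_frac: float = 0.3, r_width_frac: float = 0.05,
                       ) -> tuple[Trajectory, Trajectory]:
    """E(t), R(t) trajectories for the disease-progression scenarios.

    ``ards-sigmoid-E-constant-R`` is the slow-then-rapid elastance rise with
    constant resistance under which K = E/R tracks elastance;
    ``ards-sigmoid-E-rising-R`` additionally raises resistance (earlier and
    faster), which transiently drives K = E/R *down* even as the lung
    stiffens -- the decoupling seen when airway narrowing accompanies
    disease progression.
    """
    if kind == "healthy-constant":
        return (Trajectory(kind="constant", value=e_healthy),
                Trajectory(kind="constant", value=r_healthy))
    if kind == "ards-sigmoid-E-constant-R":
        return (Trajectory(kind="sigmoid", start=e_healthy, end=e_ards,
                           t_mid=e_mid_frac * duration,
                           width=e_width_frac * duration),
                Trajectory(kind="constant", value=r_healthy))
    if kind == "ards-sigmoid-E-rising-R":
        return (Trajectory(kind="sigmoid", start=e_healthy, end=e_ards,
                           t_mid=e_mid_frac * duration,
                           width=e_width_frac * duration),
                Trajectory(kind="sigmoid", start=r_healthy, end=r_ards,
                           t_mid=r_mid_frac * duration,
                           width=r_width_frac * duration))
    raise ConfigError(f"unknown disease trajectory kind {kind!r}")


def recruitment_model(peep: float, direction: str,
                      params: Recruitment) -> float:
    """Multiplicative/additive elastance modifier for a PEEP step.

    Returns the elastance *increment factor pair* applied as
    ``E_eff = (E_base + curvature*(peep - peep_star)^2) * h`` with h the
    hysteresis factor on the descending limb; here the combined mapping is
    returned as (additive term, multiplier) folded into one callable-free
    helper: ``E_eff = recruitment_model(...) applied by caller``.
    """
    add = params.curvature * (peep - params.peep_star) ** 2
    mult = params.hysteresis if direction == "descending" else 1.0
    return add, mult


def _protocol_directions(levels: list[float]) -> list[str]:
    """ascending up to (and including) the first maximal step, then descending."""
    peak = int(np.argmax(levels))
    return ["ascending" if i <= peak else "descending"
            for i in range(len(levels))]


def simulate_protocol(scenario: SimScenario,
                      ) -> tuple[VentilationRecord, SimulationTruth]:
    """Concatenated breaths over the PEEP protocol, with noise and truth.

    Fully reproducible from (scenario, seed); the seed is mandatory.
    """
    if scenario.seed is None:
        raise ConfigError("scenario seed is mandatory")
    rng = np.random.default_rng(scenario.seed)
    dt = 1.0 / scenario.fs
    period = scenario.t_insp + scenario.t_pause + scenario.t_exp

    levels = [lvl for lvl, _ in scenario.peep_protocol]
    counts = [int(c) for _, c in scenario.peep_protocol]
    dirs = _protocol_directions(levels)

    p_parts: list[np.ndarray] = []
    q_parts: list[np.ndarray] = []
    rows: list[dict] = []

    n_lead = int(round(scenario.lead_in_s * scenario.fs))
    if n_lead:
        p_parts.append(np.full(n_lead, float(levels[0])))
        q_parts.append(np.zeros(n_lead))

    t_start = n_lead * dt
    b_index = 0
    for lvl, count, direction in zip(levels, counts, dirs):
        for _ in range(count):
            E = scenario.elastance(t_start)
            R = scenario.resistance(t_start)
            if scenario.recruitment is not None:
                add, mult = recruitment_model(lvl, direction,
                                              scenario.recruitment)
                E = (E + add) * mult
            p, q, truth = simulate_breath(
                E, R, lvl, scenario.fs, scenario.t_insp, scenario.t_pause,
                scenario.t_exp, scenario.vt, scenario.artefacts)
            if scenario.noise_flow > 0:
                q = q + rng.normal(0.0, scenario.noise_flow *
                                   np.max(np.abs(q)), q.size)
            if scenario.noise_pressure > 0:
                p = p + rng.normal(0.0, scenario.noise_pressure *
                                   np.max(np.abs(p)), p.size)
            p_parts.append(p)
            q_parts.append(q)
            rows.append({"breath": b_index, "t_start": t_start,
                         "E": truth["E"], "R": truth["R"], "K": truth["K"],
                         "peep": lvl, "phase": scenario.label,
                         "direction": direction})
            t_start += period
            b_index += 1

    flow = np.concatenate(q_parts)
    pressure = np.concatenate(p_parts)
    time = np.arange(flow.size) * dt
    record = VentilationRecord(time=time, pressure=pressure, flow=flow,
                               fs=scenario.fs,
                               meta={"phase": scenario.label,
                                     "seed": scenario.seed})
    return record, SimulationTruth(table=pd.DataFrame(rows))


# --------------------------------------------------------------------------
# scenario factories for the three experimental phases
# --------------------------------------------------------------------------

_STAIRCASE = (5.0, 10.0, 15.0, 20.0, 15.0, 10.0, 5.0)


def phase1_scenario(seed: int, breaths_per_step: int = 30) -> SimScenario:
    """Healthy-state staircase recruitment manoeuvre."""
    return SimScenario(
        peep_protocol=tuple((lvl, breaths_per_step) for lvl in _STAIRCASE),
        elastance=Trajectory(kind="constant", value=20.0),
        resistance=Trajectory(kind="constant", value=5.0),
        recruitment=Recruitment(curvature=0.08, peep_star=15.0,
                                hysteresis=0.95),
        seed=seed, label="phase1",
    )


def phase2_scenario(seed: int, n_breaths: int = 500,
                    variable_resistance: bool = False) -> SimScenario:
    """Disease progression at constant PEEP 5 cmH2O."""
    duration = n_breaths * 3.0   # 20 breaths/min
    kind = ("ards-sigmoid-E-rising-R" if variable_resistance
            else "ards-sigmoid-E-constant-R")
    e_traj, r_traj = disease_trajectory(kind, duration=duration)
    return SimScenario(
        peep_protocol=((5.0, n_breaths),),
        elastance=e_traj, resistance=r_traj,
        seed=seed,
        label="phase2-varR" if variable_resistance else "phase2",
    )


def phase3_scenario(seed: int, breaths_per_step: int = 30,
                    hysteresis: float = 0.9) -> SimScenario:
    """ARDS-state staircase recruitment manoeuvre."""
    return SimScenario(
        peep_protocol=tuple((lvl, breaths_per_step) for lvl in _STAIRCASE),
        elastance=Trajectory(kind="constant", value=40.0),
        resistance=Trajectory(kind="constant", value=8.0),
        recruitment=Recruitment(curvature=0.15, peep_star=15.0,
                                hysteresis=hysteresis),
        seed=seed, label="phase3",
    )


def paper_scale_suite(seed: int) -> list[SimScenario]:
    """Three subjects x three phases, ~6800 breaths in total."""
    out: list[SimScenario] = []
    for s in range(3):
        sub_seed = seed + 1000 * s
        p1 = phase1_scenario(sub_seed, breaths_per_step=42)
        p2 = phase2_scenario(sub_seed + 1, n_breaths=1700,
                             variable_resistance=(s == 2))
        p3 = phase3_scenario(sub_seed + 2, breaths_per_step=42)
        for ph in (p1, p2, p3):
            out.append(replace(ph, label=f"subject{s + 1}-{ph.label}"))
    return out


_BUILTIN = {"phase1": phase1_scenario, "phase2": phase2_scenario,
            "phase3": phase3_scenario}


def builtin_scenario(name: str, seed: int | None = None, **kw) -> SimScenario:
    if name not in _BUILTIN:
        raise ConfigError(f"unknown scenario {name!r}; "
                          f"builtins: {sorted(_BUILTIN)}")
    if seed is None:
        raise ConfigError("scenario seed is mandatory")
    return _BUILTIN[name](seed, **kw)


def scenario_from_dict(raw: dict) -> SimScenario:
    """Build a scenario from a YAML-style mapping."""
    raw = dict(raw)
    if "elastance" in raw:
        raw["elastance"] = Trajectory(**raw["elastance"])
    if "resistance" in raw:
        raw["resistance"] = Trajectory(**raw["resistance"])
    if raw.get("recruitment") is not None:
        raw["recruitment"] = Recruitment(**raw["recruitment"])
    if "artefacts" in raw:
        raw["artefacts"] = Artefacts(**raw["artefacts"])
    if "peep_protocol" in raw:
        raw["peep_protocol"] = tuple(
            (float(lvl), int(c)) for lvl, c in raw["peep_protocol"])
    try:
        return SimScenario(**raw)
    except TypeError as exc:
        raise ConfigError(f"bad scenario: {exc}") from exc
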