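"""Breath detection and phase splitting.

A record is partitioned into breaths (inspiration, optional end-inspiratory
pause, expiration) from the flow channel alone, so that the tool works on
waveform-only input.  Detection runs on a boxcar-smoothed copy of the flow
with hysteresis thresholding; phase boundaries are then refined to
half-amplitude crossings of the smoothed signal, which locates a step edge
to within one sample and is robust to additive noise.  All indices are
0-based half-open spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .errors import SegmentationError
from .io import VentilationRecord

__all__ = ["Breath", "segment_breaths", "split_phases",
           "detect_inspiration_onsets"]


@dataclass
class Breath:
    """Index spans of one breathing cycle within a record.

    ``exp_start`` is the sample of peak expiratory-flow magnitude within the
    expiratory span (the fitting clock of the time-constant model starts
    there, excluding the valve-opening transient); ``pause_end`` marks the
    expiratory-valve opening, so samples in ``[pause_end, exp_start)`` belong
    to the opening transient.
    """

    insp_start: int
    insp_end: int
    pause_start: int
    pause_end: int
    exp_start: int
    exp_end: int
    peep_estimate: float = np.nan
    has_eip: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ok = (self.insp_start < self.insp_end <= self.pause_start
              <= self.pause_end <= self.exp_start < self.exp_end)
        if not ok:
            raise SegmentationError(f"inconsistent breath spans: {self}")

    @property
    def n_insp(self) -> int:
        return self.insp_end - self.insp_start

    @property
    def n_pause(self) -> int:
        return self.pause_end - self.pause_start

    @property
    def n_exp(self) -> int:
        return self.exp_end - self.exp_start


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def _noise_scale(flow: np.ndarray) -> float:
    # robust per-sample noise sigma from first differences (MAD estimator);
    # square-wave edges are sparse so the median is noise-dominated
    d = np.abs(np.diff(flow))
    return 1.4826 * float(np.median(d)) / np.sqrt(2.0)


def detect_inspiration_onsets(flow_smooth: np.ndarray, q_on: float,
                              q_off: float, min_gap: int,
                              dwell: int = 10,
                              flow_raw: np.ndarray | None = None) -> np.ndarray:
    """Hysteresis onset detection on the smoothed flow.

    An onset is an upward crossing of ``q_on`` that was preceded (since the
    last accepted onset, or record start) by flow below ``q_off`` and that
    *persists*: the mean of the next ``dwell`` raw samples must stay above
    ``q_on``.  A real inspiration sustains positive flow for the whole
    inspiratory time, whereas a noise bump in the pause or expiratory tail
    is a few samples wide and sits next to zero or negative flow, so its
    window mean collapses (persistence is judged on the raw channel because
    smoothing stretches a single spike over the boxcar width).  Onsets
    closer than ``min_gap`` samples to the previous one are ignored.
    """
    if flow_raw is None:
        flow_raw = flow_smooth
    above = flow_smooth >= q_on
    cand = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    onsets: list[int] = []
    prev = 0
    for i in cand:
        if onsets and i - onsets[-1] < min_gap:
            continue
        if np.mean(flow_raw[i:i + dwell]) < q_on:
            continue
        seg = flow_smooth[prev:i]
        if seg.size and np.min(seg) < q_off:
            onsets.append(int(i))
            prev = int(i)
    return np.asarray(onsets, dtype=int)


def split_phases(record: VentilationRecord, insp_onsets: np.ndarray,
                 config: RunConfig | None = None) -> list[Breath]:
    """Refine onsets and assign phase boundaries between consecutive onsets.

    Partial leading/trailing cycles are dropped: the span before the first
    onset is discarded, and the final span is kept only if its expiration has
    decayed below the expiratory onset threshold by the end of the record.
    """
    config = config or RunConfig()
    flow = record.flow
    sm = _smooth(flow, config.smooth_window)
    n = flow.size
    pos_peak = float(np.max(sm)) if np.max(sm) > 0 else 0.0
    neg_peak = float(-np.min(sm)) if np.min(sm) < 0 else 0.0
    sigma_sm = _noise_scale(flow) / np.sqrt(config.smooth_window)
    q_on_exp = max(config.q_on_frac * neg_peak, 4.0 * sigma_sm)
    q_zero = config.q_zero_frac * max(pos_peak, neg_peak)
    zero_thresh = max(q_zero, 3.0 * sigma_sm)

    breaths: list[Breath] = []
    spans = list(zip(insp_onsets, list(insp_onsets[1:]) + [n]))
    for k, (o, nxt) in enumerate(spans):
        is_last = k == len(spans) - 1
        seg = sm[o:nxt]
        # inspiratory plateau level: median over the contiguous run above q_off
        run = np.flatnonzero(seg < config.q_off_frac * pos_peak)
        run_end = int(run[0]) if run.size else seg.size
        if run_end < 1:
            continue
        q_level = float(np.median(seg[:run_end]))
        if q_level <= 0:
            continue
        # refine inspiration start to the half-amplitude crossing; the edge
        # midpoint is referenced to the pre-onset level so that the residual
        # expiratory tail of a slow previous breath does not bias the edge
        pre = sm[max(0, o - config.smooth_window):o]
        pre_level = min(0.0, float(np.median(pre))) if pre.size else 0.0
        start_c = np.flatnonzero(seg >= pre_level + 0.5 * (q_level - pre_level))
        insp_start = o + int(start_c[0]) if start_c.size else o
        # inspiration ends at the first drop below half level once the
        # plateau has actually been reached (guards against onset-ramp samples)
        reach = np.flatnonzero(sm[insp_start:nxt] >= 0.75 * q_level)
        if not reach.size:
            continue
        plateau = insp_start + int(reach[0])
        end_c = np.flatnonzero(sm[plateau:nxt] < 0.5 * q_level)
        if not end_c.size:
            continue  # inspiration never ends: partial cycle
        insp_end = plateau + int(end_c[0])
        # expiration: crossing of half the (negative) peak after inspiration
        tail = sm[insp_end:nxt]
        if not tail.size or np.min(tail) >= -q_on_exp:
            continue  # no expiratory flow: partial cycle
        exp_min = float(np.min(tail))
        exp_c = np.flatnonzero(tail <= 0.5 * exp_min)
        pause_end = insp_end + int(exp_c[0])
        if is_last and abs(sm[n - 1]) >= q_on_exp:
            continue  # record ends mid-expiration: trailing partial dropped
        exp_span_abs = np.abs(flow[pause_end:nxt])
        exp_start = pause_end + int(np.argmax(exp_span_abs))
        if nxt - exp_start < 2:
            continue
        flags: list[str] = []
        n_pause = pause_end - insp_end
        has_eip = n_pause >= config.min_pause_samples
        if has_eip:
            pause_level = float(np.median(np.abs(sm[insp_end:pause_end])))
            has_eip = pause_level < zero_thresh
        if not has_eip:
            flags.append("no_eip")
        if insp_end - insp_start < config.min_samples:
            flags.append("short_insp")
        if nxt - exp_start < config.min_samples:
            flags.append("short_exp")
        breaths.append(Breath(
            insp_start=insp_start, insp_end=insp_end,
            pause_start=insp_end, pause_end=pause_end,
            exp_start=exp_start, exp_end=int(nxt),
            has_eip=has_eip, flags=flags,
        ))
    return breaths


def _estimate_peep(record: VentilationRecord, breaths: list[Breath]) -> None:
    """End-expiratory pressure per breath: median over the final quarter of
    the previous expiration (own expiration for the first breath)."""
    for i, b in enumerate(breaths):
        ref = breaths[i - 1] if i > 0 else b
        n_exp = ref.exp_end - ref.exp_start
        q0 = ref.exp_end - max(1, n_exp // 4)
        b.peep_estimate = float(np.median(record.pressure[q0:ref.exp_end]))


def segment_breaths(record: VentilationRecord,
                    config: RunConfig | None = None) -> list[Breath]:
    """Partition a record into complete breathing cycles.

    Raises :class:`SegmentationError` when no complete
    inspiration -> expiration cycle is found.
    """
    config = config or RunConfig()
    sm = _smooth(record.flow, config.smooth_window)
    pos_peak = float(np.max(sm))
    if pos_peak <= 0:
        raise SegmentationError("no inspiratory flow in record")
    # thresholds never drop into the noise floor: noise scales with the
    # (often much larger) expiratory peak, not the inspiratory one
    sigma_sm = _noise_scale(record.flow) / np.sqrt(config.smooth_window)
    q_on = max(config.q_on_frac * pos_peak, 4.0 * sigma_sm)
    q_off = max(config.q_off_frac * pos_peak, 2.0 * sigma_sm)
    if q_off >= q_on:
        q_off = 0.5 * q_on
    min_gap = max(1, int(round(config.min_breath_period_s * record.fs)))
    dwell = max(config.min_samples, int(round(0.3 * record.fs)))
    onsets = detect_inspiration_onsets(sm, q_on, q_off, min_gap,
                                       dwell=dwell, flow_raw=record.flow)
    if not onsets.size:
        raise SegmentationError("no inspiration onset detected")
    breaths = split_phases(record, onsets, config)
    if not breaths:
        raise SegmentationError("no complete breathing cycle found")
    _estimate_peep(record, breaths)
    return breaths
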