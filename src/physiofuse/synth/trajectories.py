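"""Continuous ground-truth trajectories for heart rate and StO2.

Heart rate follows a piecewise first-order relaxation: within each protocol
phase HR(t) approaches the phase target (the midpoint of the prescribed
%HRmax zone, or resting HR for rest/recovery phases) exponentially with
time constant ``tau_s``, starting from the value at the phase boundary so
the trajectory is continuous.  This is deliberately phenomenological — the
point is a known, exactly recoverable HR(t), not cardiovascular mechanics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..protocol import EventTimeline
from ..streams import NS_PER_S


@dataclass(frozen=True)
class _ExpSegment:
    t0_s: float
    t1_s: float
    start_value: float
    target: float
    tau_s: float

    def __call__(self, t_s: np.ndarray) -> np.ndarray:
        dt = np.asarray(t_s, dtype=float) - self.t0_s
        if self.tau_s <= 0:
            return np.full_like(dt, self.target, dtype=float)
        return self.target + (self.start_value - self.target) * np.exp(-dt / self.tau_s)


class PiecewiseExpTrajectory:
    """Continuous piecewise first-order exponential approach to phase targets."""

    def __init__(self, segments: list[_ExpSegment], lo: float, hi: float):
        self._segments = segments
        self.lo = lo
        self.hi = hi
        self.t_start_s = segments[0].t0_s
        self.t_end_s = segments[-1].t1_s

    def __call__(self, t_s) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t_s, dtype=float))
        out = np.empty_like(t)
        edges = np.array([s.t0_s for s in self._segments] + [self._segments[-1].t1_s])
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(self._segments) - 1)
        for i, seg in enumerate(self._segments):
            m = idx == i
            if m.any():
                out[m] = seg(t[m])
        out = np.clip(out, self.lo, self.hi)
        return out if np.ndim(t_s) else float(out[0])

    def sample(self, rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
        n = int(np.floor((self.t_end_s - self.t_start_s) * rate_hz))
        t = self.t_start_s + np.arange(n) / rate_hz
        return t, self(t)


HRTrajectory = PiecewiseExpTrajectory


def _phase_target_hr(params: dict, hr_rest: float, hr_max: float) -> float:
    zone = params.get("hr_zone")
    if zone is None or tuple(zone) == (0.0, 0.0):
        return hr_rest
    lo, hi = zone
    return 0.5 * (lo + hi) * hr_max


def simulate_hr_trajectory(
    timeline: EventTimeline,
    hr_rest: float = 60.0,
    hr_max: float = 190.0,
    tau_s: float = 30.0,
    seed=None,
) -> HRTrajectory:
    """Ground-truth HR(t) in bpm over a protocol timeline.

    Each phase's target is the midpoint of its ``hr_zone`` (fraction of
    ``hr_max``); rest/recovery phases target ``hr_rest``.  The trajectory
    relaxes toward the target with time constant ``tau_s`` and is continuous
    at phase boundaries.  The result is clipped to the physiological band
    [30, 220] bpm.  ``seed`` is accepted for interface symmetry; the
    trajectory itself is deterministic.
    """
    if hr_rest >= hr_max:
        raise ValueError(f"hr_rest ({hr_rest}) must be below hr_max ({hr_max})")
    segments: list[_ExpSegment] = []
    current = hr_rest
    for ev in timeline:
        target = _phase_target_hr(ev.params, hr_rest, hr_max)
        t0, t1 = ev.start_ns / NS_PER_S, ev.end_ns / NS_PER_S
        seg = _ExpSegment(t0, t1, current, target, tau_s)
        segments.append(seg)
        current = float(seg(np.array([t1]))[0])
    return PiecewiseExpTrajectory(segments, lo=30.0, hi=220.0)


def occlusion_sto2_trajectory(
    timeline: EventTimeline,
    baseline_pct: float = 65.0,
    desat_rate_pct_per_min_per_mmhg: float = 0.10,
    reperfusion_overshoot_pct: float = 5.0,
    recovery_tau_s: float = 30.0,
    overshoot_peak_s: float = 20.0,
):
    """Ground-truth StO2(t) in percent over an occlusion protocol.

    Baseline phases hold a plateau.  During an occlusion phase at cuff
    pressure P mmHg the trace desaturates linearly at
    ``desat_rate * P`` %/min — steeper desaturation under higher pressure,
    matching the graded cuff design.  Recovery is an exponential return to
    baseline (time constant ``recovery_tau_s``) plus a transient
    reperfusion-hyperaemia overshoot shaped as an alpha function peaking at
    ``overshoot_peak_s``.  Output clipped to [0, 100].

    Returns a callable ``sto2(t_s) -> %``.
    """
    events = list(timeline)
    # precompute the value entering each phase
    entry = np.empty(len(events) + 1)
    entry[0] = baseline_pct

    def phase_value(i: int, t_rel: np.ndarray) -> np.ndarray:
        ev = events[i]
        p = float(ev.params.get("pressure_mmhg", 0.0))
        v0 = entry[i]
        if p > 0:
            slope = desat_rate_pct_per_min_per_mmhg * p / 60.0  # %/s
            return v0 - slope * t_rel
        if v0 == baseline_pct:  # plateau
            return np.full_like(t_rel, baseline_pct, dtype=float)
        # recovery: exponential return + alpha-function overshoot
        decay = baseline_pct + (v0 - baseline_pct) * np.exp(-t_rel / recovery_tau_s)
        x = t_rel / overshoot_peak_s
        overshoot = reperfusion_overshoot_pct * x * np.exp(1.0 - x)
        return decay + overshoot

    for i, ev in enumerate(events):
        dur = (ev.end_ns - ev.start_ns) / NS_PER_S
        entry[i + 1] = float(phase_value(i, np.array([dur]))[0])

    edges_ns = np.array([e.start_ns for e in events] + [events[-1].end_ns], dtype=np.int64)

    def sto2(t_s):
        t = np.atleast_1d(np.asarray(t_s, dtype=float))
        t_ns = (t * NS_PER_S).astype(np.int64)
        idx = np.clip(np.searchsorted(edges_ns, t_ns, side="right") - 1, 0, len(events) - 1)
        out = np.empty_like(t)
        for i in range(len(events)):
            m = idx == i
            if m.any():
                out[m] = phase_value(i, t[m] - events[i].start_ns / NS_PER_S)
        out = np.clip(out, 0.0, 100.0)
        return out if np.ndim(t_s) else float(out[0])

    return sto2
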