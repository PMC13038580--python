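"""Synthetic tissue-oxygenation streams over the graded occlusion protocol."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..protocol import EventTimeline
from ..streams import NS_PER_S, TimestampedStream, s_to_ns
from .trajectories import occlusion_sto2_trajectory


@dataclass(frozen=True)
class OcclusionKinetics:
    """Desaturation/reperfusion kinetics of the synthetic StO2 trace.

    ``desat_rate_pct_per_min_per_mmhg`` sets the linear desaturation slope
    per unit cuff pressure (so the 200 mmHg step falls twice as fast as the
    100 mmHg step by construction); ``reperfusion_overshoot_pct`` is the
    transient hyperaemic overshoot above baseline on cuff release.
    """

    baseline_pct: float = 65.0
    desat_rate_pct_per_min_per_mmhg: float = 0.10
    reperfusion_overshoot_pct: float = 5.0
    recovery_tau_s: float = 30.0


def synth_sto2_occlusion(
    timeline: EventTimeline,
    kinetics: OcclusionKinetics = OcclusionKinetics(),
    rate_hz: float = 0.5,
    noise_sd: float = 0.5,
    device_id: str = "moxy",
    seed=None,
) -> tuple[TimestampedStream, object]:
    """Sample the occlusion StO2 trajectory at a device rate.

    Returns ``(stream, trajectory)`` where ``trajectory`` is the noiseless
    ground-truth callable (percent vs seconds).  Values are clipped to
    [0, 100] after noise.
    """
    rng = np.random.default_rng(seed)
    traj = occlusion_sto2_trajectory(
        timeline,
        baseline_pct=kinetics.baseline_pct,
        desat_rate_pct_per_min_per_mmhg=kinetics.desat_rate_pct_per_min_per_mmhg,
        reperfusion_overshoot_pct=kinetics.reperfusion_overshoot_pct,
        recovery_tau_s=kinetics.recovery_tau_s,
    )
    t0 = timeline.start_ns / NS_PER_S
    t1 = timeline.end_ns / NS_PER_S
    n = int(np.floor((t1 - t0) * rate_hz))
    t = t0 + np.arange(n) / rate_hz
    vals = np.asarray(traj(t), dtype=float)
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=n)
    vals = np.clip(vals, 0.0, 100.0)
    stream = TimestampedStream(
        device_id=device_id,
        metric="sto2",
        units="%",
        native_rate_hz=rate_hz,
        timestamps=s_to_ns(t),
        values=vals,
    )
    return stream, traj
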