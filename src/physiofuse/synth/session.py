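"""Whole-session assembly: streams + ground-truth sidecar.

:func:`generate_session` builds a complete multi-device recording session
for a built-in protocol — ECG at 200 Hz, a fast optical channel at ~38 Hz,
muscle oxygenation at 0.5 Hz, device-reported heart rate at ~1 Hz — plus a
BLE dropout on the ECG stream with a clock-offset cached copy, and records
everything needed to score the downstream estimators in a
:class:`GroundTruth` sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..protocol import EventTimeline, get_template, make_timeline
from ..streams import NS_PER_S, TimestampedStream
from .devices import DeviceErrorModel, split_streamed_cached, synth_device_hr
from .ecg import synth_ecg
from .sto2 import OcclusionKinetics, synth_sto2_occlusion
from .trajectories import simulate_hr_trajectory


@dataclass
class GroundTruth:
    """Everything a test needs to score the pipeline on one session."""

    hr_trajectory: object = None          # callable HR(t_s) bpm
    sto2_trajectory: object = None        # callable StO2(t_s) %
    beat_times_s: np.ndarray = field(default_factory=lambda: np.array([]))
    blink_times_s: np.ndarray = field(default_factory=lambda: np.array([]))
    trial_table: object = None
    injected_lag_s: float = 0.0
    dropout_intervals: list = field(default_factory=list)
    device_models: dict = field(default_factory=dict)

    def to_json_dict(self, sample_rate_hz: float = 10.0,
                     t_start_s: float = 0.0, t_end_s: float = 0.0) -> dict:
        out: dict = {
            "beat_times_s": np.asarray(self.beat_times_s).tolist(),
            "blink_times_s": np.asarray(self.blink_times_s).tolist(),
            "injected_lag_s": self.injected_lag_s,
            "dropout_intervals": [list(map(float, iv)) for iv in self.dropout_intervals],
        }
        if self.hr_trajectory is not None and t_end_s > t_start_s:
            t = np.arange(t_start_s, t_end_s, 1.0 / sample_rate_hz)
            out["hr_t_s"] = t.tolist()
            out["hr_bpm"] = np.asarray(self.hr_trajectory(t)).tolist()
        if self.sto2_trajectory is not None and t_end_s > t_start_s:
            t = np.arange(t_start_s, t_end_s, 1.0 / sample_rate_hz)
            out["sto2_t_s"] = t.tolist()
            out["sto2_pct"] = np.asarray(self.sto2_trajectory(t)).tolist()
        return out


@dataclass
class SyntheticSession:
    timeline: EventTimeline
    streams: dict  # key -> TimestampedStream (streamed copies, may have gaps)
    cached: dict   # key -> clock-offset cached copies
    truth: GroundTruth
    seed: int | None = None
    protocol: str = ""

    def write(self, out_dir) -> list[str]:
        """Write per-stream CSVs, the event timeline and the truth sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, s in {**self.streams, **{f"{k}_cached": v for k, v in self.cached.items()}}.items():
            p = out / f"{name.replace('/', '_')}.csv"
            s.to_csv(p)
            written.append(str(p))
        ev = out / "events.json"
        ev.write_text(json.dumps(self.timeline.to_records(), indent=1))
        written.append(str(ev))
        t0 = self.timeline.start_ns / NS_PER_S
        t1 = self.timeline.end_ns / NS_PER_S
        gt = out / "ground_truth.json"
        gt.write_text(json.dumps(self.truth.to_json_dict(t_start_s=t0, t_end_s=t1)))
        written.append(str(gt))
        return written


#: native-rate roster mirrored from the acquisition system
DEFAULT_DEVICE_MODELS = {
    "polar/hr": DeviceErrorModel(reporting_rate_hz=1.0, bias=0.5, response_lag_s=2.0,
                                 jitter_sd=1.0, dropout_prob=0.01),
    "nonin/pr": DeviceErrorModel(reporting_rate_hz=1.0, bias=-1.0, response_lag_s=4.0,
                                 jitter_sd=1.5, dropout_prob=0.01),
}


def generate_session(
    protocol: str = "exercise",
    seed: int | None = 0,
    hr_rest: float = 60.0,
    hr_max: float = 190.0,
    tau_s: float = 30.0,
    ecg_noise_sd: float = 0.02,
    device_models: dict | None = None,
    dropout_intervals: list | None = None,
    clock_offset_s: float = 2.5,
    sto2_kinetics: OcclusionKinetics = OcclusionKinetics(),
) -> SyntheticSession:
    """Build one ground-truthed session for a built-in protocol.

    Exercise sessions carry ECG + two reported-HR devices with
    motion-degraded ECG in the active phases; occlusion sessions carry the
    two optical StO2 streams (fast test channel at ~38 Hz, reference at
    0.5 Hz).  In both, the ECG stream suffers one BLE dropout (default one
    30 s gap in mid-session) and a complete cached copy exists with a
    constant clock offset of ``clock_offset_s``.
    """
    rng = np.random.default_rng(seed)
    template = get_template(protocol)
    timeline = make_timeline(template, start_ns=0)
    t0 = timeline.start_ns / NS_PER_S
    t1 = timeline.end_ns / NS_PER_S

    hr_traj = simulate_hr_trajectory(timeline, hr_rest=hr_rest, hr_max=hr_max, tau_s=tau_s)

    motion = []
    if protocol == "exercise":
        for ev in timeline:
            zone = ev.params.get("hr_zone", (0, 0))
            if tuple(zone) != (0.0, 0.0):
                factor = 1.0 + 4.0 * zone[1]  # harder work, more motion artifact
                motion.append((ev.start_ns / NS_PER_S, ev.end_ns / NS_PER_S, factor))

    ecg, beat_times = synth_ecg(
        hr_traj, t0, t1, fs=200.0, noise_sd=ecg_noise_sd,
        motion_segments=motion, seed=int(rng.integers(2**31)),
    )
    if dropout_intervals is None:
        mid = 0.5 * (t0 + t1)
        dropout_intervals = [(mid, mid + 30.0)]
    ecg_streamed, ecg_cached = split_streamed_cached(ecg, dropout_intervals, clock_offset_s)

    streams = {"nps/ecg": ecg_streamed}
    cached = {"nps/ecg": ecg_cached}

    models = dict(DEFAULT_DEVICE_MODELS if device_models is None else device_models)
    for key, model in models.items():
        dev, metric = key.split("/")
        streams[key] = synth_device_hr(
            hr_traj, t0, t1, model, device_id=dev, metric=metric,
            seed=int(rng.integers(2**31)),
        )

    sto2_traj = None
    if protocol == "occlusion":
        moxy, sto2_traj = synth_sto2_occlusion(
            timeline, kinetics=sto2_kinetics, rate_hz=0.5, device_id="moxy",
            seed=int(rng.integers(2**31)),
        )
        nps_sto2, _ = synth_sto2_occlusion(
            timeline, kinetics=sto2_kinetics, rate_hz=38.0, noise_sd=1.0,
            device_id="nps", seed=int(rng.integers(2**31)),
        )
        streams["moxy/sto2"] = moxy
        streams["nps/sto2"] = nps_sto2

    truth = GroundTruth(
        hr_trajectory=hr_traj,
        sto2_trajectory=sto2_traj,
        beat_times_s=beat_times,
        injected_lag_s=clock_offset_s,
        dropout_intervals=list(dropout_intervals),
        device_models=models,
    )
    return SyntheticSession(
        timeline=timeline, streams=streams, cached=cached, truth=truth,
        seed=seed, protocol=protocol,
    )
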