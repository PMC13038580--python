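"""Device error models: reported-metric streams and streamed/cached splits.

Consumer and reference devices report processed metrics (HR, PR, SpO2) at
their own rates with systematic bias, response lag, random jitter and
telemetry dropout.  BLE loss is modeled by removing streamed samples inside
dropout intervals while a complete onboard cached copy survives with its
own clock offset — the structure the alignment module has to undo.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..streams import TimestampedStream, s_to_ns


@dataclass(frozen=True)
class DeviceErrorModel:
    """Reporting behavior of one device channel.

    Defaults follow the native-rate roster of the acquisition system:
    ECG 200 Hz, optical ~38 Hz, device-reported HR ~1 Hz, muscle
    oxygenation ~0.5 Hz.
    """

    reporting_rate_hz: float = 1.0
    bias: float = 0.0               # additive systematic offset, metric units
    response_lag_s: float = 0.0     # device smoothing/processing delay
    jitter_sd: float = 0.0          # white reporting noise, metric units
    dropout_prob: float = 0.0       # per-sample iid telemetry loss
    clock_offset_s: float = 0.0     # cached-copy clock error vs reference

    def __post_init__(self):
        if self.reporting_rate_hz <= 0:
            raise ValueError("reporting_rate_hz must be > 0")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")


def synth_device_hr(
    hr_trajectory,
    t_start_s: float,
    t_end_s: float,
    model: DeviceErrorModel,
    device_id: str = "polar",
    metric: str = "hr",
    units: str = "bpm",
    seed=None,
) -> TimestampedStream:
    """Device-reported metric stream: lagged, biased, jittered, with dropout.

    Reported value at report time t is ``truth(t - lag) + bias + noise``;
    each sample is independently dropped with ``dropout_prob``.
    """
    rng = np.random.default_rng(seed)
    n = int(np.floor((t_end_s - t_start_s) * model.reporting_rate_hz))
    t = t_start_s + np.arange(n) / model.reporting_rate_hz
    vals = np.asarray(hr_trajectory(np.maximum(t - model.response_lag_s, t_start_s)), dtype=float)
    vals = vals + model.bias
    if model.jitter_sd > 0:
        vals = vals + rng.normal(0.0, model.jitter_sd, size=n)
    keep = rng.random(n) >= model.dropout_prob
    return TimestampedStream(
        device_id=device_id,
        metric=metric,
        units=units,
        native_rate_hz=model.reporting_rate_hz,
        timestamps=s_to_ns(t[keep]),
        values=vals[keep],
    )


def split_streamed_cached(
    stream: TimestampedStream,
    dropout_intervals: list[tuple[float, float]],
    clock_offset_s: float,
) -> tuple[TimestampedStream, TimestampedStream]:
    """Split a full recording into a gappy streamed copy and an offset cached copy.

    ``streamed`` drops every sample whose time falls inside a dropout
    interval (half-open ``[start, end)`` in seconds on the stream's own
    axis).  ``cached`` is the complete recording with all timestamps shifted
    by ``clock_offset_s`` — the onboard clock disagreeing with the reference
    clock by a constant.
    """
    t_s = stream.times_s
    keep = np.ones(len(stream), dtype=bool)
    for s0, s1 in dropout_intervals:
        keep &= ~((t_s >= s0) & (t_s < s1))
    streamed = replace(
        stream,
        timestamps=stream.timestamps[keep],
        values=stream.values[keep],
        valid=stream.valid[keep],
    )
    cached = replace(
        stream,
        device_id=f"{stream.device_id}_cached",
        timestamps=stream.timestamps + s_to_ns(clock_offset_s),
    )
    return streamed, cached
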