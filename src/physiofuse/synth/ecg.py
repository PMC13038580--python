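"""Synthetic template-based ECG.

The waveform is built from stereotyped complexes placed at beat times
derived by time-warping: the instantaneous rate HR(t)/60 (beats per second)
is integrated on a fine grid and a beat is emitted each time the cumulative
beat count crosses an integer.  This guarantees HR(t) is exactly recoverable
from the inter-beat intervals, which is the property the downstream R-peak
detector and HR pipeline are tested against.

The complex template is a sum of Gaussian bumps (Q, R, S, T) — a shape
adequate for exercising bandpass + adaptive-threshold R-peak detection, not
a biophysical ECG model.
"""

from __future__ import annotations

import numpy as np

from ..streams import TimestampedStream, s_to_ns

#: (center_s, width_s, amplitude) relative to the R peak, in mV
_TEMPLATE_WAVES = (
    (-0.040, 0.010, -0.10),  # Q
    (0.000, 0.008, 1.00),    # R
    (0.040, 0.010, -0.15),   # S
    (0.250, 0.060, 0.25),    # T
)


def beat_times_from_trajectory(
    hr_trajectory, t_start_s: float, t_end_s: float, grid_hz: float = 200.0
) -> np.ndarray:
    """Beat times (s) by integrating the instantaneous rate.

    The cumulative beat phase is the trapezoidal integral of HR(t)/60; beats
    fall where the phase crosses successive integers (first beat at phase 1,
    i.e. one full interval after the start).
    """
    n = int(np.ceil((t_end_s - t_start_s) * grid_hz)) + 1
    t = t_start_s + np.arange(n) / grid_hz
    rate_bps = np.asarray(hr_trajectory(t), dtype=float) / 60.0
    phase = np.concatenate([[0.0], np.cumsum(0.5 * (rate_bps[1:] + rate_bps[:-1]) / grid_hz)])
    n_beats = int(np.floor(phase[-1]))
    targets = np.arange(1, n_beats + 1, dtype=float)
    return np.interp(targets, phase, t)


def ecg_template(t_rel_s: np.ndarray, amplitude_mv: float = 1.0) -> np.ndarray:
    """PQRST-style complex evaluated at times relative to the R peak."""
    out = np.zeros_like(t_rel_s, dtype=float)
    for center, width, amp in _TEMPLATE_WAVES:
        out += amp * np.exp(-0.5 * ((t_rel_s - center) / width) ** 2)
    return amplitude_mv * out


def synth_ecg(
    hr_trajectory,
    t_start_s: float,
    t_end_s: float,
    fs: float = 200.0,
    noise_sd: float = 0.02,
    motion_segments: list[tuple[float, float, float]] | None = None,
    amplitude_mv: float = 1.0,
    seed=None,
) -> tuple[TimestampedStream, np.ndarray]:
    """Synthesize an ECG stream; returns ``(stream, ground_truth_beat_times_s)``.

    Parameters
    ----------
    hr_trajectory
        Callable HR(t_s) in bpm (see :mod:`.trajectories`).
    fs
        Sampling rate in Hz (default 200, the master ECG rate); must exceed
        twice the maximum heart frequency.
    noise_sd
        Baseline white-noise SD in mV (R amplitude is ``amplitude_mv``).
    motion_segments
        Optional ``(start_s, end_s, degradation_factor)`` intervals where
        broadband noise and low-frequency baseline wander are scaled by the
        factor, emulating motion/immersion degradation.
    """
    rng = np.random.default_rng(seed)
    duration = t_end_s - t_start_s
    max_hr_hz = float(np.max(np.asarray(
        hr_trajectory(t_start_s + np.linspace(0, duration, 512))
    ))) / 60.0
    if fs <= 2.0 * max_hr_hz:
        raise ValueError(f"fs={fs} Hz below 2x max heart frequency {max_hr_hz:.2f} Hz")

    n = int(np.floor(duration * fs))
    t = t_start_s + np.arange(n) / fs
    beat_times = beat_times_from_trajectory(hr_trajectory, t_start_s, t_end_s, grid_hz=max(fs, 200.0))

    sig = np.zeros(n)
    half_w = 0.45  # template support (s) either side of R
    for bt in beat_times:
        i0 = max(0, int(np.ceil((bt - half_w - t_start_s) * fs)))
        i1 = min(n, int(np.floor((bt + half_w - t_start_s) * fs)) + 1)
        if i1 > i0:
            sig[i0:i1] += ecg_template(t[i0:i1] - bt, amplitude_mv)

    if noise_sd > 0:
        sig += rng.normal(0.0, noise_sd, size=n)
    for seg in motion_segments or ():
        s0, s1, factor = seg
        m = (t >= s0) & (t < s1)
        if not m.any():
            continue
        extra_sd = noise_sd * max(factor - 1.0, 0.0) if noise_sd > 0 else 0.05 * max(factor - 1.0, 0.0)
        if extra_sd > 0:
            sig[m] += rng.normal(0.0, extra_sd, size=m.sum())
        # baseline wander: slow sinusoid with random phase, grows with degradation
        f_wander = rng.uniform(0.15, 0.4)
        sig[m] += 0.1 * max(factor - 1.0, 0.0) * np.sin(
            2 * np.pi * f_wander * t[m] + rng.uniform(0, 2 * np.pi)
        )

    stream = TimestampedStream(
        device_id="nps",
        metric="ecg",
        units="mV",
        native_rate_hz=fs,
        timestamps=s_to_ns(t),
        values=sig,
    )
    return stream, beat_times
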