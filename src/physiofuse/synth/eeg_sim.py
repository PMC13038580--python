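"""Synthetic Simon-task EEG sessions.

Eight channels at 250 Hz containing pink-noise background, 10 Hz posterior
alpha, stereotyped frontal-dominant blink transients, and — on error trials
only — a frontal-midline theta burst in the first 400 ms after the
response.  Stimulus/response markers are embedded and a behavioral trial
table is produced alongside, so the full cognitive pipeline (blink ICA,
epoching, rejection, ERSP, error-vs-correct contrast) can be scored against
known ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..eeg import CHANNELS_8, EEGRecording, TaskConfig

#: blink spatial profile: steep frontal falloff of the ocular dipole field
_BLINK_TOPO = {"Fz": 1.0, "C3": 0.25, "Cz": 0.30, "C4": 0.25,
               "Pz": 0.08, "PO7": 0.02, "Oz": 0.02, "PO8": 0.02}
#: frontal-midline theta: Cz-centered midline distribution
_THETA_TOPO = {"Fz": 0.90, "Cz": 1.0, "C3": 0.50, "C4": 0.50,
               "Pz": 0.40, "PO7": 0.15, "Oz": 0.15, "PO8": 0.15}
_ALPHA_CHANNELS = ("Pz", "PO7", "Oz", "PO8")
_KEY_SIDE = {"2": "left", "8": "right"}


def _pink_sources(rng: np.random.Generator, n_src: int, n: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise by spectral shaping of white noise."""
    white = rng.standard_normal((n_src, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n=n, axis=1)
    return pink / pink.std(axis=1, keepdims=True)


def _background(
    rng: np.random.Generator, n_ch: int, n: int, sd_uv: float, n_src: int = 6
) -> np.ndarray:
    """Spatially shared pink-noise background plus small sensor noise.

    Scalp EEG background is dominated by a modest number of cortical
    sources seen through volume conduction, so neighboring channels are
    strongly correlated; modeling channels as independent noise would give
    the recording more effective sources than channels and make blink-ICA
    separation impossible in principle.  ``n_src`` shared pink sources are
    mixed through a fixed random topography and topped with independent
    per-channel sensor noise at 15% of the background SD.
    """
    sources = _pink_sources(rng, n_src, n)
    mixing = rng.normal(size=(n_ch, n_src))
    mixed = mixing @ sources
    mixed *= sd_uv / mixed.std(axis=1, keepdims=True)
    sensor = rng.standard_normal((n_ch, n)) * (0.15 * sd_uv)
    return mixed + sensor


def _blink_template(fs: float, width_ms: float = 300.0) -> np.ndarray:
    n = int(round(width_ms / 1000.0 * fs))
    return 0.5 * (1.0 - np.cos(2 * np.pi * np.arange(n) / (n - 1)))  # raised cosine


def synth_eeg_simon(
    cfg: TaskConfig = TaskConfig(),
    n_blocks: int = 1,
    error_rate: float = 0.10,
    late_rate: float = 0.02,
    miss_rate: float = 0.01,
    theta_freq_hz: float = 6.0,
    theta_amp_uv: float = 8.0,
    theta_window_ms: tuple[float, float] = (0.0, 400.0),
    blink_rate_hz: float = 0.15,
    blink_amp_uv: float = 80.0,
    alpha_amp_uv: float = 4.0,
    noise_sd_uv: float = 6.0,
    fs_hz: float = 250.0,
    seed=None,
) -> tuple[EEGRecording, pd.DataFrame, dict]:
    """Generate one Simon-task EEG session.

    Returns ``(recording, trial_table, truth)`` where ``truth`` carries the
    injected blink peak times (s), the error-trial ids that received theta
    bursts, and the injected theta amplitude.
    """
    rng = np.random.default_rng(seed)
    fs = fs_hz
    n_trials = n_blocks * cfg.trials_per_block

    # ---- behavioral timeline -------------------------------------------
    lead_in_s = 3.0
    cursor = lead_in_s
    rows = []
    for k in range(n_trials):
        color = rng.choice(["red", "green"])
        side = rng.choice(["left", "right"])
        correct_key = cfg.key_map[color]
        congruent = _KEY_SIDE[correct_key] == side
        u = rng.random()
        if u < miss_rate:
            response_key, rt_ms = None, np.nan
        else:
            is_err = rng.random() < error_rate
            response_key = (
                ({"2", "8"} - {correct_key}).pop() if is_err else correct_key
            )
            if rng.random() < late_rate:
                rt_ms = rng.uniform(cfg.response_window_ms + 1.0, cfg.response_window_ms + 250.0)
            else:
                # truncated log-normal inside the response window
                rt_ms = np.inf
                while not (150.0 <= rt_ms <= cfg.response_window_ms - 1.0):
                    rt_ms = float(np.exp(rng.normal(np.log(330.0), 0.25)))
        stim_s = cursor
        resp_s = stim_s + rt_ms / 1000.0 if response_key is not None else np.nan
        rows.append({
            "trial": k,
            "block": k // cfg.trials_per_block,
            "stimulus_color": color,
            "stimulus_side": side,
            "congruency": "congruent" if congruent else "incongruent",
            "response_key": response_key,
            "rt_ms": rt_ms,
            "stim_time_s": stim_s,
            "resp_time_s": resp_s,
        })
        rsi_s = rng.uniform(*cfg.rsi_ms) / 1000.0
        cursor = stim_s + cfg.response_window_ms / 1000.0 + rsi_s
    trial_table = pd.DataFrame(rows)
    total_s = cursor + 3.0
    n = int(round(total_s * fs))
    n_ch = len(CHANNELS_8)

    # ---- signal ---------------------------------------------------------
    data = _background(rng, n_ch, n, noise_sd_uv)
    t = np.arange(n) / fs
    alpha_env = 1.0 + 0.5 * np.sin(2 * np.pi * 0.1 * t + rng.uniform(0, 2 * np.pi))
    alpha = alpha_amp_uv * alpha_env * np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
    for ch in _ALPHA_CHANNELS:
        data[CHANNELS_8.index(ch)] += alpha

    # blinks: Poisson-ish with 1 s refractory
    blink_times = []
    if blink_rate_hz > 0:
        tt = rng.exponential(1.0 / blink_rate_hz)
        while tt < total_s - 1.0:
            blink_times.append(tt)
            tt += 1.0 + rng.exponential(1.0 / blink_rate_hz)
    tpl = _blink_template(fs)
    for bt in blink_times:
        i0 = int(round(bt * fs))
        i1 = min(n, i0 + len(tpl))
        seg = tpl[: i1 - i0]
        amp = blink_amp_uv * rng.uniform(0.8, 1.2)
        for ci, ch in enumerate(CHANNELS_8):
            data[ci, i0:i1] += amp * _BLINK_TOPO[ch] * seg
    # ground-truth blink PEAK times (template max at its center)
    blink_peaks = [bt + 0.5 * len(tpl) / fs for bt in blink_times]

    # error-trial theta bursts after the response
    theta_trials = []
    w0, w1 = theta_window_ms
    for r in rows:
        if r["response_key"] is None or np.isnan(r["resp_time_s"]):
            continue
        correct_key = cfg.key_map[r["stimulus_color"]]
        if r["response_key"] == correct_key:
            continue
        theta_trials.append(r["trial"])
        i0 = int(round((r["resp_time_s"] + w0 / 1000.0) * fs))
        i1 = min(n, int(round((r["resp_time_s"] + w1 / 1000.0) * fs)))
        if i1 <= i0:
            continue
        seg_t = np.arange(i1 - i0) / fs
        burst = np.sin(2 * np.pi * theta_freq_hz * seg_t + rng.uniform(0, 2 * np.pi))
        burst *= np.hanning(i1 - i0)
        for ci, ch in enumerate(CHANNELS_8):
            data[ci, i0:i1] += theta_amp_uv * _THETA_TOPO[ch] * burst

    # ---- markers --------------------------------------------------------
    marker_rows = []
    for r in rows:
        acc = "missed"
        if r["response_key"] is not None:
            acc = "correct" if r["response_key"] == cfg.key_map[r["stimulus_color"]] else "error"
        marker_rows.append({
            "label": "stimulus", "sample": int(round(r["stim_time_s"] * fs)),
            "trial": r["trial"], "congruency": r["congruency"], "accuracy": acc,
        })
        if r["response_key"] is not None:
            marker_rows.append({
                "label": "response", "sample": int(round(r["resp_time_s"] * fs)),
                "trial": r["trial"], "congruency": r["congruency"], "accuracy": acc,
            })
    markers = pd.DataFrame(marker_rows)

    rec = EEGRecording(channel_labels=CHANNELS_8, fs_hz=fs, data=data, markers=markers)
    truth = {
        "blink_times_s": np.asarray(blink_peaks),
        "theta_trials": theta_trials,
        "theta_amp_uv": theta_amp_uv,
        "theta_freq_hz": theta_freq_hz,
    }
    return rec, trial_table, truth
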