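"""EEG processing chain for the 8-channel Simon-task recordings.

The chain mirrors a cognitive-monitoring workflow built around a
low-channel-count wireless headset (Fz, C3, Cz, C4, Pz, PO7, Oz, PO8 at
250 Hz) with no dedicated ocular channels:

1. detrend + zero-phase Butterworth band-pass 0.1-30 Hz;
2. blink detection on the low-passed frontal channel;
3. blink-segment ICA — ICA fitted on +/-500 ms segments around blinks,
   the blink component identified by frontal correlation, and the unmixing
   weights transferred to the full continuous recording where the component
   is removed;
4. epoching -1000..1500 ms around stimulus and response markers;
5. two-stage artifact rejection (100 uV voltage threshold; 50 dB spectral
   threshold in 20-40 Hz);
6. channel hygiene: channels bad in >20% of epochs are rebuilt by
   spherical-spline interpolation, and a participant with >10% of channels
   interpolated is excluded;
7. single-trial complex-Morlet time-frequency (2-30 Hz, 20 linear steps,
   3-6 cycles log-spaced) with divisive dB baseline -400..-100 ms relative
   to stimulus onset.

Amplitudes are in microvolts throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.decomposition import FastICA

CHANNELS_8 = ("Fz", "C3", "Cz", "C4", "Pz", "PO7", "Oz", "PO8")


@dataclass
class EEGRecording:
    """Continuous multichannel recording with task event markers.

    ``data`` is channels x samples in microvolts. ``markers`` is a DataFrame
    with columns ``label`` ("stimulus" | "response"), ``sample`` and
    ``trial``.
    """

    channel_labels: tuple[str, ...]
    fs_hz: float
    data: np.ndarray
    markers: pd.DataFrame

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data must be channels x samples matching channel_labels")
        if len(self.markers) and self.markers["sample"].max() >= self.data.shape[1]:
            raise ValueError("marker index beyond data")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def ch_index(self, name: str) -> int:
        return self.channel_labels.index(name)


@dataclass(frozen=True)
class TaskConfig:
    """Simon-task timing: 200 ms stimulus, 500 ms response window from
    stimulus onset, jittered 800-1200 ms response-stimulus interval,
    160 trials per block."""

    stim_duration_ms: float = 200.0
    response_window_ms: float = 500.0
    rsi_ms: tuple[float, float] = (800.0, 1200.0)
    trials_per_block: int = 160
    #: color -> correct response key (counterbalanced across participants)
    key_map: dict = field(default_factory=lambda: {"red": "2", "green": "8"})

    def __post_init__(self):
        if self.response_window_ms < self.stim_duration_ms:
            raise ValueError("response window shorter than stimulus")
        if self.rsi_ms[0] <= 0 or self.rsi_ms[1] < self.rsi_ms[0]:
            raise ValueError("invalid RSI range")


@dataclass
class EpochSet:
    """Epoched data with per-epoch/channel rejection bookkeeping.

    ``data``: epochs x channels x time (uV); ``metadata``: one row per epoch
    (trial, lock, congruency, accuracy); ``flags``: epochs x channels bool
    (artifact detected); ``reasons``: epochs x channels, "" | "voltage" |
    "spectral"; ``epoch_rejected``: epoch-level verdict; channels in
    ``interpolated_channels`` were rebuilt by spherical splines.
    """

    data: np.ndarray
    times_ms: np.ndarray
    fs_hz: float
    channel_labels: tuple[str, ...]
    metadata: pd.DataFrame
    flags: np.ndarray
    reasons: np.ndarray
    epoch_rejected: np.ndarray
    interpolated_channels: list[str] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def kept(self) -> "EpochSet":
        m = ~self.epoch_rejected
        return replace(
            self,
            data=self.data[m],
            metadata=self.metadata.loc[m].reset_index(drop=True),
            flags=self.flags[m],
            reasons=self.reasons[m],
            epoch_rejected=self.epoch_rejected[m],
        )


@dataclass
class TFMap:
    """Single-trial time-frequency power.

    ``power``: epochs x channels x freqs x times; raw uV^2 from
    :func:`morlet_tf`, dB relative to the per-trial stimulus baseline after
    :func:`baseline_normalize`. ``times_valid`` flags samples farther than
    one wavelet half-length from the epoch edge.
    """

    freqs: np.ndarray
    cycles: np.ndarray
    times_ms: np.ndarray
    power: np.ndarray
    metadata: pd.DataFrame
    channel_labels: tuple[str, ...]
    times_valid: np.ndarray
    is_db: bool = False


# ----------------------------------------------------------------- filtering


def preprocess(rec: EEGRecording, band: tuple[float, float] = (0.1, 30.0)) -> EEGRecording:
    """Linear detrend then zero-phase (forward-backward) Butterworth band-pass."""
    data = signal.detrend(rec.data, axis=1, type="linear")
    sos = signal.butter(4, band, btype="bandpass", fs=rec.fs_hz, output="sos")
    data = signal.sosfiltfilt(sos, data, axis=1)
    return replace(rec, data=data)


def _lowpass_frontal(rec: EEGRecording, channel: str, cutoff_hz: float = 4.0) -> np.ndarray:
    sos = signal.butter(4, cutoff_hz, btype="lowpass", fs=rec.fs_hz, output="sos")
    return signal.sosfiltfilt(sos, rec.data[rec.ch_index(channel)])


def detect_blinks(
    rec: EEGRecording,
    channel: str = "Fz",
    mad_k: float = 4.0,
    min_separation_s: float = 0.5,
) -> np.ndarray:
    """Blink peak sample indices on the low-passed (<=4 Hz) frontal channel.

    The threshold is adaptive — median + ``mad_k`` * MAD of the low-passed
    trace — so detection is invariant to overall amplitude scaling.
    """
    low = _lowpass_frontal(rec, channel)
    med = np.median(low)
    mad = np.median(np.abs(low - med))
    if mad == 0:
        return np.array([], dtype=int)
    thresh = med + mad_k * mad * 1.4826  # MAD -> SD-equivalent scale
    peaks, _ = signal.find_peaks(
        low, height=thresh, distance=max(1, int(min_separation_s * rec.fs_hz))
    )
    return peaks


def blink_ica_clean(
    rec: EEGRecording,
    blink_indices: np.ndarray,
    segment_ms: float = 500.0,
    channel: str = "Fz",
    min_blinks: int = 5,
    random_state: int = 0,
) -> EEGRecording:
    """Remove the blink component via blink-segment ICA with weight transfer.

    ICA is fitted only on the concatenated +/-``segment_ms`` windows around
    detected blinks, where the blink source dominates and is reliably
    separable despite the low channel count.  The blink component is the one
    whose segment activation correlates most with the low-passed frontal
    channel.  The unmixing learned on the segments is applied to the FULL
    continuous recording, the blink component is zeroed, and the remaining
    components are remixed — channel count, length and rate are unchanged.
    """
    if len(blink_indices) < min_blinks:
        warnings.warn(
            f"only {len(blink_indices)} blinks (< {min_blinks}); skipping ICA clean",
            stacklevel=2,
        )
        return rec

    half = int(round(segment_ms / 1000.0 * rec.fs_hz))
    n = rec.n_samples
    seg_mask = np.zeros(n, dtype=bool)
    for b in blink_indices:
        seg_mask[max(0, b - half): min(n, b + half + 1)] = True
    segments = rec.data[:, seg_mask]  # channels x seg-samples

    n_comp = rec.data.shape[0]
    ica = FastICA(
        n_components=n_comp, whiten="unit-variance", random_state=random_state,
        max_iter=2000, tol=1e-3,
    )
    try:
        sources_seg = ica.fit_transform(segments.T)  # seg-samples x comps
    except Exception as exc:  # pragma: no cover - convergence diagnostics
        raise RuntimeError(f"blink ICA failed on {segments.shape[1]} segment samples: {exc}")

    frontal_low = _lowpass_frontal(rec, channel)[seg_mask]
    corrs = np.array([
        abs(np.corrcoef(sources_seg[:, k], frontal_low)[0, 1]) for k in range(n_comp)
    ])
    blink_comp = int(np.nanargmax(corrs))

    # weight transfer: unmix full data with segment-learned weights
    sources_full = ica.transform(rec.data.T)  # samples x comps
    mixing = ica.mixing_  # channels x comps
    blink_signal = np.outer(sources_full[:, blink_comp], mixing[:, blink_comp]).T
    return replace(rec, data=rec.data - blink_signal)


# ------------------------------------------------------------ trial handling


def classify_trials(trial_table: pd.DataFrame, cfg: TaskConfig) -> pd.DataFrame:
    """Label trials correct/error by the key mapping and apply the late rule.

    Input columns: ``stimulus_color``, ``response_key`` (NaN/None = no
    response), ``rt_ms``.  Responses after the response window are excluded
    as ``late``; absent responses as ``missed``.  Responses are still
    recorded during the RSI, which is why late trials exist at all.
    """
    out = trial_table.copy()
    correct_key = out["stimulus_color"].map(cfg.key_map)
    responded = out["response_key"].notna()
    late = responded & (out["rt_ms"] > cfg.response_window_ms)
    out["accuracy"] = np.where(
        out["response_key"].astype(object).eq(correct_key), "correct", "error"
    )
    out.loc[~responded, "accuracy"] = "missed"
    out["included"] = responded & ~late
    out["exclusion_reason"] = ""
    out.loc[late, "exclusion_reason"] = "late"
    out.loc[~responded, "exclusion_reason"] = "missed"
    return out


# ------------------------------------------------------- epochs & rejection


def _band_power_db(
    epoch_ch: np.ndarray, fs: float, band: tuple[float, float]
) -> float:
    """Mean Welch PSD in the band, in dB re 1 uV^2/Hz."""
    nper = min(len(epoch_ch), int(fs))
    f, pxx = signal.welch(epoch_ch, fs=fs, nperseg=nper)
    m = (f >= band[0]) & (f <= band[1])
    mean_psd = float(np.mean(pxx[m])) if m.any() else 0.0
    return 10.0 * np.log10(max(mean_psd, 1e-300))


def epoch_and_reject(
    rec: EEGRecording,
    markers: pd.DataFrame | None = None,
    window_ms: tuple[float, float] = (-1000.0, 1500.0),
    volt_thresh_uv: float = 100.0,
    spec_thresh_db: float = 50.0,
    spec_band: tuple[float, float] = (20.0, 40.0),
) -> EpochSet:
    """Cut epochs around markers and apply the two-stage artifact rejection.

    An epoch x channel cell is flagged if |amplitude| exceeds
    ``volt_thresh_uv`` anywhere in the epoch, or (checked second) if its
    Welch band power in ``spec_band`` exceeds ``spec_thresh_db`` dB re
    1 uV^2/Hz.  An epoch is rejected when any channel is flagged.  Markers
    too close to the recording edge for a full window are dropped.
    """
    if markers is None:
        markers = rec.markers
    fs = rec.fs_hz
    i0 = int(round(window_ms[0] / 1000.0 * fs))
    i1 = int(round(window_ms[1] / 1000.0 * fs))
    n_t = i1 - i0
    times_ms = (np.arange(i0, i1) / fs) * 1000.0

    rows, cut = [], []
    for _, mk in markers.iterrows():
        s = int(mk["sample"])
        if s + i0 < 0 or s + i1 > rec.n_samples:
            continue
        cut.append(rec.data[:, s + i0: s + i1])
        rows.append({
            "trial": mk.get("trial", -1),
            "lock": mk["label"],
            "congruency": mk.get("congruency", ""),
            "accuracy": mk.get("accuracy", ""),
        })
    n_ep = len(cut)
    data = np.stack(cut) if n_ep else np.empty((0, len(rec.channel_labels), n_t))
    meta = pd.DataFrame(rows, columns=["trial", "lock", "congruency", "accuracy"])

    n_ch = len(rec.channel_labels)
    flags = np.zeros((n_ep, n_ch), dtype=bool)
    reasons = np.full((n_ep, n_ch), "", dtype=object)
    for e in range(n_ep):
        for c in range(n_ch):
            if np.max(np.abs(data[e, c])) > volt_thresh_uv:
                flags[e, c] = True
                reasons[e, c] = "voltage"
            elif _band_power_db(data[e, c], fs, spec_band) > spec_thresh_db:
                flags[e, c] = True
                reasons[e, c] = "spectral"
    return EpochSet(
        data=data,
        times_ms=times_ms,
        fs_hz=fs,
        channel_labels=tuple(rec.channel_labels),
        metadata=meta,
        flags=flags,
        reasons=reasons,
        epoch_rejected=flags.any(axis=1),
    )


def _spline_interpolate(
    data: np.ndarray, channel_labels: tuple[str, ...], bad: list[str]
) -> np.ndarray:
    """Rebuild bad channels by spherical-spline interpolation (order-4
    splines on standard 10-20 electrode positions)."""
    import mne

    info = mne.create_info(list(channel_labels), sfreq=1000.0, ch_types="eeg")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        info.set_montage(mne.channels.make_standard_montage("standard_1005"))
    epoched = data.ndim == 3
    # channels x total-samples; mne expects volts, but the spline operator is
    # linear in amplitude so only the relative scale matters
    flat = np.concatenate(list(data), axis=1) if epoched else data
    raw = mne.io.RawArray(flat * 1e-6, info, verbose="error")
    raw.info["bads"] = list(bad)
    raw.interpolate_bads(reset_bads=True, mode="accurate", verbose="error")
    fixed = raw.get_data() * 1e6
    if epoched:
        return np.stack(np.split(fixed, data.shape[0], axis=1))
    return fixed


def channel_hygiene(
    epochset: EpochSet,
    chan_epoch_limit: float = 0.20,
    participant_limit: float = 0.10,
) -> tuple[EpochSet, dict]:
    """Exclude & interpolate bad channels; render the participant verdict.

    A channel flagged in more than ``chan_epoch_limit`` of epochs is
    excluded and reconstructed from the remaining channels by
    spherical-spline interpolation; its flags are cleared and epoch verdicts
    recomputed.  The participant is excluded when the interpolated fraction
    exceeds ``participant_limit`` — applied literally, so with 8 channels a
    single interpolation (12.5%) already exceeds 10%.
    """
    n_ep = max(epochset.n_epochs, 1)
    frac = epochset.flags.mean(axis=0) if epochset.n_epochs else np.zeros(len(epochset.channel_labels))
    bad = [
        ch for ch, f in zip(epochset.channel_labels, frac) if f > chan_epoch_limit
    ]
    out = epochset
    if bad and epochset.n_epochs:
        fixed = _spline_interpolate(epochset.data, epochset.channel_labels, bad)
        flags = epochset.flags.copy()
        reasons = epochset.reasons.copy()
        for ch in bad:
            c = epochset.channel_labels.index(ch)
            flags[:, c] = False
            reasons[:, c] = ""
        out = replace(
            epochset,
            data=fixed,
            flags=flags,
            reasons=reasons,
            epoch_rejected=flags.any(axis=1),
            interpolated_channels=list(bad),
        )
    frac_interp = len(bad) / len(epochset.channel_labels)
    verdict = {
        "interpolated_channels": list(bad),
        "fraction_interpolated": frac_interp,
        "participant_excluded": frac_interp > participant_limit,
    }
    return out, verdict


# --------------------------------------------------------- time-frequency


def morlet_freq_grid(
    f_lo: float = 2.0, f_hi: float = 30.0, n_freqs: int = 20,
    c_lo: float = 3.0, c_hi: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """20 linearly spaced frequencies 2-30 Hz with cycle counts increasing
    3 -> 6 in matching logarithmically spaced steps."""
    freqs = np.linspace(f_lo, f_hi, n_freqs)
    cycles = np.logspace(np.log10(c_lo), np.log10(c_hi), n_freqs)
    return freqs, cycles


def _morlet_wavelet(f: float, n_cycles: float, fs: float) -> np.ndarray:
    """Complex Morlet, unit-energy, support +/-3 temporal SDs."""
    sd_t = n_cycles / (2.0 * np.pi * f)
    half = int(np.ceil(3.0 * sd_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * f * t) * np.exp(-(t ** 2) / (2 * sd_t ** 2))
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


def morlet_tf(
    epochset: EpochSet,
    freqs: np.ndarray | None = None,
    cycles: np.ndarray | None = None,
    decim: int = 5,
    channels: list[str] | None = None,
) -> TFMap:
    """Single-trial complex-Morlet convolution power.

    Power is the squared magnitude of the convolution of each epoch/channel
    with a unit-energy complex Morlet wavelet at each frequency.  ``decim``
    down-samples the time axis of the output (power varies slowly relative
    to the 250 Hz raw rate).  Samples within one wavelet half-length of the
    epoch edge are flagged unreliable in ``times_valid``.
    """
    if freqs is None or cycles is None:
        freqs, cycles = morlet_freq_grid()
    ch_idx = (
        [epochset.channel_labels.index(c) for c in channels]
        if channels is not None
        else list(range(len(epochset.channel_labels)))
    )
    data = epochset.data[:, ch_idx, :]
    n_ep, n_ch, n_t = data.shape
    t_keep = np.arange(0, n_t, decim)
    power = np.empty((n_ep, n_ch, len(freqs), len(t_keep)), dtype=np.float32)
    times_valid = np.ones((len(freqs), len(t_keep)), dtype=bool)
    flat = data.reshape(n_ep * n_ch, n_t)
    for fi, (f, nc) in enumerate(zip(freqs, cycles)):
        w = _morlet_wavelet(f, nc, epochset.fs_hz)
        conv = signal.fftconvolve(flat, w[np.newaxis, :], mode="same", axes=1)
        p = np.abs(conv) ** 2
        power[:, :, fi, :] = p.reshape(n_ep, n_ch, n_t)[:, :, t_keep].astype(np.float32)
        half = (len(w) - 1) // 2
        edge = t_keep < half
        edge |= t_keep >= n_t - half
        times_valid[fi, edge] = False
    return TFMap(
        freqs=freqs,
        cycles=cycles,
        times_ms=epochset.times_ms[t_keep],
        power=power,
        metadata=epochset.metadata.reset_index(drop=True),
        channel_labels=tuple(epochset.channel_labels[i] for i in ch_idx),
        times_valid=times_valid,
    )


def baseline_normalize(
    tf: TFMap,
    baseline_ms: tuple[float, float] = (-400.0, -100.0),
) -> TFMap:
    """Divisive dB baseline: 10*log10(power / trial's stimulus baseline).

    Every epoch (stimulus- or response-locked) of trial N is divided, per
    channel and frequency, by the mean power of trial N's STIMULUS-locked
    epoch within ``baseline_ms`` before stimulus onset, then log-scaled.
    Trials without a stimulus-locked epoch in the map are dropped.
    """
    if tf.is_db:
        raise ValueError("TFMap already baseline-normalized")
    meta = tf.metadata
    bl_mask = (tf.times_ms >= baseline_ms[0]) & (tf.times_ms <= baseline_ms[1])
    if not bl_mask.any():
        raise ValueError("baseline window outside epoch time axis")
    stim_rows = meta.index[meta["lock"] == "stimulus"]
    baseline_by_trial = {
        int(meta.loc[i, "trial"]): tf.power[i][:, :, bl_mask].mean(axis=2)
        for i in stim_rows
    }
    keep, db = [], []
    for i in range(len(meta)):
        trial = int(meta.loc[i, "trial"])
        bl = baseline_by_trial.get(trial)
        if bl is None:
            continue
        keep.append(i)
        db.append(10.0 * np.log10(tf.power[i] / bl[:, :, np.newaxis]))
    return replace(
        tf,
        power=np.stack(db).astype(np.float32) if keep else tf.power[:0],
        metadata=meta.loc[keep].reset_index(drop=True),
        is_db=True,
    )


def condition_average(tf: TFMap, lock: str, accuracy: str) -> np.ndarray:
    """Mean power over epochs of one condition: channels x freqs x times."""
    m = (tf.metadata["lock"] == lock) & (tf.metadata["accuracy"] == accuracy)
    return tf.power[m.to_numpy()].mean(axis=0)


def roi_power(
    tf_cond: np.ndarray,
    tf: TFMap,
    channel: str,
    f_band: tuple[float, float],
    t_window_ms: tuple[float, float],
) -> float:
    """Mean condition power in a channel x frequency-band x time-window ROI."""
    c = tf.channel_labels.index(channel)
    fm = (tf.freqs >= f_band[0]) & (tf.freqs <= f_band[1])
    tm = (tf.times_ms >= t_window_ms[0]) & (tf.times_ms <= t_window_ms[1])
    return float(tf_cond[c][np.ix_(fm, tm)].mean())
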