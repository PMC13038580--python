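import numpy as np
import pandas as pd
import pytest
from scipy import signal as sg

from physiofuse.eeg import (
    CHANNELS_8,
    EEGRecording,
    EpochSet,
    TaskConfig,
    baseline_normalize,
    blink_ica_clean,
    channel_hygiene,
    classify_trials,
    condition_average,
    detect_blinks,
    epoch_and_reject,
    morlet_freq_grid,
    morlet_tf,
    preprocess,
    roi_power,
)
from physiofuse.synth import synth_eeg_simon

FS = 250.0


def make_recording(data, markers=None):
    if markers is None:
        markers = pd.DataFrame(columns=["label", "sample", "trial"])
    return EEGRecording(CHANNELS_8, FS, data, markers)


@pytest.fixture(scope="module")
def simon_session():
    return synth_eeg_simon(TaskConfig(), n_blocks=1, seed=3)


@pytest.fixture(scope="module")
def cleaned_session(simon_session):
    rec, trials, truth = simon_session
    rec_f = preprocess(rec)
    blinks = detect_blinks(rec_f)
    rec_c = blink_ica_clean(rec_f, blinks, random_state=0)
    return rec_f, rec_c, blinks, truth


class TestPreprocess:
    def _sine(self, f, n=30000):
        t = np.arange(n) / FS
        return make_recording(np.tile(np.sin(2 * np.pi * f * t), (8, 1)))

    def test_50hz_attenuated(self):
        # interior only: the 0.1 Hz high-pass edge transient decays over ~10 s
        out = preprocess(self._sine(50.0))
        ratio = out.data[0][5000:-5000].std() / self._sine(50.0).data[0][5000:-5000].std()
        assert ratio < 0.10

    def test_10hz_preserved(self):
        out = preprocess(self._sine(10.0))
        ratio = out.data[0][5000:-5000].std() / self._sine(10.0).data[0][5000:-5000].std()
        assert abs(ratio - 1.0) < 0.05

    def test_dc_removed(self):
        rec = make_recording(np.full((8, 5000), 42.0))
        out = preprocess(rec)
        assert abs(out.data.mean()) < 0.1


class TestBlinkDetection:
    def test_injected_blinks_found_within_40ms(self, cleaned_session):
        rec_f, _, blinks, truth = cleaned_session
        det_t = blinks / FS
        true_t = truth["blink_times_s"]
        matched = sum(np.min(np.abs(det_t - bt)) <= 0.040 for bt in true_t)
        assert matched >= 0.9 * len(true_t)
        assert len(det_t) <= len(true_t) + 2

    def test_blink_free_recording_zero_detections(self):
        rec, _, _ = synth_eeg_simon(TaskConfig(), blink_rate_hz=0.0, seed=4)
        assert len(detect_blinks(preprocess(rec))) == 0

    def test_amplitude_scaling_robust(self, simon_session):
        rec, _, _ = simon_session
        rec_f = preprocess(rec)
        doubled = make_recording(rec_f.data * 2, rec.markers)
        assert np.array_equal(detect_blinks(rec_f), detect_blinks(doubled))


class TestBlinkICA:
    def test_blink_band_power_reduced_80pct(self, cleaned_session):
        rec_f, rec_c, _, truth = cleaned_session
        sos = sg.butter(4, (0.5, 4.0), btype="bandpass", fs=FS, output="sos")

        def blink_power(r):
            f = sg.sosfiltfilt(sos, r.data[0])
            return sum(
                np.mean(f[max(0, int(bt * FS) - 125): int(bt * FS) + 125] ** 2)
                for bt in truth["blink_times_s"]
            )

        assert blink_power(rec_c) <= 0.2 * blink_power(rec_f)

    def test_posterior_alpha_preserved_within_10pct(self, cleaned_session):
        rec_f, rec_c, _, _ = cleaned_session
        oz = CHANNELS_8.index("Oz")

        def alpha(r):
            f, p = sg.welch(r.data[oz], fs=FS, nperseg=1024)
            return p[(f >= 9) & (f <= 11)].mean()

        assert alpha(rec_c) == pytest.approx(alpha(rec_f), rel=0.10)

    def test_shape_and_rate_preserved(self, cleaned_session):
        rec_f, rec_c, _, _ = cleaned_session
        assert rec_c.data.shape == rec_f.data.shape
        assert rec_c.fs_hz == rec_f.fs_hz
        assert rec_c.channel_labels == rec_f.channel_labels

    def test_too_few_blinks_returns_unchanged(self, simon_session):
        rec, _, _ = simon_session
        rec_f = preprocess(rec)
        with pytest.warns(UserWarning, match="skipping"):
            out = blink_ica_clean(rec_f, np.array([100, 600]))
        assert out.data is rec_f.data


class TestClassifyTrials:
    def _table(self, rt_ms, key="2", color="red"):
        return pd.DataFrame([{
            "trial": 0, "stimulus_color": color, "response_key": key, "rt_ms": rt_ms,
        }])

    def test_rt_499_included_correct(self):
        out = classify_trials(self._table(499.0), TaskConfig())
        assert bool(out.loc[0, "included"]) and out.loc[0, "accuracy"] == "correct"

    def test_rt_501_excluded_late(self):
        out = classify_trials(self._table(501.0), TaskConfig())
        assert not bool(out.loc[0, "included"])
        assert out.loc[0, "exclusion_reason"] == "late"

    def test_wrong_key_is_error(self):
        out = classify_trials(self._table(300.0, key="8"), TaskConfig())
        assert out.loc[0, "accuracy"] == "error"

    def test_no_response_missed(self):
        out = classify_trials(self._table(np.nan, key=None), TaskConfig())
        assert out.loc[0, "exclusion_reason"] == "missed"

    def test_generator_error_rate_recovered(self, simon_session):
        _, trials, truth = simon_session
        out = classify_trials(trials, TaskConfig())
        n_err = (out["accuracy"] == "error").sum()
        assert n_err == len(truth["theta_trials"])
        assert 8 <= n_err <= 28  # ~16 expected at error_rate 0.1


class TestEpochRejection:
    def _quiet_rec(self, n_markers=4, noise=1.0, seed=0):
        rng = np.random.default_rng(seed)
        n = 12000
        data = rng.normal(0, noise, (8, n))
        samples = np.linspace(1000, n - 2000, n_markers).astype(int)
        markers = pd.DataFrame({
            "label": "stimulus", "sample": samples, "trial": np.arange(n_markers),
        })
        return make_recording(data, markers), samples

    def test_quiet_epochs_not_rejected(self):
        rec, _ = self._quiet_rec()
        es = epoch_and_reject(rec)
        assert es.n_epochs == 4
        assert es.epoch_rejected.sum() == 0
        assert es.data.shape[2] == int(2.5 * FS)

    def test_voltage_spike_rejected(self):
        rec, samples = self._quiet_rec()
        rec.data[3, samples[1] + 50] = 150.0  # 150 uV spike inside epoch 1
        es = epoch_and_reject(rec)
        assert bool(es.epoch_rejected[1])
        assert es.reasons[1, 3] == "voltage"
        assert es.epoch_rejected.sum() == 1

    def test_spectral_burst_rejected(self):
        rec, samples = self._quiet_rec(noise=0.5)
        t = np.arange(rec.n_samples) / FS
        s0 = samples[2]
        burst = 80.0 * np.sin(2 * np.pi * 30.0 * t[s0 - 250: s0 + 375])
        rec.data[5, s0 - 250: s0 + 375] += burst  # ~22 dB band PSD, < 100 uV
        es = epoch_and_reject(rec, spec_thresh_db=20.0)
        assert bool(es.epoch_rejected[2])
        assert es.reasons[2, 5] == "spectral"

    def test_default_60db_burst_rejected(self):
        # a 30 Hz burst whose 20-40 Hz Welch PSD reaches ~60 dB re 1 uV^2/Hz
        rec, samples = self._quiet_rec()
        t = np.arange(rec.n_samples) / FS
        s0 = samples[0]
        rec.data[0, s0 - 250: s0 + 375] += 7000.0 * np.sin(
            2 * np.pi * 30.0 * t[s0 - 250: s0 + 375])
        es = epoch_and_reject(rec)
        assert bool(es.epoch_rejected[0])

    def test_rejection_deterministic(self):
        rec, samples = self._quiet_rec(seed=5)
        rec.data[2, samples[0]] = 200.0
        a = epoch_and_reject(rec)
        b = epoch_and_reject(rec)
        assert np.array_equal(a.flags, b.flags)
        assert np.array_equal(a.epoch_rejected, b.epoch_rejected)


class TestChannelHygiene:
    def _epochset_with_bad_channel(self, frac_bad, n_ep=50, seed=0):
        rng = np.random.default_rng(seed)
        n = 40000
        data = rng.normal(0, 2.0, (8, n))
        samples = np.linspace(1000, n - 2000, n_ep).astype(int)
        n_bad = int(round(frac_bad * n_ep))
        for s in samples[:n_bad]:
            data[1, s] = 500.0  # C3 spikes in the first n_bad epochs
        markers = pd.DataFrame({"label": "stimulus", "sample": samples,
                                "trial": np.arange(n_ep)})
        return epoch_and_reject(make_recording(data, markers))

    def test_channel_over_20pct_interpolated_participant_excluded(self):
        es = self._epochset_with_bad_channel(0.24)
        out, verdict = channel_hygiene(es)
        assert verdict["interpolated_channels"] == ["C3"]
        # literal rule: 1 of 8 channels = 12.5% > 10% -> excluded
        assert verdict["participant_excluded"] is True
        # the spike is gone from the reconstructed channel
        assert np.abs(out.data[:, 1, :]).max() < 100.0
        assert out.epoch_rejected.sum() == 0

    def test_channel_below_threshold_untouched(self):
        es = self._epochset_with_bad_channel(0.10)
        out, verdict = channel_hygiene(es)
        assert verdict["interpolated_channels"] == []
        assert verdict["participant_excluded"] is False
        assert out.data is es.data


class TestMorletTF:
    def _epochs(self, trace, n_ep=1, lock="stimulus", accuracy="correct"):
        n_t = len(trace)
        data = np.tile(trace, (n_ep, 8, 1))
        times = (np.arange(n_t) - n_t // 2) / FS * 1000
        meta = pd.DataFrame({"trial": np.arange(n_ep), "lock": lock,
                             "congruency": "congruent", "accuracy": accuracy})
        return EpochSet(data, times, FS, CHANNELS_8, meta,
                        np.zeros((n_ep, 8), bool),
                        np.full((n_ep, 8), "", object),
                        np.zeros(n_ep, bool))

    def test_pure_tone_peaks_at_nearest_bin(self):
        freqs, _ = morlet_freq_grid()
        t = np.arange(625) / FS
        # 20 Hz sits uniquely nearest one grid bin
        tf = morlet_tf(self._epochs(np.sin(2 * np.pi * 20.0 * t)), decim=1)
        mid = tf.power.shape[-1] // 2
        assert int(tf.power[0, 0, :, mid].argmax()) == int(np.argmin(np.abs(freqs - 20.0)))
        # 16 Hz is equidistant between two bins: either neighbor is nearest
        tf16 = morlet_tf(self._epochs(np.sin(2 * np.pi * 16.0 * t)), decim=1)
        two_nearest = set(np.argsort(np.abs(freqs - 16.0))[:2].tolist())
        assert int(tf16.power[0, 0, :, mid].argmax()) in two_nearest

    def test_amplitude_doubling_quadruples_power(self):
        t = np.arange(625) / FS
        tf1 = morlet_tf(self._epochs(np.sin(2 * np.pi * 10 * t)), decim=1)
        tf2 = morlet_tf(self._epochs(2 * np.sin(2 * np.pi * 10 * t)), decim=1)
        mid = tf1.power.shape[-1] // 2
        fbin = int(tf1.power[0, 0, :, mid].argmax())
        assert tf2.power[0, 0, fbin, mid] == pytest.approx(
            4 * tf1.power[0, 0, fbin, mid], rel=1e-4)

    def test_white_noise_flat_in_time(self):
        rng = np.random.default_rng(0)
        es = self._epochs(rng.normal(0, 1, 1625), n_ep=1)
        es.data = rng.normal(0, 1, (40, 8, 1625))
        es.metadata = pd.DataFrame({"trial": np.arange(40), "lock": "stimulus",
                                    "congruency": "c", "accuracy": "correct"})
        es.flags = np.zeros((40, 8), bool)
        es.reasons = np.full((40, 8), "", object)
        es.epoch_rejected = np.zeros(40, bool)
        tf = morlet_tf(es, decim=5, channels=["Cz"])
        valid = tf.times_valid[5]
        tp = tf.power[:, 0, 5, :].mean(axis=0)[valid]
        assert tp.std() / tp.mean() < 0.25

    def test_agrees_with_mne_reference(self):
        """Cross-check the wavelet transform against mne's Morlet TFR."""
        import mne

        rng = np.random.default_rng(1)
        data = rng.normal(0, 1, (3, 2, 800))
        freqs, cycles = morlet_freq_grid()
        ours = morlet_tf(
            EpochSet(data, np.arange(800) / FS * 1000, FS, ("Fz", "Cz"),
                     pd.DataFrame({"trial": range(3), "lock": "stimulus",
                                   "congruency": "c", "accuracy": "correct"}),
                     np.zeros((3, 2), bool), np.full((3, 2), "", object),
                     np.zeros(3, bool)),
            decim=1,
        )
        ref = mne.time_frequency.tfr_array_morlet(
            data, sfreq=FS, freqs=freqs, n_cycles=cycles, output="power",
            zero_mean=False, verbose="error",
        )
        # compare shapes and (normalization-independent) time courses away
        # from the epoch edges
        assert ours.power.shape == ref.shape
        for fi in (5, 10, 15):
            a = ours.power[0, 0, fi, 100:-100]
            b = ref[0, 0, fi, 100:-100]
            assert np.corrcoef(a, b)[0, 1] > 0.99


class TestBaselineNormalize:
    def _paired_epochs(self, resp_trace, stim_trace, accuracy="correct"):
        n_t = len(stim_trace)
        times = np.linspace(-1000, 1500, n_t)
        data = np.stack([np.tile(stim_trace, (8, 1)), np.tile(resp_trace, (8, 1))])
        meta = pd.DataFrame({"trial": [0, 0], "lock": ["stimulus", "response"],
                             "congruency": "c", "accuracy": accuracy})
        return EpochSet(data, times, FS, CHANNELS_8, meta,
                        np.zeros((2, 8), bool), np.full((2, 8), "", object),
                        np.zeros(2, bool))

    def test_baseline_window_maps_to_zero_db(self):
        t = np.linspace(-1.0, 1.5, 625)
        trace = np.sin(2 * np.pi * 6.0 * t)
        es = self._paired_epochs(trace, trace)
        tf = baseline_normalize(morlet_tf(es, decim=1))
        bl = (tf.times_ms >= -400) & (tf.times_ms <= -100)
        fbin = 3  # ~6.4 Hz
        stim_db = tf.power[0, 0, fbin, bl]
        assert np.abs(stim_db.mean()) < 0.2

    def test_power_doubling_is_3db(self):
        t = np.linspace(-1.0, 1.5, 625)
        stim = np.sin(2 * np.pi * 6.0 * t)
        resp = stim + np.cos(2 * np.pi * 6.0 * t)  # doubles 6 Hz power
        es = self._paired_epochs(resp, stim, accuracy="error")
        tf = baseline_normalize(morlet_tf(es, decim=1))
        fbin = 3
        mid = (tf.times_ms >= 0) & (tf.times_ms <= 400)
        resp_db = tf.power[1, 0, fbin, mid].mean()
        assert resp_db == pytest.approx(10 * np.log10(2), abs=0.35)

    def test_double_normalization_rejected(self):
        t = np.linspace(-1.0, 1.5, 625)
        es = self._paired_epochs(np.sin(2 * np.pi * 6 * t), np.sin(2 * np.pi * 6 * t))
        tf = baseline_normalize(morlet_tf(es, decim=1))
        with pytest.raises(ValueError):
            baseline_normalize(tf)


def test_full_chain_theta_contrast_positive(cleaned_session, simon_session):
    """Error trials carry more post-response frontal-midline theta than
    correct trials after the full pipeline."""
    rec, trials, truth = simon_session
    _, rec_c, _, _ = cleaned_session
    es = epoch_and_reject(rec_c, rec.markers)
    tf = baseline_normalize(morlet_tf(es.kept(), decim=5, channels=["Fz", "Cz"]))
    err = roi_power(condition_average(tf, "response", "error"),
                    tf, "Cz", (4, 7), (0, 400))
    cor = roi_power(condition_average(tf, "response", "correct"),
                    tf, "Cz", (4, 7), (0, 400))
    assert err - cor > 1.0
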