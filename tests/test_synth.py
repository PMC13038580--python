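import numpy as np
import pytest

import physiofuse as pf
from physiofuse.eeg import TaskConfig
from physiofuse.synth import (
    DeviceErrorModel,
    OcclusionKinetics,
    generate_session,
    occlusion_sto2_trajectory,
    simulate_hr_trajectory,
    split_streamed_cached,
    synth_device_hr,
    synth_ecg,
    synth_eeg_simon,
    synth_sto2_occlusion,
)
from physiofuse.synth.ecg import beat_times_from_trajectory


class TestHRTrajectory:
    def test_rest_only_constant(self, exercise_timeline):
        traj = simulate_hr_trajectory(exercise_timeline, 60, 190)
        t = np.linspace(0, 119, 50)
        assert np.allclose(traj(t), 60.0)

    def test_tau_zero_jumps_to_target(self, exercise_timeline):
        traj = simulate_hr_trajectory(exercise_timeline, 60, 190, tau_s=0.0)
        # mild phase targets the 50-60% HRmax midpoint: 0.55 * 190 = 104.5
        assert traj(150.0) == pytest.approx(104.5)

    def test_asymptote_is_zone_midpoint(self, exercise_timeline):
        # moderate phase with hr_max 200: midpoint 65% -> 130 bpm at t >> tau
        traj = simulate_hr_trajectory(exercise_timeline, 60, 200, tau_s=5.0)
        assert traj(359.0) == pytest.approx(130.0, abs=0.5)

    def test_continuous_at_boundaries(self, exercise_timeline):
        traj = simulate_hr_trajectory(exercise_timeline, 60, 190, tau_s=30.0)
        for ev in exercise_timeline.events[1:]:
            tb = ev.start_ns / 1e9
            assert traj(tb - 1e-6) == pytest.approx(traj(tb + 1e-6), abs=0.01)

    def test_bounds_clipped(self, exercise_timeline):
        traj = simulate_hr_trajectory(exercise_timeline, 60, 190)
        t = np.linspace(0, 720, 2000)
        assert np.all((traj(t) >= 30.0) & (traj(t) <= 220.0))

    def test_rest_above_max_rejected(self, exercise_timeline):
        with pytest.raises(ValueError):
            simulate_hr_trajectory(exercise_timeline, 200, 190)


class TestBeatPlacement:
    def test_constant_rate_beat_count(self):
        traj = lambda t: np.full_like(np.asarray(t, dtype=float), 60.0)
        beats = beat_times_from_trajectory(traj, 0.0, 60.0)
        assert abs(len(beats) - 60) <= 1
        assert np.allclose(np.diff(beats), 1.0, atol=1e-3)

    def test_rate_recoverable_from_ibis(self, exercise_hr):
        """Time-warped placement makes HR(t) exactly recoverable from IBIs."""
        beats = beat_times_from_trajectory(exercise_hr, 0.0, 720.0)
        ibi = np.diff(beats)
        hr_from_ibi = 60.0 / ibi
        hr_true = exercise_hr((beats[1:] + beats[:-1]) / 2)
        assert np.median(np.abs(hr_from_ibi - hr_true)) < 0.5


class TestSynthECG:
    def test_noiseless_r_amplitudes_equal_template(self, exercise_hr):
        stream, beats = synth_ecg(exercise_hr, 0, 60, noise_sd=0.0, seed=0)
        beats = beats[beats < 59.5]  # final complex may be truncated at the edge
        idx = np.searchsorted(stream.times_s, beats)
        amps = np.array([stream.values[max(0, i - 2): i + 3].max() for i in idx])
        # sampled at 200 Hz the discrete maximum sits within half a sample of
        # the true peak; all amplitudes match the unit template to ~5%
        assert np.all(np.abs(amps - 1.0) < 0.06)

    def test_motion_segment_raises_variance(self, exercise_hr):
        stream, _ = synth_ecg(
            exercise_hr, 0, 240, noise_sd=0.02,
            motion_segments=[(120.0, 240.0, 5.0)], seed=4,
        )
        t = stream.times_s
        v_rest = stream.values[t < 120].var()
        v_move = stream.values[t >= 120].var()
        assert v_move > v_rest

    def test_fs_below_nyquist_rejected(self, exercise_hr):
        # exercise HR tops out near 142 bpm (~2.4 Hz): fs must exceed 4.8 Hz
        with pytest.raises(ValueError):
            synth_ecg(exercise_hr, 0, 720, fs=3.0)

    def test_same_seed_bit_identical(self, exercise_hr):
        a, _ = synth_ecg(exercise_hr, 0, 30, seed=7)
        b, _ = synth_ecg(exercise_hr, 0, 30, seed=7)
        assert np.array_equal(a.values, b.values)
        c, _ = synth_ecg(exercise_hr, 0, 30, seed=8)
        assert not np.array_equal(a.values, c.values)


class TestDeviceModel:
    def test_identity_model_samples_trajectory(self, exercise_hr):
        m = DeviceErrorModel(reporting_rate_hz=1.0)
        s = synth_device_hr(exercise_hr, 0, 600, m, seed=0)
        assert np.allclose(s.values, exercise_hr(s.times_s))

    def test_bias_recovered_in_mean(self, exercise_hr):
        m = DeviceErrorModel(reporting_rate_hz=1.0, bias=5.0, jitter_sd=1.0)
        s = synth_device_hr(exercise_hr, 0, 600, m, seed=1)
        diffs = s.values - exercise_hr(s.times_s)
        assert diffs.mean() == pytest.approx(5.0, abs=0.2)

    def test_full_dropout_empty_stream(self, exercise_hr):
        m = DeviceErrorModel(reporting_rate_hz=1.0, dropout_prob=1.0)
        s = synth_device_hr(exercise_hr, 0, 60, m, seed=0)
        assert len(s) == 0

    def test_invalid_dropout_rejected(self):
        with pytest.raises(ValueError):
            DeviceErrorModel(dropout_prob=1.5)


class TestStreamedCachedSplit:
    def test_no_dropout_zero_offset_identity(self, clean_exercise_ecg):
        stream, _ = clean_exercise_ecg
        streamed, cached = split_streamed_cached(stream, [], 0.0)
        assert np.array_equal(streamed.timestamps, stream.timestamps)
        assert np.array_equal(cached.timestamps, stream.timestamps)

    def test_offset_exact_on_shared_samples(self, clean_exercise_ecg):
        stream, _ = clean_exercise_ecg
        streamed, cached = split_streamed_cached(stream, [], 2.5)
        assert np.all(cached.timestamps - streamed.timestamps == 2_500_000_000)

    def test_gap_removes_exact_sample_count(self, exercise_hr):
        m = DeviceErrorModel(reporting_rate_hz=1.0)
        s = synth_device_hr(exercise_hr, 0, 600, m, seed=0)
        streamed, cached = split_streamed_cached(s, [(100.0, 130.0)], 0.0)
        assert len(streamed) == len(s) - 30
        assert len(cached) == len(s)


class TestSto2:
    def test_zero_desat_rate_flat(self, occlusion_timeline):
        k = OcclusionKinetics(desat_rate_pct_per_min_per_mmhg=0.0,
                              reperfusion_overshoot_pct=0.0)
        s, _ = synth_sto2_occlusion(occlusion_timeline, k, noise_sd=0.0, seed=0)
        assert np.allclose(s.values, 65.0)

    def test_desat_slope_scales_with_pressure(self, occlusion_timeline):
        traj = occlusion_sto2_trajectory(occlusion_timeline)
        slope_100 = traj(235.0) - traj(185.0)
        slope_200 = traj(355.0) - traj(305.0)
        assert slope_200 < slope_100 < 0

    def test_recovery_returns_to_baseline(self, occlusion_timeline):
        traj = occlusion_sto2_trajectory(occlusion_timeline, recovery_tau_s=30.0)
        assert traj(659.0) == pytest.approx(65.0, abs=0.65)  # within 1% after 5 min

    def test_values_bounded(self, occlusion_timeline):
        k = OcclusionKinetics(desat_rate_pct_per_min_per_mmhg=1.0)  # extreme
        s, _ = synth_sto2_occlusion(occlusion_timeline, k, rate_hz=2.0, seed=0)
        assert np.all((s.values >= 0) & (s.values <= 100))


class TestSimonEEG:
    def test_one_block_160_trials(self):
        _, trials, _ = synth_eeg_simon(TaskConfig(), n_blocks=1, seed=0)
        assert len(trials) == 160

    def test_error_rate_zero_no_theta(self):
        _, _, truth = synth_eeg_simon(TaskConfig(), error_rate=0.0, miss_rate=0.0, seed=1)
        assert truth["theta_trials"] == []

    def test_blink_free_kurtosis_near_background(self):
        from scipy import stats

        rec_b, _, _ = synth_eeg_simon(TaskConfig(), blink_rate_hz=0.2, seed=2)
        rec_0, _, _ = synth_eeg_simon(TaskConfig(), blink_rate_hz=0.0, seed=2)
        k_b = stats.kurtosis(rec_b.data[0])
        k_0 = stats.kurtosis(rec_0.data[0])
        assert abs(k_0) < 1.0       # background is near-Gaussian
        assert k_b > k_0 + 1.0      # blinks add heavy frontal tails

    def test_determinism(self):
        a, ta, _ = synth_eeg_simon(TaskConfig(), seed=5)
        b, tb, _ = synth_eeg_simon(TaskConfig(), seed=5)
        assert np.array_equal(a.data, b.data)
        assert ta.equals(tb)


class TestGenerateSession:
    @pytest.mark.parametrize("protocol", ["exercise", "occlusion"])
    def test_streams_monotone_and_finite(self, protocol):
        sess = generate_session(protocol=protocol, seed=3)
        for s in list(sess.streams.values()) + list(sess.cached.values()):
            if len(s) > 1:
                assert np.all(np.diff(s.timestamps) > 0)
            assert np.all(np.isfinite(s.values))

    def test_same_seed_bit_identical_session(self):
        a = generate_session(seed=9)
        b = generate_session(seed=9)
        for k in a.streams:
            assert np.array_equal(a.streams[k].values, b.streams[k].values)
            assert np.array_equal(a.streams[k].timestamps, b.streams[k].timestamps)

    def test_truth_sidecar_sufficient(self, tmp_path):
        sess = generate_session(protocol="occlusion", seed=1)
        assert len(sess.truth.beat_times_s) > 0
        assert sess.truth.injected_lag_s == 2.5
        files = sess.write(tmp_path)
        assert any(f.endswith("ground_truth.json") for f in files)
        assert any(f.endswith("events.json") for f in files)
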