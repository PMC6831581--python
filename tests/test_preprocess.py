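"""Unit tests for the EMG/kinematic preprocessing chain."""

import numpy as np
import pytest

from synreach import preprocess as pp
from synreach.muscles import KINEMATIC_VARIABLES, MUSCLES, SENSOR_POSITIONS

FS = 2048.0


def _rec(data, fs=FS, labels=None):
    data = np.atleast_2d(np.asarray(data, float))
    if data.shape[0] < data.shape[1]:
        data = data.T
    labels = labels or tuple(f"m{i}" for i in range(data.shape[1]))
    return pp.EMGRecording(data=data, sampling_rate=fs, muscle_labels=labels)


class TestFiltering:
    def test_low_frequency_artifact_attenuated(self):
        """A 5 Hz component (movement artifact) must drop by > 20 dB."""
        t = np.arange(int(4 * FS)) / FS
        rec = _rec(np.sin(2 * np.pi * 5 * t))
        out = pp.bandpass_then_highpass(rec)
        mid = slice(int(FS), int(3 * FS))  # avoid filtfilt edge transients
        atten = np.max(np.abs(out.data[mid])) / 1.0
        assert atten < 10 ** (-20 / 20)
        # analytic response agrees
        assert pp.combined_filter_response([5.0])[0] < 10 ** (-20 / 20)

    def test_passband_frequency_kept(self):
        """100 Hz lies in the passband: < 3 dB attenuation."""
        t = np.arange(int(4 * FS)) / FS
        rec = _rec(np.sin(2 * np.pi * 100 * t))
        out = pp.bandpass_then_highpass(rec)
        mid = slice(int(FS), int(3 * FS))
        assert np.max(np.abs(out.data[mid])) > 10 ** (-3 / 20)
        assert pp.combined_filter_response([100.0])[0] > 10 ** (-3 / 20)

    def test_zero_signal_maps_to_zero(self):
        out = pp.bandpass_then_highpass(_rec(np.zeros(4096)))
        assert np.allclose(out.data, 0.0)

    def test_time_reversal_symmetry(self):
        """Zero-phase filtering commutes with time reversal away from the
        edge-transient regions."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(8192)
        fwd = pp.bandpass_then_highpass(_rec(x)).data[:, 0]
        rev = pp.bandpass_then_highpass(_rec(x[::-1])).data[:, 0]
        interior = slice(1024, -1024)
        assert np.allclose(fwd[interior], rev[::-1][interior], atol=1e-6)

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(pp.PreprocessError):
            pp.bandpass_then_highpass(_rec(np.zeros(2048), fs=800.0))


def _kin_from_speed(speed, fs=100.0):
    """Build a kinematic trace whose forearm speed proxy equals ``speed``."""
    n = speed.size
    acc1 = np.gradient(speed, 1.0 / fs)
    data, cols = [], []
    for sensor in SENSOR_POSITIONS:
        for var in KINEMATIC_VARIABLES:
            if sensor == "forearm" and var == "acc_x":
                data.append(acc1)
            elif var.startswith("acc"):
                data.append(np.zeros(n))
            else:
                data.append(np.ones(n))
            cols.append(f"{sensor}:{var}")
    return pp.KinematicTrace(
        data=np.column_stack(data), sampling_rate=fs, columns=tuple(cols)
    )


class TestSegmentation:
    def test_known_onset_detected(self):
        """A bell-shaped speed burst with a known analytic onset is localized
        to within two kinematic samples."""
        fs, n = 100.0, 1200
        t = np.arange(n) / fs
        rng = np.random.default_rng(1)
        speed = 0.002 * rng.random(n)
        burst = (t >= 4.0) & (t <= 6.0)
        speed[burst] += np.sin(np.pi * (t[burst] - 4.0) / 2.0) ** 2
        kin = _kin_from_speed(np.zeros(n), fs)
        seg = pp.segment_movement(
            kin, rest_window=(50, 350), emg_rate=fs, speed=speed
        )
        assert abs(seg.start_sample - 400) <= 4
        assert abs(seg.end_sample - 600) <= 4

    def test_flat_speed_raises(self):
        n = 1000
        kin = _kin_from_speed(np.zeros(n))
        speed = np.full(n, 0.5)
        speed[:400] += 1e-6 * np.sin(np.arange(400))  # rest SD > 0
        with pytest.raises(pp.SegmentationError):
            pp.segment_movement(kin, rest_window=(0, 400), emg_rate=100.0,
                                speed=speed, search_window=(500, 900))

    def test_threshold_linearity(self):
        """Doubling the rest SD doubles the margin above the rest mean."""
        n = 1000
        kin = _kin_from_speed(np.zeros(n))
        base = np.sin(np.arange(n) * 0.7)

        def detected_start(scale):
            speed = 1.0 + 0.01 * scale * base
            speed[600:] = 1.0 + np.linspace(0, 1, n - 600)  # slow ramp
            seg = pp.segment_movement(
                kin, rest_window=(0, 500), emg_rate=100.0, speed=speed
            )
            return seg.start_sample

        # the crossing of the linear ramp moves proportionally to the margin
        s1 = detected_start(1.0) - 600
        s2 = detected_start(2.0) - 600
        assert s2 == pytest.approx(2 * s1, abs=2)


class TestTonicSubtraction:
    def test_exact_ramp_cancels(self):
        """An envelope equal to its own interpolated baseline zeroes out."""
        n, w = 2000, 307  # 300 ms at 1024 Hz
        rate = 1024.0
        seg = pp.MovementSegment(start_sample=800, end_sample=1300)
        env = np.ones((n, 2))
        env[:800] *= 0.2
        env[1300:] *= 0.6
        ramp = np.linspace(0.2, 0.6, seg.n_samples)
        env[800:1300, 0] = ramp
        env[800:1300, 1] = ramp
        out = pp.tonic_subtract(env, seg, rate)
        assert np.allclose(out[800:1300], 0.0)

    def test_equal_window_means_subtract_constant(self):
        rate = 1000.0
        seg = pp.MovementSegment(start_sample=500, end_sample=900)
        env = np.full((1500, 1), 0.3)
        env[500:900] = 1.0
        out = pp.tonic_subtract(env, seg, rate)
        assert np.allclose(out[500:900], 0.7)

    def test_dips_below_baseline_clamp_to_zero(self):
        rate = 1000.0
        seg = pp.MovementSegment(start_sample=500, end_sample=900)
        env = np.full((1500, 1), 0.5)
        env[600:650] = 0.1  # dip below the flat 0.5 baseline
        out = pp.tonic_subtract(env, seg, rate)
        assert np.all(out[600:650] == 0.0)

    def test_insufficient_flank_raises(self):
        seg = pp.MovementSegment(start_sample=100, end_sample=900)
        with pytest.raises(pp.PreprocessError):
            pp.tonic_subtract(np.ones((1000, 1)), seg, rate=1000.0)


class TestEnvelopeResample:
    @pytest.mark.parametrize("seg_len", [250, 1000, 3333])
    def test_output_always_200_samples(self, seg_len):
        rng = np.random.default_rng(2)
        sig = rng.standard_normal((seg_len + 600, 3))
        seg = pp.MovementSegment(start_sample=300, end_sample=300 + seg_len)
        out = pp.envelope_and_resample(sig, seg, rate=2048.0)
        assert out.shape == (200, 3)

    def test_constant_input_passes_dc(self):
        sig = np.full((4000, 1), 0.7)
        seg = pp.MovementSegment(start_sample=1000, end_sample=3000)
        out = pp.envelope_and_resample(sig, seg, rate=2048.0)
        assert np.allclose(out, 0.7, rtol=1e-6)

    def test_rectification_sign_invariance(self):
        rng = np.random.default_rng(3)
        sig = -np.abs(rng.standard_normal((4000, 2)))
        seg = pp.MovementSegment(start_sample=1000, end_sample=3000)
        assert np.allclose(
            pp.envelope_and_resample(sig, seg, rate=2048.0),
            pp.envelope_and_resample(np.abs(sig), seg, rate=2048.0),
        )

    def test_short_segment_rejected(self):
        seg = pp.MovementSegment(start_sample=0, end_sample=10)
        with pytest.raises(pp.PreprocessError):
            pp.envelope_and_resample(np.ones((100, 1)), seg, rate=2048.0)


class TestNormalizeAverage:
    def test_identical_trials_peak_one(self):
        rng = np.random.default_rng(4)
        a = rng.random((200, 3))
        a[50] = 2.0  # common global max per muscle
        avg, div = pp.normalize_and_average(a, a)
        assert np.allclose(div, a.max(axis=0))
        assert np.allclose(avg.max(axis=0), 1.0)
        assert np.allclose(avg, a / a.max(axis=0))

    def test_divisor_is_mean_of_maxima(self):
        a = np.zeros((200, 1)); a[10] = 1.0
        b = np.zeros((200, 1)); b[20] = 3.0
        _, div = pp.normalize_and_average(a, b)
        assert div[0] == pytest.approx(2.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.random((200, 2)) + 0.1, rng.random((200, 2)) + 0.1
        avg1, _ = pp.normalize_and_average(a, b)
        avg2, _ = pp.normalize_and_average(10 * a, 10 * b)
        assert np.allclose(avg1, avg2)

    def test_global_mode_uses_single_scalar(self):
        a = np.zeros((200, 2)); a[0, 0] = 2.0; a[0, 1] = 1.0
        avg, div = pp.normalize_and_average(a, a, mode="global")
        assert np.allclose(div, 2.0)
        assert avg[0, 1] == pytest.approx(0.5)

    def test_dead_channel_named(self):
        a = np.zeros((200, 2)); a[0, 0] = 1.0
        with pytest.raises(pp.DeadChannelError, match="DEADMUSCLE"):
            pp.normalize_and_average(a, a, muscle_labels=["OK", "DEADMUSCLE"])


class TestAssembleX:
    def test_eight_targets_give_1600_columns(self, rng):
        envs = [rng.random((200, 13)) for _ in range(8)]
        X = pp.assemble_X(envs, MUSCLES)
        assert X.X.shape == (13, 1600)
        assert X.block_boundaries[-1] == (1400, 1600)
        assert np.all(X.X >= 0)
        for i in range(8):
            assert np.array_equal(X.block(i), envs[i].T)

    def test_inconsistent_muscle_count_rejected(self, rng):
        with pytest.raises(pp.PreprocessError):
            pp.assemble_X([rng.random((200, 12))], MUSCLES)


class TestSummaries:
    def test_rms_closed_forms(self):
        assert np.allclose(pp.rms_activity(np.full((200, 2), 0.4)), 0.4)
        assert np.allclose(pp.rms_activity(np.zeros((200, 1))), 0.0)
        # toy two-sample case: sqrt((9+16)/2) = sqrt(12.5)
        assert pp.rms_activity(np.array([[3.0], [4.0]]))[0] == pytest.approx(
            np.sqrt(12.5)
        )

    def test_cov_closed_forms(self):
        kin = _kin_from_speed(np.zeros(100))
        covs = pp.kinematic_cov(kin, (0, 100))
        # constant channels (roll/pitch/yaw == 1) have COV 0
        assert covs[("sternum", "roll")] == pytest.approx(0.0)
        # zero-mean acceleration channels are flagged undefined
        assert np.isnan(covs[("sternum", "acc_x")])

    def test_cov_pair_and_scale_invariance(self):
        x = np.array([1.0, 3.0])
        sd = np.std(x, ddof=1)
        assert sd / np.abs(x.mean()) == pytest.approx(0.7071, abs=1e-4)
        # COV(k x) == COV(x): direct from the definition used
        y = 5.0 * x
        assert np.std(y, ddof=1) / abs(y.mean()) == pytest.approx(
            sd / abs(x.mean())
        )
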