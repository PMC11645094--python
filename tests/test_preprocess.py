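"""Preprocessing pipeline: GRF/CoP, calibration, filtering, resampling."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fatlat import preprocess as pp
from fatlat import synthio as sio


class TestGrfCop:
    def test_equal_corner_forces_center_cop(self):
        board = np.full((50, 4), 170.0)
        out = pp.derive_grf_cop(board, mass=68.0)
        np.testing.assert_allclose(out[:, 0], 4 * 170.0 / 68.0)
        np.testing.assert_allclose(out[:, 1:], 0.0, atol=1e-12)

    def test_static_stand_grf_is_g(self):
        meta = sio.ParticipantMeta(id="b", group="B", mass=68.2, height=1.75,
                                   sets_per_exercise={"Squat": 2},
                                   random_effect={})
        board = sio.generate_static_stance(meta, 4.0, seed=1, noise_scale=0.0)
        out = pp.derive_grf_cop(board, mass=meta.mass)
        assert out[:, 0].mean() == pytest.approx(sio.GRAVITY, rel=0.01)

    def test_weight_on_right_sensors_moment_balance(self):
        """All load on the right pair puts CoP at +half the mediolateral spacing."""
        f = np.zeros((10, 4))
        f[:, 1] = f[:, 3] = 300.0  # front_right, back_right
        a, b = pp.BOARD_DIMS[0] / 2, pp.BOARD_DIMS[1] / 2
        total = f.sum(axis=1)
        cop_y_raw = b * (-f[:, 0] + f[:, 1] - f[:, 2] + f[:, 3]) / total
        np.testing.assert_allclose(cop_y_raw, b)
        # through the public API the initial value is subtracted
        out = pp.derive_grf_cop(f, mass=61.0)
        np.testing.assert_allclose(out[0, 1:], 0.0)

    def test_unloaded_board_error(self):
        with pytest.raises(pp.UnloadedBoardError, match="unloaded"):
            pp.derive_grf_cop(np.full((20, 4), 1.0), mass=70.0)

    def test_cop_first_frame_zero(self):
        rng = np.random.default_rng(4)
        board = np.abs(rng.normal(150, 20, size=(60, 4)))
        out = pp.derive_grf_cop(board, mass=70.0)
        assert out[0, 1] == 0.0 and out[0, 2] == 0.0


class TestCalibration:
    def _tpose(self, R, n=60, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        g = np.array([0, 0, sio.GRAVITY])
        acc = (R.T @ g)[None, :] + noise * rng.normal(size=(n, 3))
        gyro = noise * rng.normal(size=(n, 3))
        return acc, gyro

    def test_world_aligned_sensor_gives_identity(self):
        acc, gyro = self._tpose(np.eye(3), noise=0.01)
        R = pp.estimate_tpose_rotation(acc, gyro)
        assert np.allclose(R, np.eye(3), atol=0.02)

    def test_rotated_sensor_recovers_gravity(self):
        """90-degree mounting error about a horizontal axis is corrected."""
        true_R = Rotation.from_euler("x", 90, degrees=True).as_matrix()
        acc, gyro = self._tpose(true_R, noise=0.005)
        R_est = pp.estimate_tpose_rotation(acc, gyro)
        world = pp.apply_calibration(acc, R_est)
        mean = world.mean(axis=0)
        angle = np.degrees(np.arccos(mean[2] / np.linalg.norm(mean)))
        assert angle < 2.0  # alignment with the vertical within tolerance

    def test_non_static_window_rejected(self):
        rng = np.random.default_rng(1)
        acc = np.tile([0, 0, sio.GRAVITY], (60, 1))
        gyro = rng.normal(0, 2.0, size=(60, 3))  # far above threshold
        with pytest.raises(pp.CalibrationError, match="non-static"):
            pp.estimate_tpose_rotation(acc, gyro)

    def test_short_window_rejected(self):
        acc, gyro = self._tpose(np.eye(3), n=10)
        with pytest.raises(pp.CalibrationError, match="shorter"):
            pp.estimate_tpose_rotation(acc, gyro)


class TestGravityRemoval:
    def test_static_sensor_outputs_zero(self):
        acc = np.tile([0, 0, sio.GRAVITY], (50, 1))
        out = pp.remove_gravity_normalize(acc, height=1.8)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_linearity_and_height_scaling(self):
        t = np.linspace(0, 2, 120)
        a = np.sin(2 * np.pi * t)
        acc = np.stack([np.zeros_like(a), np.zeros_like(a),
                        sio.GRAVITY + a], axis=1)
        out1 = pp.remove_gravity_normalize(acc, height=1.75)
        np.testing.assert_allclose(out1[:, 2], a / 1.75, atol=1e-12)
        out2 = pp.remove_gravity_normalize(acc, height=3.5)
        np.testing.assert_allclose(out2[:, 2], out1[:, 2] / 2, atol=1e-12)


class TestLowpass:
    def test_dc_gain_unity(self):
        x = np.full(300, 3.7)
        np.testing.assert_allclose(pp.lowpass_filter(x, fs=60), x, atol=1e-9)

    def test_cutoff_attenuation_half(self):
        """Forward-backward 15 Hz Butterworth halves a 15 Hz sinusoid."""
        t = np.arange(0, 60, 1 / 60)
        x = np.sin(2 * np.pi * 15 * t)
        y = pp.lowpass_filter(x, fs=60)
        core = slice(300, -300)  # avoid edge transients
        ratio = np.abs(y[core]).max() / np.abs(x[core]).max()
        assert ratio == pytest.approx(0.5, abs=0.02)

    def test_stopband_attenuation(self):
        t = np.arange(0, 60, 1 / 60)
        x = np.sin(2 * np.pi * 25 * t)
        y = pp.lowpass_filter(x, fs=60)
        assert np.abs(y[300:-300]).max() < 0.05

    def test_passband_idempotent(self):
        t = np.arange(0, 10, 1 / 60)
        x = np.sin(2 * np.pi * 1.0 * t)
        once = pp.lowpass_filter(x, fs=60)
        twice = pp.lowpass_filter(once, fs=60)
        core = slice(120, -120)
        assert np.abs(twice[core] - once[core]).max() < 0.005 * np.abs(once[core]).max()

    def test_nyquist_error(self):
        with pytest.raises(ValueError, match="cutoff"):
            pp.lowpass_filter(np.zeros(100), fs=30)

    def test_short_signal_error(self):
        with pytest.raises(ValueError, match="too short"):
            pp.lowpass_filter(np.zeros(10), fs=60)


class TestSegmentation:
    def test_concatenated_cohort_reps_recovered(self):
        cfg = sio.GeneratorConfig(n_group_a=0, n_group_b=1, sets_range=(2, 2), seed=7)
        _, reps = sio.generate_cohort(cfg)
        rep_list = [reps[("B00", "Squat", 0, i)] for i in range(10)]
        stream, truth = sio.concatenate_repetitions(rep_list, seed=3)
        found = pp.segment_repetitions(stream)
        assert len(found) == 10
        for (fs, fe), (ts, te) in zip(found, truth):
            assert abs(fs - ts) <= 3 and abs(fe - te) <= 3

    def test_all_zero_stream_empty(self):
        assert pp.segment_repetitions(np.zeros(600)) == []

    def test_single_burst_single_interval(self):
        x = np.zeros(600)
        x[200:400] = 2.0
        iv = pp.segment_repetitions(x)
        assert len(iv) == 1
        s, e = iv[0]
        assert abs(s - 200) <= 4 and abs(e - 400) <= 4

    def test_intervals_sorted_disjoint(self):
        rng = np.random.default_rng(0)
        x = np.abs(rng.normal(0, 0.1, 2000))
        x[100:300] += 2.0
        x[500:800] += 2.0
        iv = pp.segment_repetitions(x)
        assert iv == sorted(iv)
        for (s1, e1), (s2, e2) in zip(iv, iv[1:]):
            assert e1 <= s2


class TestResampling:
    def test_linear_ramp_preserved(self):
        t = np.arange(0, 2, 1 / 30)
        x = 3.0 * t
        out = pp.resample_to_frames(t, x)
        assert len(out) == 192
        np.testing.assert_allclose(out, np.linspace(x[0], x[-1], 192), atol=1e-9)

    def test_sine_close_to_analytic(self):
        t = np.arange(0, 2, 1 / 60)
        out = pp.resample_to_frames(t, np.sin(2 * np.pi * t))
        grid = np.linspace(t[0], t[-1], 192)
        assert np.abs(out - np.sin(2 * np.pi * grid)).max() < 1e-4

    def test_uniform_192_identity(self):
        t = np.linspace(0, 1, 192)
        x = np.random.default_rng(1).normal(size=192)
        np.testing.assert_allclose(pp.resample_to_frames(t, x), x, atol=1e-9)

    def test_endpoints_exact(self):
        t = np.arange(0, 1.5, 1 / 30)
        x = np.random.default_rng(2).normal(size=len(t))
        out = pp.resample_to_frames(t, x)
        assert out[0] == pytest.approx(x[0], abs=1e-12)
        assert out[-1] == pytest.approx(x[-1], abs=1e-12)

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError, match=">= 4"):
            pp.resample_to_frames(np.arange(3), np.arange(3))


class TestStandardization:
    def _toy(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 192, 4))
        X[:, :, 0] = X[:, :, 0] * 3 + 10  # grf channel, different scale
        return X, ["grf", "cop", "cop", "acc"]

    def test_training_pool_mean_zero_sd_one(self):
        X, types = self._toy()
        std = pp.compute_standardization(X, types)
        Z = std.transform(X)
        ta = np.asarray(types)
        for t in ("grf", "cop", "acc"):
            vals = Z[:, :, ta == t]
            assert abs(vals.mean()) < 1e-10
            assert abs(vals.std() - 1) < 1e-10

    def test_constant_at_mean_maps_to_zero(self):
        X, types = self._toy()
        std = pp.compute_standardization(X, types)
        X0 = np.stack([np.full((192, 1), std.stats_[t][0]) for t in types], axis=2
                      ).transpose(1, 0, 2).reshape(1, 192, 4)
        np.testing.assert_allclose(std.transform(X0), 0.0, atol=1e-12)

    def test_held_out_hand_computed(self):
        X, types = self._toy()
        std = pp.compute_standardization(X, types)
        x = np.array([1.0, -2.0, 0.5, 7.0, 3.0])
        mu, sd = std.stats_["cop"]
        hand = (x - mu) / sd
        held = np.zeros((1, 192, 4))
        held[0, :5, 1] = x
        out = std.transform(held)
        np.testing.assert_allclose(out[0, :5, 1], hand, atol=1e-12)

    def test_invertible(self):
        X, types = self._toy()
        std = pp.compute_standardization(X, types)
        np.testing.assert_allclose(std.inverse_transform(std.transform(X)), X,
                                   atol=1e-10)

    def test_degenerate_type_errors_with_name(self):
        X, types = self._toy()
        X[:, :, 3] = 2.0
        with pytest.raises(ValueError, match="acc"):
            pp.compute_standardization(X, types)

    def test_json_round_trip(self):
        X, types = self._toy()
        std = pp.compute_standardization(X, types)
        restored = pp.TypeStandardizer.from_json(std.to_json(fold=2, training_subjects=["a"]))
        np.testing.assert_allclose(restored.transform(X), std.transform(X))
        assert restored.fold == 2


@pytest.fixture(scope="module")
def cohort(tmp_path_factory):
    cfg = sio.GeneratorConfig(n_group_a=2, n_group_b=0, seed=21)
    manifest, reps = sio.generate_cohort(cfg)
    d = tmp_path_factory.mktemp("coh")
    sio.write_cohort(manifest, reps, d)
    return sio.read_cohort(d)


class TestAssembleDataset:

    @pytest.mark.parametrize("db,n", [("DB0", 3), ("DB1", 9), ("DB2", 21),
                                      ("DB3", 6), ("DB4", 18)])
    def test_channel_counts(self, db, n):
        assert len(pp.db_channels(db)) == n

    def test_dataset_shapes_and_counts(self, cohort):
        ds = pp.assemble_dataset(cohort, "DB0")
        assert len(ds) == 2 * 4 * 10
        assert all(d.X.shape == (192, 3) for d in ds)

    def test_one_hot_class_order(self, cohort):
        ds = pp.assemble_dataset(cohort, "DB0", participants=["A00"])
        squat = next(d for d in ds if d.exercise == "Squat")
        np.testing.assert_array_equal(squat.y, [1, 0, 0, 0])
        lunge = next(d for d in ds if d.exercise == "LungeLeft")
        np.testing.assert_array_equal(lunge.y, [0, 1, 0, 0])

    def test_cop_channels_start_at_zero(self, cohort):
        ds = pp.assemble_dataset(cohort, "DB0", participants=["A00"])
        for d in ds:
            assert d.X[0, 1] == pytest.approx(0.0, abs=1e-9)
            assert d.X[0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_pipeline_pure(self, cohort):
        a = pp.assemble_dataset(cohort, "DB3", participants=["A00"])
        b = pp.assemble_dataset(cohort, "DB3", participants=["A00"])
        np.testing.assert_array_equal(a[0].X, b[0].X)

    def test_unknown_database(self, cohort):
        with pytest.raises(ValueError, match="unknown database"):
            pp.db_channels("DB9")
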