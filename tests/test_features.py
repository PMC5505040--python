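import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.regression.linear_model import burg as sm_burg

from emgimu.errors import ValidationError
from emgimu.features import (
    LOGVAR_EPS,
    WindowConfig,
    apply_standardizer,
    build_feature_matrix,
    burg_ar,
    emg_td_features,
    fit_standardizer,
    im_mean_features,
    segment_windows,
)
from emgimu.preprocessing import synchronize
from emgimu.synthetic_data import SynthConfig, generate_recording
from tests.conftest import small_config


class TestSegmentWindows:
    def test_count_matches_enumeration_oracle(self, small_aligned):
        # oracle: enumerate starts while start + len <= n
        for wc in (WindowConfig(), WindowConfig(256, 256), WindowConfig(100, 30)):
            length, inc = wc.in_samples(small_aligned.f_emg)
            n = small_aligned.n_samples
            oracle = len([s for s in range(0, n, inc) if s + length <= n])
            win = segment_windows(small_aligned, wc)
            assert len(win) == oracle == (n - length) // inc + 1

    def test_default_one_second_gives_15_windows(self, small_aligned):
        # 1 s at 2 kHz: len 512, inc 100 -> floor((2000-512)/100)+1 = 15
        import copy

        ar = copy.copy(small_aligned)
        ar.emg = ar.emg[:2000]
        ar.im_on_emg_grid = ar.im_on_emg_grid[:2000]
        ar.labels = ar.labels[:2000]
        win = segment_windows(ar, WindowConfig())
        assert win.length == 512 and win.increment == 100
        assert len(win) == 15

    def test_nonoverlapping_tiling(self, small_aligned):
        wc = WindowConfig(length_ms=256, increment_ms=256)
        win = segment_windows(small_aligned, wc)
        n = small_aligned.n_samples
        assert len(win) == n // win.length

    def test_majority_label_rule(self, small_aligned):
        import copy

        ar = copy.copy(small_aligned)
        n = 2000
        ar.emg = np.zeros((n, 1))
        ar.im_on_emg_grid = np.zeros((n, 9))
        labels = np.zeros(n, dtype=int)
        labels[:307] = 1  # window 0 (512 samples): 307 of class 1 vs 205 rest
        ar.labels = labels
        from emgimu.dataio import SensorLayout

        ar.layout = SensorLayout.default(1)
        win = segment_windows(ar, WindowConfig())
        assert win.labels[0] == 1

    def test_tie_goes_to_window_end_label(self, small_aligned):
        import copy

        ar = copy.copy(small_aligned)
        n = 2000
        ar.emg = np.zeros((n, 1))
        ar.im_on_emg_grid = np.zeros((n, 9))
        labels = np.zeros(n, dtype=int)
        labels[256:512] = 2  # exactly half of window 0; end label = 2
        ar.labels = labels
        from emgimu.dataio import SensorLayout

        ar.layout = SensorLayout.default(1)
        win = segment_windows(ar, WindowConfig())
        assert win.labels[0] == 2

    def test_too_short_recording_rejected(self, small_aligned):
        import copy

        ar = copy.copy(small_aligned)
        ar.emg = ar.emg[:100]
        ar.im_on_emg_grid = ar.im_on_emg_grid[:100]
        ar.labels = ar.labels[:100]
        with pytest.raises(ValidationError):
            segment_windows(ar, WindowConfig())


class TestEmgTdFeatures:
    def test_alternating_signal_hand_computed(self):
        x = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        f = emg_td_features(x)
        assert f[0] == pytest.approx(1.0)  # MAV
        assert f[1] == pytest.approx(14.0)  # WL

    def test_constant_window(self):
        x = np.full(64, 3.0)
        f = emg_td_features(x)
        assert f[0] == pytest.approx(3.0)
        assert f[1] == pytest.approx(0.0)
        assert f[6] == pytest.approx(np.log(LOGVAR_EPS))  # floored LogVar
        np.testing.assert_allclose(f[2:6], 0.0)  # degenerate AR -> zeros

    def test_brute_force_definitions(self, rng):
        # independent oracle on 1000 random 512-sample windows
        X = rng.standard_normal((1000, 512))
        for i in range(0, 1000, 97):
            x = X[i]
            f = emg_td_features(x)
            assert abs(f[0] - sum(abs(v) for v in x) / len(x)) < 1e-10
            assert abs(f[1] - sum(abs(x[j + 1] - x[j]) for j in range(511))) < 1e-10
            mean = sum(x) / len(x)
            var = sum((v - mean) ** 2 for v in x) / (len(x) - 1)
            assert abs(f[6] - np.log(var)) < 1e-10

    def test_ar_recovery_within_0_1(self, rng):
        # planted AR(4) process; averaged estimate within 0.1 of truth
        a_true = np.array([0.5, -0.3, 0.2, -0.1])
        errs = []
        for _ in range(100):
            x = np.zeros(612)
            e = rng.standard_normal(612)
            for t in range(4, 612):
                x[t] = a_true @ x[t - 4 : t][::-1] + e[t]
            est = burg_ar(x[100:][None, :], 4)[0]
            errs.append(np.abs(est - a_true))
        assert np.mean(errs, axis=0).max() < 0.1

    def test_burg_matches_statsmodels_oracle(self, rng):
        for _ in range(20):
            x = rng.standard_normal(256)
            mine = burg_ar(x[None, :], 4)[0]
            ref, _ = sm_burg(x - x.mean(), order=4, demean=False)
            np.testing.assert_allclose(mine, ref, atol=1e-8)

    def test_too_short_window_rejected(self):
        with pytest.raises(ValidationError):
            emg_td_features(np.ones(4), ar_order=4)

    def test_non_finite_rejected(self):
        x = np.ones(32)
        x[3] = np.nan
        with pytest.raises(ValidationError):
            emg_td_features(x)

    @given(
        k=st.floats(min_value=0.01, max_value=100),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(max_examples=25, deadline=None)
    def test_scaling_homogeneity(self, k, seed):
        # MAV, WL scale by k; LogVar shifts by 2 ln k; AR unchanged
        x = np.random.default_rng(seed).standard_normal(128)
        f1 = emg_td_features(x)
        f2 = emg_td_features(k * x)
        assert f2[0] == pytest.approx(k * f1[0], rel=1e-9)
        assert f2[1] == pytest.approx(k * f1[1], rel=1e-9)
        np.testing.assert_allclose(f2[2:6], f1[2:6], atol=1e-9)
        assert f2[6] - f1[6] == pytest.approx(2 * np.log(k), abs=1e-8)


class TestImMeanFeatures:
    def test_constant_channels(self):
        w = np.tile(np.arange(9.0), (50, 1))
        np.testing.assert_allclose(im_mean_features(w), np.arange(9.0))

    def test_linear_ramp_midpoint(self):
        w = np.linspace(0, 1, 11)[:, None] * np.ones((1, 9))
        np.testing.assert_allclose(im_mean_features(w), 0.5)

    def test_empty_window_rejected(self):
        with pytest.raises(ValidationError):
            im_mean_features(np.empty((0, 9)))

    def test_generator_offsets_recovered(self):
        off = np.zeros((2, 9))
        off[1] = np.arange(1, 10.0)
        cfg = SynthConfig(
            n_classes=1, n_sensors=1, n_repetitions=2,
            trial_duration_s=1.0, rest_duration_s=0.5,
            im_offset=off, noise_sd_im=0.05, seed=6,
        )
        ar = synchronize(generate_recording(cfg))
        F = build_feature_matrix(ar, modality="im")
        win = segment_windows(ar, WindowConfig())
        # only windows lying fully inside a class-1 segment; boundary
        # windows mix rest samples into the mean by construction
        full = np.array(
            [np.all(ar.labels[s : s + win.length] == 1) for s in win.starts]
        )
        active = F.X[full]
        # window means within 3*sd/sqrt(len_im) of the planted offsets
        len_im = int(0.256 * 128)
        tol = 3 * 0.05 / np.sqrt(len_im)
        assert np.all(np.abs(active.mean(axis=0) - off[1]) < tol)


@pytest.fixture(scope="module")
def aligned12():
    cfg = SynthConfig(
        n_classes=2, n_sensors=12, n_repetitions=1,
        trial_duration_s=0.5, rest_duration_s=0.3, seed=2,
    )
    return synchronize(generate_recording(cfg))


class TestBuildFeatureMatrix:

    def test_condition_dimensionalities(self, aligned12):
        # conditions I-IV of the real-time experiment
        assert build_feature_matrix(aligned12, modality="emg").d == 84
        assert build_feature_matrix(aligned12, modality="im").d == 108
        assert build_feature_matrix(aligned12, modality="both").d == 192
        assert build_feature_matrix(
            aligned12, modality="both", sensors=[1, 2, 10]
        ).d == 48

    def test_per_sensor_blocks_contiguous(self, aligned12):
        F = build_feature_matrix(aligned12, modality="both")
        sensors = [c.sensor for c in F.columns]
        assert sensors == sorted(sensors)
        block = F.sensor_block(5)
        assert list(block) == list(range(block[0], block[0] + 16))

    def test_unknown_sensor_rejected(self, aligned12):
        with pytest.raises(ValidationError):
            build_feature_matrix(aligned12, sensors=[13])

    def test_start_time_invariance(self, small_recording):
        # features do not depend on the recording's absolute start time:
        # dropping whole increments shifts windows but leaves values equal
        ar = synchronize(small_recording)
        F = build_feature_matrix(ar)
        import copy

        ar2 = copy.copy(ar)
        shift = 200  # 2 increments at 2 kHz
        ar2.emg = ar.emg[shift:]
        ar2.im_on_emg_grid = ar.im_on_emg_grid[shift:]
        ar2.labels = ar.labels[shift:]
        F2 = build_feature_matrix(ar2)
        np.testing.assert_allclose(F2.X[:10], F.X[2:12], atol=1e-12)


class TestStandardizer:
    def test_train_rows_zero_mean_unit_sd(self, small_features):
        rows = np.arange(small_features.n_windows)
        S = fit_standardizer(small_features, rows)
        Fz = apply_standardizer(S, small_features)
        assert np.abs(Fz.X.mean(axis=0)).max() < 1e-10
        np.testing.assert_allclose(Fz.X.std(axis=0), 1.0, atol=1e-10)

    def test_single_row_training_rejected(self, small_features):
        with pytest.raises(ValidationError):
            fit_standardizer(small_features, np.array([0]))

    def test_affine_contract_on_test_rows(self, small_features):
        import copy

        rows = np.arange(small_features.n_windows // 2)
        S = fit_standardizer(small_features, rows)
        Fz = apply_standardizer(S, small_features)
        F2 = copy.copy(small_features)
        F2.X = small_features.X + 5.0
        Fz2 = apply_standardizer(S, F2)
        np.testing.assert_allclose(Fz2.X, Fz.X + 5.0 / S.sd, atol=1e-9)

    def test_zero_variance_column_dropped_with_warning(self, small_features, caplog):
        import copy

        F2 = copy.copy(small_features)
        F2.X = small_features.X.copy()
        F2.X[:, 3] = 7.0
        with caplog.at_level("WARNING"):
            S = fit_standardizer(F2, np.arange(F2.n_windows))
        assert S.n_kept == F2.d - 1
        assert "zero-variance" in caplog.text
        Fz = apply_standardizer(S, F2)
        assert Fz.d == F2.d - 1
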