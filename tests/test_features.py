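"""Window preprocessing, hand-movement gating and the 36-feature catalog."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import sleepscratch as ss
from sleepscratch.features import (
    FEATURE_NAMES,
    detect_hand_movement,
    extract_features,
    preprocess_window,
    sparc,
)

FS = 20.0
N = 60  # one 3-s window


def _tone(freq, amp=0.3, n=N, fs=FS, axis=None):
    t = np.arange(n) / fs
    s = amp * np.sin(2 * np.pi * freq * t)
    if axis is None:
        return s
    out = np.zeros((n, 3))
    out[:, axis] = s
    return out


class TestPreprocess:
    def test_svm_is_norm_of_filtered_axes(self):
        # 3-4-5 proportions on x/y, high enough in frequency to pass the
        # 0.25-Hz high-pass almost untouched
        sq = np.sign(np.sin(2 * np.pi * 5.0 * np.arange(N) / FS + 0.3))
        raw = np.column_stack([0.6 * sq, 0.8 * sq, np.zeros(N)])
        svm, _, _ = preprocess_window(raw, fs=FS)
        from sleepscratch.features import highpass_filter

        np.testing.assert_allclose(
            svm, np.linalg.norm(highpass_filter(raw, fs=FS), axis=1), atol=1e-12
        )
        np.testing.assert_allclose(svm[10:], 1.0, atol=0.1)  # filter droop

    def test_constant_window_filters_to_zero(self):
        # the causal first-order high-pass has a ~0.6-s time constant, so a
        # constant input decays to (near) zero after the transient
        n = 200
        raw = np.tile([0.2, -0.1, 0.95], (n, 1))
        svm, pc1, pc2 = preprocess_window(raw, fs=FS)
        assert np.abs(svm[-50:]).max() < 0.02
        assert np.abs(pc1[-50:]).max() < 0.1
        assert np.abs(pc2[-50:]).max() < 0.1

    def test_svm_invariant_to_fixed_rotation(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(0, 0.3, size=(N, 3)) + np.array([0, 0, 1.0])
        rot = Rotation.from_euler("xyz", [30, -45, 60], degrees=True).as_matrix()
        svm_a, _, _ = preprocess_window(raw, fs=FS)
        svm_b, _, _ = preprocess_window(raw @ rot.T, fs=FS)
        np.testing.assert_allclose(svm_a, svm_b, atol=1e-9)

    def test_svm_features_invariant_to_fixed_rotation(self):
        rng = np.random.default_rng(4)
        raw = rng.normal(0, 0.3, size=(N, 3)) + np.array([0, 0, 1.0])
        rot = Rotation.from_euler("zyx", [10, 70, -25], degrees=True).as_matrix()
        fa = extract_features(*preprocess_window(raw, fs=FS), fs=FS)
        fb = extract_features(*preprocess_window(raw @ rot.T, fs=FS), fs=FS)
        svm_slice = slice(0, 12)  # svm features lead the catalog
        np.testing.assert_allclose(fa[svm_slice], fb[svm_slice], atol=1e-7)

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            preprocess_window(np.zeros((N, 2)))


class TestHandMovement:
    def test_still_gravity_window_is_not_movement(self):
        raw = np.tile([0.0, 0.0, 1.0], (N, 1))
        assert detect_hand_movement(raw, fs=FS) is False

    def test_oscillation_on_gravity_is_movement(self):
        raw = np.tile([0.0, 0.0, 1.0], (N, 1)) + _tone(4.0, amp=0.4, axis=0)
        assert detect_hand_movement(raw, fs=FS) is True

    def test_threshold_boundary_is_strict(self):
        raw = np.tile([0.0, 0.0, 1.0], (N, 1)) + _tone(4.0, amp=0.4, axis=0)
        mag = np.linalg.norm(raw, axis=1)
        views = np.lib.stride_tricks.sliding_window_view(mag, 10)
        min_cov = (views.std(axis=1) / views.mean(axis=1)).min()
        # at exactly the minimal CoV the strict ">" must fail the gate
        assert detect_hand_movement(raw, fs=FS, cov_threshold=min_cov) is False
        assert detect_hand_movement(raw, fs=FS, cov_threshold=min_cov * 0.999) is True

    def test_movement_in_only_half_the_window_fails_gate(self):
        raw = np.tile([0.0, 0.0, 1.0], (N, 1))
        raw[: N // 2] += _tone(4.0, amp=0.4, n=N, axis=0)[: N // 2]
        assert detect_hand_movement(raw, fs=FS) is False

    def test_zero_magnitude_window_is_not_movement(self):
        assert detect_hand_movement(np.zeros((N, 3)), fs=FS) is False


class TestFeatureCatalog:
    def test_exactly_36_finite_features(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(0, 0.3, size=(N, 3)) + np.array([0, 0, 1.0])
        f = extract_features(*preprocess_window(raw, fs=FS), fs=FS)
        assert f.shape == (36,)
        assert np.isfinite(f).all()
        assert len(FEATURE_NAMES) == 36
        assert len(set(FEATURE_NAMES)) == 36

    def test_pure_tone_dominant_frequency(self):
        x = _tone(3.0, n=600)  # 30-s signal: fine frequency resolution
        f = extract_features(x, np.zeros(600), np.zeros(600), fs=FS)
        dom = f[FEATURE_NAMES.index("svm_dominant_freq")]
        assert dom == pytest.approx(3.0, abs=FS / 600 + 1e-9)

    def test_all_zero_signal_conventions(self):
        z = np.zeros(N)
        f = extract_features(z, z, z, fs=FS)
        assert np.isfinite(f).all()
        assert f[FEATURE_NAMES.index("svm_mean_cross_rate")] == 0.0
        assert f[FEATURE_NAMES.index("svm_dominant_freq")] == 0.0
        assert f[FEATURE_NAMES.index("svm_sparc")] == 0.0

    def test_mismatched_signal_lengths_rejected(self):
        with pytest.raises(ValueError):
            extract_features(np.zeros(10), np.zeros(11), np.zeros(10))

    def test_sparc_ranks_smooth_below_jerky(self):
        smooth = _tone(1.0, n=200)
        jerky = _tone(1.0, n=200) + 0.5 * _tone(7.0, n=200)
        assert sparc(smooth, FS) > sparc(jerky, FS)  # less negative = smoother

    def test_jerk_ratio_increases_with_frequency(self):
        lo = extract_features(_tone(1.0), np.zeros(N), np.zeros(N), fs=FS)
        hi = extract_features(_tone(6.0), np.zeros(N), np.zeros(N), fs=FS)
        j = FEATURE_NAMES.index("svm_jerk_ratio")
        assert hi[j] > lo[j]


class TestExtractorEstimator:
    def test_transform_shape_and_names(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 0.2, size=(5, N, 3))
        ext = ss.WindowFeatureExtractor()
        out = ext.fit_transform(X)
        assert out.shape == (5, 36)
        assert list(ext.get_feature_names_out()) == list(FEATURE_NAMES)

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            ss.WindowFeatureExtractor().transform(np.zeros((5, N)))
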