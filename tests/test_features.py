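import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from afdetect.features import (
    DecorrelationParams,
    FeatureConfig,
    _dwt97_1d,
    decorrelate,
    delta_series,
    extract_features,
    lorenz_points,
    rasterize,
    wavelet_approx,
)
from afdetect.rr_io import Window

window_arrays = hnp.arrays(
    np.float64, 60,
    elements=st.floats(min_value=300.0, max_value=2000.0),
)


class TestDeltaAndLorenz:
    def test_constant_input_gives_zero_deltas(self):
        assert np.array_equal(delta_series(np.array([800.0] * 4)), [0, 0, 0])

    def test_successive_differences(self):
        assert np.array_equal(delta_series(np.array([800.0, 760.0, 900.0])),
                              [-40, 140])

    def test_sixty_intervals_give_59_deltas_58_points(self):
        w = Window(np.linspace(700, 900, 60))
        d = delta_series(w)
        assert d.size == 59
        assert lorenz_points(d).shape == (58, 2)

    def test_pairing_definition(self):
        pts = lorenz_points(np.array([3.0, 7.0]))
        assert pts.tolist() == [[7.0, 3.0]]  # X = current, Y = previous

    def test_too_short_inputs_rejected(self):
        with pytest.raises(ValueError):
            delta_series(np.array([800.0]))
        with pytest.raises(ValueError):
            lorenz_points(np.array([1.0]))


class TestDecorrelate:
    def test_zero_x_leaves_y_unchanged(self):
        out = decorrelate(np.array([[0.0, 120.0]]))
        assert np.allclose(out, [[0.0, 120.0]])

    def test_positive_branch_value(self):
        # 0.5 * 100**0.75 = 15.8113883...
        out = decorrelate(np.array([[100.0, 0.0]]))
        assert out[0, 1] == pytest.approx(15.8113883, abs=1e-6)

    def test_signed_power_for_negative_x(self):
        out = decorrelate(np.array([[-100.0, 20.0]]))
        assert out[0, 1] == pytest.approx(20.0 - 15.8113883, abs=1e-6)

    def test_x_coordinates_preserved(self):
        pts = np.array([[-50.0, 10.0], [0.0, -3.0], [120.0, 7.0]])
        assert np.array_equal(decorrelate(pts)[:, 0], pts[:, 0])

    @given(hnp.arrays(np.float64, (20, 2),
                      elements=st.floats(min_value=-500, max_value=500)))
    @settings(max_examples=50, deadline=None)
    def test_odd_symmetry(self, pts):
        """Transforming the negated cloud equals negating the transform."""
        assert np.allclose(decorrelate(-pts), -decorrelate(pts), atol=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            decorrelate(np.array([[np.nan, 0.0]]))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            DecorrelationParams(alpha=-1.0)
        with pytest.raises(ValueError):
            DecorrelationParams(beta=1.5)

    @pytest.mark.parametrize("sd", [50.0, 100.0, 150.0, 200.0])
    def test_correlation_reduction_for_iid_intervals(self, sd):
        """|corr(X, Y')| < |corr(X, Y)| for uncorrelated RR streams."""
        rng = np.random.default_rng(1234)
        rr = 800 + rng.normal(0.0, sd, 10_000)
        pts = lorenz_points(delta_series(rr))
        dec = decorrelate(pts)
        c_before = np.corrcoef(pts[:, 0], pts[:, 1])[0, 1]
        c_after = np.corrcoef(dec[:, 0], dec[:, 1])[0, 1]
        assert c_before == pytest.approx(-0.5, abs=0.05)
        assert abs(c_after) < abs(c_before)


class TestRasterize:
    def test_single_bin_case(self):
        pts = np.zeros((58, 2))
        img = rasterize(pts)
        assert img[32, 32] == 58
        assert img.sum() == 58

    def test_empty_point_set(self):
        assert rasterize(np.empty((0, 2))).sum() == 0

    def test_corner_binning(self):
        # floor((599.9+600)/1200*64) = 63; floor((-599.9+600)/1200*64) = 0
        img = rasterize(np.array([[599.9, -599.9]]))
        assert img[0, 63] == 1

    def test_out_of_range_points_clamp_to_edges(self):
        img = rasterize(np.array([[10_000.0, -10_000.0]]))
        assert img[0, 63] == 1

    @given(hnp.arrays(np.float64, (58, 2),
                      elements=st.floats(min_value=-2000, max_value=2000)))
    @settings(max_examples=50, deadline=None)
    def test_counts_conserved(self, pts):
        assert rasterize(pts).sum() == 58


class TestWaveletApprox:
    def test_zero_image(self):
        assert np.array_equal(wavelet_approx(np.zeros((64, 64))), np.zeros(64))

    def test_constant_image_haar(self):
        out = wavelet_approx(np.full((64, 64), 3.0), wavelet="haar")
        assert np.allclose(out, 24.0)  # 8 * c for orthonormal Haar

    def test_constant_image_cdf97(self):
        # CDF 9/7 low-pass has DC gain sqrt(2) per level per axis
        out = wavelet_approx(np.full((64, 64), 3.0), wavelet="cdf97")
        assert np.allclose(out, 24.0, rtol=1e-9)

    def test_linearity(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 30, (64, 64)).astype(float)
        assert np.allclose(wavelet_approx(3.5 * img),
                           3.5 * wavelet_approx(img), rtol=1e-12)

    def test_haar_ll_equals_block_sums_over_8(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            img = rng.integers(0, 50, (64, 64)).astype(float)
            ll = wavelet_approx(img, wavelet="haar").reshape(8, 8)
            blocks = img.reshape(8, 8, 8, 8).sum(axis=(1, 3)) / 8.0
            assert np.allclose(ll, blocks, atol=1e-9)

    def test_lifting_matches_pywt_filter_bank_interior(self):
        """One 9/7 analysis level agrees with the convolutional
        implementation away from the boundary (extension differs)."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=128)
        lo, hi = _dwt97_1d(x[None, :], axis=1)
        ca, cd = pywt.dwt(x, "bior4.4", mode="symmetric")
        off = 2  # pywt's symmetric mode emits extra boundary coefficients
        n = lo.shape[1]
        assert np.allclose(lo[0, 3:n - 3], ca[3 + off:n - 3 + off], atol=1e-9)
        assert np.allclose(np.abs(hi[0, 3:n - 3]),
                           np.abs(cd[3 + off:n - 3 + off]), atol=1e-9)

    def test_indivisible_side_rejected(self):
        with pytest.raises(ValueError):
            wavelet_approx(np.zeros((20, 20)), levels=3)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            wavelet_approx(np.zeros((64, 32)))


class TestExtractFeatures:
    def test_output_length_64(self, constant_window, config):
        assert extract_features(constant_window, config).shape == (64,)

    def test_constant_window_matches_manual_composition(self, config):
        w = Window(np.full(60, 800.0))
        fv = extract_features(w, config)
        img = rasterize(np.zeros((58, 2)), config.resolution, config.extent_ms)
        manual = wavelet_approx(img, config.levels, config.wavelet)
        assert np.array_equal(fv, manual)

    @given(window_arrays)
    @settings(max_examples=25, deadline=None)
    def test_deterministic_and_count_conserving(self, rr):
        w = Window(rr)
        assert np.array_equal(extract_features(w), extract_features(w))
        pts = decorrelate(lorenz_points(delta_series(w)))
        assert rasterize(pts).sum() == 58

    def test_af_and_sinus_windows_differ(self):
        from afdetect.synthetic import Rhythm, RhythmGeneratorSpec, generate
        af = generate(RhythmGeneratorSpec(Rhythm.AF, 1, 11))[0]
        sinus = generate(RhythmGeneratorSpec(Rhythm.SINUS, 1, 12))[0]
        d = np.linalg.norm(extract_features(af) - extract_features(sinus))
        assert d > 0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FeatureConfig(resolution=48)  # not a power of two
        with pytest.raises(ValueError):
            FeatureConfig(wavelet="db4")

    def test_feature_csv_round_trip(self, tmp_path, small_dataset):
        from afdetect.features import read_feature_csv, write_feature_csv
        from afdetect.rr_io import RhythmLabel
        x, y, _ = small_dataset
        path = tmp_path / "features.csv"
        write_feature_csv(path, x, y)
        x2, y2 = read_feature_csv(path)
        assert np.allclose(x, x2)
        assert [RhythmLabel(v) for v in y2] == y

    def test_fingerprint_tracks_content(self):
        assert FeatureConfig().fingerprint() == FeatureConfig().fingerprint()
        assert (FeatureConfig(extent_ms=500.0).fingerprint()
                != FeatureConfig().fingerprint())
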