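import numpy as np
import pytest

from streetstat import ica, maps, synth
from .conftest import GRATING_FREQS


def brute_force_contrast_map(img, size, stride):
    nh = (img.shape[0] - size) // stride + 1
    nw = (img.shape[1] - size) // stride + 1
    out = np.zeros((nh, nw))
    for i in range(nh):
        for j in range(nw):
            patch = img[i * stride:i * stride + size,
                        j * stride:j * stride + size]
            out[i, j] = np.std(patch.flatten(order="F"))
    return out


def brute_force_kurtosis_at(img, bank, i, j):
    patch = img[i:i + bank.patch_size, j:j + bank.patch_size]
    x = maps.vectorize_neighborhood(patch)
    a = maps.filter_responses(maps.log_transform(x), bank)
    return maps.response_kurtosis(a)


class TestVectorize:
    def test_column_major_convention(self):
        out = maps.vectorize_neighborhood(np.array([[1, 2], [3, 4]]))
        assert list(out) == [1, 3, 2, 4]

    def test_constant_patch(self):
        assert np.array_equal(maps.vectorize_neighborhood(np.full((3, 3), 7)),
                              np.full(9, 7))

    def test_round_trip(self, rng):
        patch = rng.uniform(0, 255, (5, 5))
        vec = maps.vectorize_neighborhood(patch)
        assert np.array_equal(vec.reshape(5, 5, order="F"), patch)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            maps.vectorize_neighborhood(np.zeros((2, 3)))


class TestRmsContrast:
    def test_constant_vector_zero(self):
        assert maps.rms_contrast(np.full(16, 42.0)) == 0.0

    def test_two_level_edge_closed_form(self):
        x = np.concatenate([np.full(8, 30.0), np.full(8, 130.0)])
        assert maps.rms_contrast(x) == pytest.approx(50.0, abs=1e-12)

    def test_extreme_binary_vector(self):
        assert maps.rms_contrast(np.tile([0.0, 255.0], 8)) == \
            pytest.approx(127.5, abs=1e-12)

    def test_affine_scaling_property(self, rng):
        for _ in range(20):
            x = rng.uniform(0, 255, 32)
            alpha, beta = rng.uniform(0, 3), rng.uniform(-10, 10)
            assert maps.rms_contrast(alpha * x + beta) == \
                pytest.approx(alpha * maps.rms_contrast(x), rel=1e-10)


class TestContrastMap:
    def test_constant_image_all_zero(self):
        out = maps.contrast_map(np.full((32, 32), 99.0), size=16)
        assert out.shape == (17, 17)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_high_contrast_square_localized(self):
        img = np.full((32, 32), 100.0)
        img[12:20, 12:20] = 250.0
        cmap = maps.contrast_map(img, size=8, stride=1)
        i, j = np.unravel_index(np.argmax(cmap), cmap.shape)
        # window of the peak must overlap the square's border region
        assert 4 <= i <= 20 and 4 <= j <= 20
        assert cmap[0, 0] == 0.0

    def test_stride_16_paper_scale_geometry(self):
        assert maps.map_shape((2144, 1424), 16, 16) == (134, 89)

    def test_matches_brute_force(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        for stride in (1, 3):
            dense = maps.contrast_map(img, size=16, stride=stride)
            brute = brute_force_contrast_map(img, 16, stride)
            assert np.abs(dense - brute).max() < 1e-9

    def test_too_small_image(self):
        with pytest.raises(ValueError, match="smaller"):
            maps.contrast_map(np.zeros((8, 8)), size=16)


class TestLogTransform:
    @pytest.mark.parametrize("v,expected", [
        (0.0, 0.0), (1.0, 0.0), (np.e, 1.0),
    ])
    def test_piecewise_values(self, v, expected):
        assert maps.log_transform(np.array([v]))[0] == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            maps.log_transform(np.array([-1.0]))

    def test_output_finite_on_8bit_range(self):
        out = maps.log_transform(np.arange(256.0))
        assert np.all(np.isfinite(out))


class TestFilterResponses:
    def test_zero_vector_gives_dc_constant_only(self, small_bank):
        a = maps.filter_responses(np.zeros(64), small_bank)
        assert np.allclose(np.delete(a, small_bank.dc_index), 0.0)
        assert a[small_bank.dc_index] == small_bank.dc_constant

    def test_matched_filter_is_maximal_response(self, small_bank):
        k = int(small_bank.non_dc_indices()[0])
        a = maps.filter_responses(small_bank.filters[k].copy(), small_bank)
        assert a[k] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.abs(np.delete(a, small_bank.dc_index)) <= 1.0 + 1e-9)

    def test_linearity(self, small_bank, rng):
        x = rng.uniform(0, 5, 64)
        a1 = maps.filter_responses(x, small_bank)
        a2 = maps.filter_responses(2 * x, small_bank)
        non_dc = small_bank.non_dc_indices()
        assert np.allclose(a2[non_dc], 2 * a1[non_dc])

    def test_dimension_mismatch(self, small_bank):
        with pytest.raises(ValueError, match="dimensionality"):
            maps.filter_responses(np.zeros(256), small_bank)


class TestResponseKurtosis:
    def test_symmetric_binary_minimum(self):
        assert maps.response_kurtosis(np.tile([1.0, -1.0], 8)) == \
            pytest.approx(1.0, abs=1e-12)

    def test_gaussian_reference_value(self, rng):
        a = rng.standard_normal(100_000)
        assert maps.response_kurtosis(a) == pytest.approx(3.0, abs=0.1)

    def test_constant_vector_undefined(self):
        assert np.isnan(maps.response_kurtosis(np.full(16, 2.0)))

    def test_affine_invariance_with_dc_rescaled(self, rng):
        a = rng.standard_normal(64)
        k0 = maps.response_kurtosis(a)
        assert maps.response_kurtosis(3.5 * a + 1.2) == pytest.approx(k0, rel=1e-9)


class TestKurtosisMap:
    def test_valid_region_geometry(self, small_bank, rng):
        img = rng.uniform(1, 255, (20, 24))
        kmap = maps.kurtosis_map(img, small_bank, stride=1)
        assert kmap.shape == (13, 17)

    def test_matches_brute_force_at_random_positions(self, small_bank, rng):
        img = rng.uniform(1, 255, (64, 64))
        kmap = maps.kurtosis_map(img, small_bank, stride=1)
        s = small_bank.patch_size
        for _ in range(50):
            i = int(rng.integers(0, 64 - s + 1))
            j = int(rng.integers(0, 64 - s + 1))
            assert kmap[i, j] == pytest.approx(
                brute_force_kurtosis_at(img, small_bank, i, j), abs=1e-9)

    def test_low_frequency_grating_higher_kurtosis(self, natural_bank):
        k_low = maps.kurtosis_map(synth.make_grating(16, 0.06), natural_bank)
        k_high = maps.kurtosis_map(synth.make_grating(16, 0.38), natural_bank)
        assert k_low[0, 0] > k_high[0, 0]

    def test_grating_kurtosis_strictly_decreasing(self, natural_bank):
        ks = [maps.kurtosis_map(synth.make_grating(16, f), natural_bank)[0, 0]
              for f in GRATING_FREQS]
        assert all(ks[i] > ks[i + 1] for i in range(len(ks) - 1)), ks

    def test_piecewise_constant_region_higher_than_noise_region(
            self, natural_bank, rng):
        # road-like piecewise-constant region (flat areas + one step
        # edge) versus a white-noise texture region
        road = np.full((48, 48), 80.0)
        road[:, 24:] = 160.0
        noisy = rng.uniform(0, 255, (48, 48))
        k_road = maps.kurtosis_map(road, natural_bank, stride=8)
        k_noisy = maps.kurtosis_map(noisy, natural_bank, stride=8)
        assert k_road.mean() > k_noisy.mean()

    def test_degenerate_neighborhood_masked(self, small_bank):
        # zero luminance -> zero transformed vector -> zero responses
        kmap = maps.kurtosis_map(np.zeros((12, 12)), small_bank)
        assert kmap.mask.all()

    def test_size_mismatch_rejected(self, small_bank):
        with pytest.raises(ValueError, match="patch size"):
            maps.kurtosis_map(np.zeros((32, 32)), small_bank, size=16)
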