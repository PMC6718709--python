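"""Bubble-mask generation, combination, and application."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as npst
from scipy import stats

from bubblerc import (
    StimulusGeometry,
    apply_mask,
    combine_bubbles,
    frame_to_time,
    gaussian_bubble,
    sample_bubble_centers,
)
from bubblerc.masks import make_profile, spatial_profile, temporal_profiles
from bubblerc.masks import BubbleSpec


class TestGaussianBubble:
    def test_unit_height_at_center(self, geometry):
        b = gaussian_bubble(50, 3, geometry)
        assert b[49] == 1.0  # frame 50 is index 49
        assert b.max() == 1.0

    def test_one_sigma_falloff(self, geometry):
        b = gaussian_bubble(50, 3, geometry)
        assert b[52] == pytest.approx(np.exp(-0.5))  # frame 53, one sigma out

    def test_spatial_isotropy(self, small_geometry):
        b = gaussian_bubble((30, 20), 5, small_geometry)
        assert b[20, 38] == pytest.approx(b[28, 30])  # +8 px along x vs y
        assert b[20, 30] == 1.0

    def test_off_grid_center_peaks_at_nearest_point(self, geometry):
        b = gaussian_bubble(50.4, 3, geometry)
        assert b[49] == 1.0
        assert b.argmax() == 49

    @pytest.mark.parametrize("sigma", [0, -1.5])
    def test_invalid_sigma(self, sigma, geometry):
        with pytest.raises(ValueError, match="sigma"):
            gaussian_bubble(50, sigma, geometry)

    @pytest.mark.parametrize("center", [0.2, 97, (700, 10), (10, -1)])
    def test_center_outside_domain(self, center, geometry):
        with pytest.raises(ValueError, match="outside"):
            gaussian_bubble(center, 3, geometry)

    def test_integral_matches_continuous_gaussian(self, geometry):
        # far from edges the discrete sum approximates sigma * sqrt(2*pi)
        for center in [20, 50, 76.3]:
            b = gaussian_bubble(center, 3, geometry)
            assert b.sum() == pytest.approx(3 * np.sqrt(2 * np.pi), rel=0.01)


class TestCombineBubbles:
    def test_single_bubble_identity(self, geometry):
        g = gaussian_bubble(30, 3, geometry)
        assert np.array_equal(combine_bubbles([g]), g)

    def test_two_half_values(self):
        out = combine_bubbles([np.array([0.5]), np.array([0.5])])
        assert out[0] == pytest.approx(0.75)

    def test_full_bubble_absorbs(self, rng):
        others = [rng.random(10) for _ in range(3)]
        out = combine_bubbles(others + [np.ones(10)])
        assert np.all(out == 1.0)

    def test_empty_list_gives_zeros(self):
        out = combine_bubbles([], shape=(5,))
        assert np.array_equal(out, np.zeros(5))
        with pytest.raises(ValueError, match="shape"):
            combine_bubbles([])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            combine_bubbles([np.zeros(3), np.zeros(4)])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        npst.arrays(
            float,
            st.tuples(st.integers(1, 5), st.integers(2, 12)),
            elements=st.floats(0, 1),
        )
    )
    def test_bounded_permutation_invariant_zero_neutral(self, values):
        bubbles = list(values)
        out = combine_bubbles(bubbles)
        assert np.all((0 <= out) & (out <= 1))
        shuffled = combine_bubbles(bubbles[::-1])
        np.testing.assert_allclose(out, shuffled, atol=1e-12)
        with_zero = combine_bubbles(bubbles + [np.zeros_like(bubbles[0])])
        np.testing.assert_allclose(out, with_zero, atol=1e-12)

    def test_monotone_in_inputs(self, rng):
        a, b = rng.random((2, 20))
        base = combine_bubbles([a, b])
        bumped = combine_bubbles([np.minimum(a + 0.1, 1.0), b])
        assert np.all(bumped >= base)

    def test_unity_only_where_a_bubble_is_one(self, geometry):
        profile = make_profile(BubbleSpec(centers=(20.3, 60.0), sigma=3), geometry)
        ones = np.nonzero(profile == 1.0)[0]
        # each bubble peaks at exactly 1 at its nearest grid point, nowhere else
        assert list(ones) == [19, 59]


class TestSampleCenters:
    def test_zero_and_negative(self, geometry, rng):
        assert sample_bubble_centers(0, geometry, rng) == []
        with pytest.raises(ValueError):
            sample_bubble_centers(-1, geometry, rng)

    def test_deterministic_given_seed(self, geometry):
        a = sample_bubble_centers(50, geometry, np.random.default_rng(7))
        b = sample_bubble_centers(50, geometry, np.random.default_rng(7))
        assert a == b

    def test_temporal_uniformity_chi_square(self, geometry, rng):
        centers = np.asarray(sample_bubble_centers(100_000, geometry, rng))
        frames = np.clip(np.rint(centers), 1, geometry.n_frames).astype(int)
        counts = np.bincount(frames, minlength=97)[1:]
        assert stats.chisquare(counts).pvalue > 0.001

    def test_spatial_centers_in_bounds(self, small_geometry, rng):
        pts = sample_bubble_centers(1000, small_geometry, rng, domain="spatial")
        x, y = np.array(pts).T
        assert x.min() >= 0 and x.max() < small_geometry.width
        assert y.min() >= 0 and y.max() < small_geometry.height


class TestApplyMask:
    def test_full_mask_uniform_gray(self, rng):
        frame = rng.uniform(0, 255, (10, 12))
        out = apply_mask(frame, np.zeros_like(frame), mean_intensity=128)
        assert np.all(out == 128)

    def test_no_mask_identity(self, rng):
        frame = rng.uniform(0, 255, (10, 12))
        np.testing.assert_allclose(apply_mask(frame, np.ones_like(frame)), frame)

    def test_half_mask_value(self):
        out = apply_mask(np.array([[200.0]]), np.array([[0.5]]), mean_intensity=128)
        assert out[0, 0] == pytest.approx(164.0)

    def test_weber_contrast_scaling(self, rng):
        frame = rng.uniform(10, 240, (8, 9))
        mask = rng.random((8, 9))
        mean = 100.0
        out = apply_mask(frame, mask, mean_intensity=mean)
        np.testing.assert_allclose(
            (out - mean) / mean, mask * (frame - mean) / mean
        )

    def test_uint8_export(self):
        out = apply_mask(
            np.array([[200.4]]), np.array([[1.0]]), mean_intensity=128,
            as_uint8=True,
        )
        assert out.dtype == np.uint8 and out[0, 0] == 200

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            apply_mask(np.zeros((2, 2)), np.zeros((3, 2)))


class TestFrameToTime:
    def test_default_geometry_mapping(self, geometry):
        assert frame_to_time(86, geometry) == pytest.approx(10 / 120)
        assert frame_to_time(96, geometry) == 0.0
        assert frame_to_time(1, geometry) == pytest.approx(95 / 120)

    def test_out_of_range(self, geometry):
        for k in (0, 97):
            with pytest.raises(ValueError):
                frame_to_time(k, geometry)


class TestVectorizedProfiles:
    def test_matches_per_trial_construction(self, geometry, rng):
        centers = rng.uniform(0.5, 96.5, (5, 4))
        block = temporal_profiles(centers, 3.0, geometry)
        for t in range(5):
            single = make_profile(BubbleSpec(centers=tuple(centers[t]), sigma=3.0),
                                  geometry)
            np.testing.assert_array_equal(block[t], single)

    def test_spatial_matches_combine(self, small_geometry, rng):
        centers = [(10.5, 20.0), (40.0, 5.5)]
        prof = spatial_profile(centers, 4.0, small_geometry)
        manual = combine_bubbles(
            [gaussian_bubble(c, 4.0, small_geometry) for c in centers]
        )
        np.testing.assert_allclose(prof, manual)
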