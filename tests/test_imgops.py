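"""Morphological primitives against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from colonyquant import imgops
from colonyquant.imgops import (
    BinaryMask,
    GrayImage,
    LabelMap,
    ParameterError,
    binarize,
    contrast_adjust,
    distance_transform,
    extended_maxima,
    gaussian_smooth,
    hminima_suppress,
    tophat_filter,
    watershed_segment,
)
from oracle_utils import (
    brute_distance_transform,
    brute_tophat,
    count_regional_minima,
    geodesic_hminima,
)


def gi(arr, pitch=2.692):
    return GrayImage(np.asarray(arr, dtype=float), pitch)


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


# ---------------------------------------------------------------------------
# domain types

class TestTypes:
    def test_grayimage_rejects_bad_inputs(self):
        with pytest.raises(ParameterError):
            GrayImage(np.zeros((3,)))
        with pytest.raises(ParameterError):
            GrayImage(np.array([[np.nan, 1.0]]))
        with pytest.raises(ParameterError):
            GrayImage(np.zeros((2, 2)), pixel_pitch_um=0)

    def test_binarymask_requires_01(self):
        with pytest.raises(ParameterError):
            BinaryMask(np.array([[0, 2]]))
        m = BinaryMask(np.array([[0, 1], [1, 0]]))
        assert m.foreground_count == 2

    def test_labelmap_requires_contiguous_labels(self):
        with pytest.raises(ParameterError):
            LabelMap(np.array([[0, 2], [0, 0]]))
        lm = LabelMap(np.array([[0, 1], [2, 2]]))
        assert lm.n_labels == 2
        assert lm.areas().tolist() == [1, 2]

    def test_pixel_area_follows_pitch(self):
        assert GrayImage(np.zeros((2, 2)), 2.0).pixel_area_um2 == pytest.approx(4.0)


# ---------------------------------------------------------------------------
# tophat

class TestTophat:
    def test_constant_image_maps_to_zero(self):
        out = tophat_filter(gi(np.full((16, 16), 0.7)), 3)
        assert np.allclose(out.pixels, 0.0)

    def test_ramp_plus_disk_matches_brute_force(self):
        rng = np.random.default_rng(0)
        yy, xx = np.mgrid[:64, :64]
        img = 0.3 * (xx / 63.0)  # linear ramp
        img[disk_mask((64, 64), (32, 32), 3)] += 0.5
        out = tophat_filter(gi(img), 10)
        expected = brute_tophat(img, 10)
        assert np.allclose(out.pixels, np.maximum(expected, 0), atol=1e-12)
        # ramp removed, disk peak retained
        assert out.pixels[32, 32] == pytest.approx(0.5, abs=0.02)
        assert out.pixels[5, 60] < 0.05

    def test_isolated_pixel_survives(self):
        img = np.zeros((21, 21))
        img[10, 10] = 1.0
        out = tophat_filter(gi(img), 5)
        assert out.pixels[10, 10] == pytest.approx(1.0)

    def test_bounded_by_input_and_nonnegative(self):
        rng = np.random.default_rng(1)
        img = rng.random((32, 32))
        out = tophat_filter(gi(img), 4)
        assert (out.pixels >= 0).all()
        assert (out.pixels <= img + 1e-12).all()

    def test_bad_radius_raises(self):
        with pytest.raises(ParameterError):
            tophat_filter(gi(np.zeros((4, 4))), 0)


# ---------------------------------------------------------------------------
# gaussian

class TestGaussian:
    def test_sigma_zero_is_identity(self):
        img = np.random.default_rng(2).random((16, 16))
        assert np.array_equal(gaussian_smooth(gi(img), 0).pixels, img)

    def test_delta_gives_centered_kernel(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        out = gaussian_smooth(gi(img), 2.0).pixels
        yy, xx = np.mgrid[:33, :33]
        kernel = np.exp(-((yy - 16) ** 2 + (xx - 16) ** 2) / 8.0)
        kernel /= kernel.sum()
        assert np.allclose(out, kernel, atol=1e-4)

    def test_constant_preserved(self):
        out = gaussian_smooth(gi(np.full((12, 12), 0.4)), 3.0).pixels
        assert np.allclose(out, 0.4)

    def test_negative_sigma_raises(self):
        with pytest.raises(ParameterError):
            gaussian_smooth(gi(np.zeros((4, 4))), -1.0)


# ---------------------------------------------------------------------------
# contrast / binarize

class TestContrastBinarize:
    def test_full_range_identity(self):
        img = np.linspace(0, 1, 25).reshape(5, 5)
        out = contrast_adjust(gi(img), 0, 100).pixels
        assert np.allclose(out, img)

    def test_four_level_linear_map(self):
        img = np.array([[10.0, 20.0], [30.0, 40.0]])
        out = contrast_adjust(gi(img), 0, 100).pixels
        assert np.allclose(out, [[0.0, 1 / 3], [2 / 3, 1.0]])

    def test_constant_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            out = contrast_adjust(gi(np.full((4, 4), 2.0)), 1, 99).pixels
        assert np.allclose(out, 0.0)

    def test_bad_percentiles_raise(self):
        with pytest.raises(ParameterError):
            contrast_adjust(gi(np.zeros((4, 4))), 50, 50)

    def test_binarize_all_zero(self):
        assert binarize(gi(np.zeros((4, 4))), "fixed", 0.5).foreground_count == 0

    def test_otsu_separates_two_levels(self):
        img = np.where(np.random.default_rng(3).random((20, 20)) < 0.4, 0.1, 0.9)
        mask = binarize(gi(img), "otsu").pixels
        assert np.array_equal(mask, img == 0.9)

    def test_otsu_constant_warns_empty(self):
        with pytest.warns(UserWarning):
            mask = binarize(gi(np.full((6, 6), 0.3)), "otsu")
        assert mask.foreground_count == 0

    def test_fixed_threshold(self):
        img = np.array([[0.4, 0.6]])
        assert binarize(gi(img), "fixed", 0.5).pixels.tolist() == [[False, True]]

    def test_fixed_threshold_out_of_range_raises(self):
        with pytest.raises(ParameterError):
            binarize(gi(np.zeros((2, 2))), "fixed", 1.5)


# ---------------------------------------------------------------------------
# distance transform

class TestDistanceTransform:
    def test_all_background_is_zero(self):
        out = distance_transform(BinaryMask(np.zeros((8, 8), dtype=bool)))
        assert np.allclose(out.pixels, 0.0)

    def test_single_pixel_is_one(self):
        m = np.zeros((7, 7), dtype=bool)
        m[3, 3] = True
        assert distance_transform(BinaryMask(m)).pixels[3, 3] == pytest.approx(1.0)

    def test_random_masks_match_brute_force_exhaustively(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            h, w = rng.integers(2, 17, size=2)
            mask = rng.random((h, w)) < rng.uniform(0.2, 0.8)
            if mask.all():  # keep at least one background pixel
                mask[0, 0] = False
            got = distance_transform(BinaryMask(mask)).pixels
            want = brute_distance_transform(mask)
            assert np.allclose(got, want, atol=1e-9)


# ---------------------------------------------------------------------------
# h-minima / extended maxima

class TestHMinima:
    def test_h_zero_identity(self):
        img = np.random.default_rng(4).random((10, 10))
        assert np.array_equal(hminima_suppress(gi(img), 0).pixels, img)

    def test_1d_profile_fills_shallow_keeps_deep(self):
        profile = np.array([[5.0, 1.0, 5.0, 4.0, 5.0]])
        out = hminima_suppress(gi(profile), 2.0).pixels
        want = geodesic_hminima(profile, 2.0)
        assert np.allclose(out, want)
        # the depth-4 minimum survives as a regional minimum, the
        # depth-1 minimum is filled flat
        assert out[0, 3] == pytest.approx(5.0)
        assert out[0, 1] < out[0, 0]

    def test_matches_geodesic_oracle_on_random_images(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            img = rng.random((12, 12))
            h = rng.uniform(0.05, 0.5)
            assert np.allclose(
                hminima_suppress(gi(img), h).pixels, geodesic_hminima(img, h), atol=1e-12
            )

    def test_pointwise_geq_and_shallow_minima_removed(self):
        img = np.random.default_rng(6).random((15, 15))
        once = hminima_suppress(gi(img), 0.3)
        assert (once.pixels >= img - 1e-12).all()
        # every suppression is itself a fixed point of the oracle at h=0
        assert np.allclose(once.pixels, geodesic_hminima(once.pixels, 0.0))
        assert count_regional_minima(once.pixels) <= count_regional_minima(img)

    def test_minima_count_nonincreasing_in_h(self):
        rng = np.random.default_rng(8)
        img = rng.random((14, 14))
        counts = [
            count_regional_minima(hminima_suppress(gi(img), h).pixels)
            for h in (0.0, 0.1, 0.2, 0.4, 0.8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_negative_h_raises(self):
        with pytest.raises(ParameterError):
            hminima_suppress(gi(np.zeros((3, 3))), -0.1)


class TestExtendedMaxima:
    def test_constant_has_no_maxima(self):
        assert extended_maxima(gi(np.full((9, 9), 0.5)), 1.0).foreground_count == 0

    def test_only_tall_peak_marked(self):
        yy, xx = np.mgrid[:40, :80]
        img = 10.0 * np.exp(-((yy - 20) ** 2 + (xx - 20) ** 2) / 18.0)
        img += 3.0 * np.exp(-((yy - 20) ** 2 + (xx - 60) ** 2) / 18.0)
        mask = extended_maxima(gi(img), 5.0).pixels
        assert mask[20, 20]
        assert not mask[:, 40:].any()

    def test_shift_invariance(self):
        rng = np.random.default_rng(9)
        img = rng.random((12, 12))
        a = extended_maxima(gi(img), 0.3).pixels
        b = extended_maxima(gi(img + 5.0), 0.3).pixels
        assert np.array_equal(a, b)

    def test_nonpositive_h_raises(self):
        with pytest.raises(ParameterError):
            extended_maxima(gi(np.zeros((3, 3))), 0.0)


# ---------------------------------------------------------------------------
# watershed

class TestWatershed:
    def test_empty_domain(self):
        out = watershed_segment(
            gi(np.zeros((6, 6))), BinaryMask(np.zeros((6, 6), dtype=bool))
        )
        assert out.n_labels == 0

    def test_disjoint_disks_get_one_label_each(self):
        dom = disk_mask((60, 120), (30, 30), 15) | disk_mask((60, 120), (30, 90), 15)
        dist = distance_transform(BinaryMask(dom))
        relief = gi(dist.pixels.max() - dist.pixels)
        labels = watershed_segment(relief, BinaryMask(dom))
        assert labels.n_labels == 2
        assert len(np.unique(labels.pixels[disk_mask((60, 120), (30, 30), 15)])) == 1

    def test_overlapping_disks_split_near_equidistance(self):
        dom = disk_mask((80, 100), (40, 35), 20) | disk_mask((80, 100), (40, 65), 20)
        dist = distance_transform(BinaryMask(dom))
        relief = gi(dist.pixels.max() - dist.pixels)
        labels = watershed_segment(relief, BinaryMask(dom))
        assert labels.n_labels == 2
        # each pixel belongs to the nearer disk center, +/- 1 px at the ridge
        yy, xx = np.mgrid[:80, :100]
        nearer_left = np.hypot(yy - 40, xx - 35) < np.hypot(yy - 40, xx - 65)
        left_label = labels.pixels[40, 35]
        interior = dom & (np.abs(np.hypot(yy - 40, xx - 35) - np.hypot(yy - 40, xx - 65)) > 1.5)
        assert ((labels.pixels == left_label) == nearer_left)[interior].all()

    def test_labels_partition_domain(self):
        rng = np.random.default_rng(11)
        dom = rng.random((40, 40)) < 0.45
        relief = gi(rng.random((40, 40)))
        labels = watershed_segment(relief, BinaryMask(dom))
        assert int((labels.pixels > 0).sum()) == int(dom.sum())
        assert labels.areas().sum() == dom.sum()
        assert not labels.pixels[~dom].any()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ParameterError):
            watershed_segment(gi(np.zeros((4, 4))), BinaryMask(np.zeros((5, 5), dtype=bool)))


# ---------------------------------------------------------------------------
# determinism / hypothesis properties

@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    arrays(
        np.float64,
        (8, 8),
        elements=st.floats(0, 1, allow_nan=False, width=16),
    ),
    st.floats(0.01, 0.9),
)
def test_hminima_output_dominates_input(img, h):
    out = hminima_suppress(gi(img), h).pixels
    assert (out >= img - 1e-12).all()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    arrays(np.float64, (10, 10), elements=st.floats(0, 1, allow_nan=False, width=16))
)
def test_operators_are_deterministic(img):
    a = tophat_filter(gi(img), 2).pixels
    b = tophat_filter(gi(img.copy()), 2).pixels
    assert np.array_equal(a, b)
    c = gaussian_smooth(gi(img), 1.3).pixels
    d = gaussian_smooth(gi(img.copy()), 1.3).pixels
    assert np.array_equal(c, d)
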