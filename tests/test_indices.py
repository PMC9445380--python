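"""Unit tests for the scoring math: HSV conversion, classification, indices,
GVI/EGVI aggregation and region scoring."""

import numpy as np
import pytest

from greenview import (
    CoRegistrationError,
    GreenMask,
    HSVThreshold,
    IndexMap,
    NIRImage,
    RegionOfInterest,
    RGBImage,
    classify_green,
    compute_egvi,
    compute_gvi,
    compute_ndvi,
    compute_vari,
    mean_index_over_mask,
    rgb_to_hsv,
    score_region,
    score_scene,
)


def one_pixel(r, g, b):
    return RGBImage(np.array([[r]]), np.array([[g]]), np.array([[b]]))


class TestRgbToHsv:
    @pytest.mark.parametrize(
        "rgb, expected_hsv",
        [
            ((0.0, 1.0, 0.0), (120.0, 1.0, 1.0)),  # pure green hexcone corner
            ((0.5, 0.5, 0.5), (0.0, 0.0, 0.5)),    # achromatic: H defined as 0
            ((1.0, 0.0, 0.0), (0.0, 1.0, 1.0)),    # pure red corner
            ((0.0, 0.0, 1.0), (240.0, 1.0, 1.0)),
            ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),    # black
        ],
    )
    def test_hexcone_corners_and_achromatic(self, rgb, expected_hsv):
        h, s, v = rgb_to_hsv(one_pixel(*rgb))
        assert (h[0, 0], s[0, 0], v[0, 0]) == pytest.approx(expected_hsv, abs=1e-12)

    def test_ranges(self, rng):
        img = RGBImage(rng.random((20, 20)), rng.random((20, 20)), rng.random((20, 20)))
        h, s, v = rgb_to_hsv(img)
        assert h.min() >= 0 and h.max() < 360
        assert s.min() >= 0 and s.max() <= 1
        assert v.min() >= 0 and v.max() <= 1


class TestClassifyGreen:
    def test_pure_green_is_green(self):
        mask = classify_green(one_pixel(0, 1, 0))
        assert mask.n_green == 1

    def test_gray_is_not_green(self):
        # saturation 0 can never pass saturation_min
        mask = classify_green(one_pixel(0.5, 0.5, 0.5))
        assert mask.n_green == 0

    def test_red_is_not_green(self):
        assert classify_green(one_pixel(1, 0, 0)).n_green == 0

    def test_counts_on_worked_example_scene(self, location1):
        bundle, _ = location1
        mask = classify_green(bundle.rgb)
        assert (mask.n_green, mask.n_total) == (26, 165)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            HSVThreshold(hue_min=200, hue_max=100)
        with pytest.raises(ValueError):
            HSVThreshold(saturation_min=1.5)

    def test_custom_band_excludes_out_of_band_hue(self):
        # cyan-ish pixel at H=180 excluded by a narrow band
        narrow = HSVThreshold(hue_min=90, hue_max=150)
        assert classify_green(one_pixel(0, 1, 1), narrow).n_green == 0


class TestIndexMaps:
    def test_ndvi_values(self):
        img = one_pixel(0.05, 0.5, 0.1)
        ndvi = compute_ndvi(NIRImage(np.array([[0.95]])), img)
        assert ndvi.values[0, 0] == pytest.approx(0.9)
        assert ndvi.valid[0, 0]

    def test_ndvi_symmetric_is_zero(self):
        ndvi = compute_ndvi(NIRImage(np.array([[0.3]])), one_pixel(0.3, 0.1, 0.1))
        assert ndvi.values[0, 0] == 0.0

    def test_ndvi_zero_denominator_invalid(self):
        ndvi = compute_ndvi(NIRImage(np.array([[0.0]])), one_pixel(0.0, 0.2, 0.2))
        assert not ndvi.valid[0, 0]

    def test_ndvi_bounded_where_valid(self, rng):
        h = w = 15
        img = RGBImage(rng.random((h, w)), rng.random((h, w)), rng.random((h, w)))
        ndvi = compute_ndvi(NIRImage(rng.random((h, w))), img)
        vals = ndvi.values[ndvi.valid]
        assert vals.min() >= -1 and vals.max() <= 1

    def test_ndvi_dimension_mismatch(self):
        with pytest.raises(CoRegistrationError):
            compute_ndvi(NIRImage(np.zeros((2, 2))), one_pixel(0.1, 0.2, 0.3))

    def test_vari_values(self):
        vari = compute_vari(one_pixel(0.4, 0.8, 0.4))
        assert vari.values[0, 0] == pytest.approx(0.5)

    def test_vari_zero_numerator(self):
        vari = compute_vari(one_pixel(0.3, 0.3, 0.2))
        assert vari.values[0, 0] == 0.0

    def test_vari_zero_denominator_invalid(self):
        # B = G + R makes the denominator vanish
        vari = compute_vari(one_pixel(0.2, 0.3, 0.5))
        assert not vari.valid[0, 0]

    def test_vari_can_exceed_unity(self):
        vari = compute_vari(one_pixel(0.1, 0.5, 0.5))
        assert vari.values[0, 0] > 1.0


class TestGvi:
    def test_worked_example_fraction(self):
        m = np.zeros((15, 11), dtype=bool)
        m.flat[:26] = True
        assert compute_gvi(GreenMask(m)) == pytest.approx(100 * 26 / 165)

    def test_all_green_is_100(self):
        assert compute_gvi(GreenMask(np.ones((4, 4), dtype=bool))) == 100.0

    def test_empty_mask_is_0(self):
        assert compute_gvi(GreenMask(np.zeros((4, 4), dtype=bool))) == 0.0


class TestMeanIndexOverMask:
    def uniform(self, value, shape=(2, 13)):
        return IndexMap(np.full(shape, value), np.ones(shape, dtype=bool), "NDVI")

    def test_uniform_index_over_green(self):
        mask = GreenMask(np.ones((2, 13), dtype=bool))
        mean, n = mean_index_over_mask(self.uniform(0.9), mask)
        assert (mean, n) == (pytest.approx(0.9), 26)

    def test_clamp_clips_negatives_before_averaging(self):
        values = np.array([[-0.5, 0.5]])
        idx = IndexMap(values, np.ones_like(values, dtype=bool), "NDVI")
        mask = GreenMask(np.ones((1, 2), dtype=bool))
        mean, n = mean_index_over_mask(idx, mask, clamp=True)
        assert mean == pytest.approx(0.25)  # mean of {0, 0.5}
        raw, _ = mean_index_over_mask(idx, mask, clamp=False)
        assert raw == pytest.approx(0.0)

    def test_invalid_pixels_excluded(self):
        values = np.array([[0.8, 123.0]])
        idx = IndexMap(values, np.array([[True, False]]), "NDVI")
        mask = GreenMask(np.ones((1, 2), dtype=bool))
        mean, n = mean_index_over_mask(idx, mask)
        assert (mean, n) == (pytest.approx(0.8), 1)

    def test_empty_support_gives_zero(self):
        mask = GreenMask(np.zeros((2, 13), dtype=bool))
        assert mean_index_over_mask(self.uniform(0.9), mask) == (0.0, 0)


class TestComputeEgvi:
    def scores(self, index_value, n_green=26, shape=(15, 11)):
        m = np.zeros(shape, dtype=bool)
        m.flat[:n_green] = True
        idx = IndexMap(np.full(shape, index_value), np.ones(shape, dtype=bool), "NDVI")
        return compute_egvi(GreenMask(m), idx)

    def test_location1_arithmetic(self):
        s = self.scores(0.9)
        assert s.egvi == pytest.approx(26 * 0.9 / 165 * 100)
        assert s.egvi == pytest.approx(s.gvi * s.mean_index)

    def test_location2_arithmetic(self):
        assert self.scores(0.4).egvi == pytest.approx(26 * 0.4 / 165 * 100)

    def test_unit_index_gives_egvi_equal_gvi(self):
        s = self.scores(1.0)
        assert s.egvi == s.gvi

    def test_empty_greenery_gives_zero(self):
        s = self.scores(0.9, n_green=0)
        assert s.egvi == 0.0 and s.gvi == 0.0 and s.n_aggregated == 0

    def test_no_index_scores_fraction_only(self):
        m = np.zeros((5, 5), dtype=bool)
        m[0] = True
        s = compute_egvi(GreenMask(m), None)
        assert s.index_kind == "none" and s.egvi == s.gvi == 20.0

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            compute_egvi(GreenMask(np.zeros((0, 0), dtype=bool)), None)


class TestScoreRegion:
    def test_full_frame_equals_whole_scene(self, location1):
        bundle, _ = location1
        whole = score_scene(bundle.rgb, bundle.nir)
        roi = RegionOfInterest.full_frame(bundle.rgb.height, bundle.rgb.width)
        assert score_region(bundle.rgb, bundle.nir, roi) == whole

    def test_all_green_roi(self, location1):
        # crown row 4 spans cols 2..8 of green at index 0.9
        bundle, _ = location1
        roi = RegionOfInterest(4, 5, 2, 9)
        s = score_region(bundle.rgb, bundle.nir, roi)
        assert s.gvi == 100.0
        assert s.egvi == pytest.approx(90.0)

    def test_background_only_roi(self, location1):
        bundle, _ = location1
        s = score_region(bundle.rgb, bundle.nir, RegionOfInterest(0, 2, 0, 11))
        assert s.gvi == 0.0 and s.egvi == 0.0

    def test_roi_out_of_bounds(self, location1):
        bundle, _ = location1
        with pytest.raises(ValueError):
            score_region(bundle.rgb, bundle.nir, RegionOfInterest(0, 99, 0, 5))

    def test_ndvi_without_nir_rejected(self, location1):
        bundle, _ = location1
        with pytest.raises(ValueError, match="NIR"):
            score_scene(bundle.rgb, None, index_kind="NDVI")

    def test_vari_needs_no_nir(self, location1):
        bundle, _ = location1
        s = score_scene(bundle.rgb, None, index_kind="VARI")
        assert s.index_kind == "VARI" and s.n_green == 26


class TestDomainTypeInvariants:
    def test_rgb_plane_shape_mismatch(self):
        with pytest.raises(CoRegistrationError):
            RGBImage(np.zeros((2, 2)), np.zeros((2, 3)), np.zeros((2, 2)))

    def test_rgb_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            RGBImage(np.full((2, 2), 1.5), np.zeros((2, 2)), np.zeros((2, 2)))

    def test_nir_non_finite_rejected(self):
        with pytest.raises(ValueError):
            NIRImage(np.array([[np.nan]]))

    def test_mask_counts(self, rng):
        m = rng.random((7, 9)) > 0.5
        gm = GreenMask(m)
        assert gm.n_green == int(m.sum()) and gm.n_total == 63

    def test_degenerate_roi_rejected(self):
        with pytest.raises(ValueError):
            RegionOfInterest(3, 3, 0, 5)
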