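import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bandstraight.lane import DimensionError, LaneGeometry
from bandstraight.preprocess import (
    apply_artifact_mask,
    compute_wmax,
    crop_margins,
    rectify_lane,
    rgb_to_gray,
)


class TestRgbToGray:
    @pytest.mark.parametrize(
        "rgb, expected",
        [
            ((255, 255, 255), 255.0),
            ((0, 0, 0), 0.0),
            ((100, 200, 50), 136.0),  # 16 + 104 + 16
        ],
    )
    def test_pixel_values(self, rgb, expected):
        img = np.array(rgb, dtype=float).reshape(1, 1, 3)
        assert rgb_to_gray(img)[0, 0] == pytest.approx(expected)

    def test_rejects_non_rgb(self):
        with pytest.raises(DimensionError):
            rgb_to_gray(np.zeros((4, 4)))
        with pytest.raises(DimensionError):
            rgb_to_gray(np.zeros((4, 4, 4)))

    @settings(max_examples=50, derandomize=True)
    @given(
        st.tuples(*[st.integers(0, 255)] * 3),
        st.integers(0, 2),
        st.integers(1, 255),
    )
    def test_monotone_in_each_channel(self, rgb, channel, bump):
        """Increasing any channel never decreases the grayscale value."""
        lo = np.array(rgb, dtype=float).reshape(1, 1, 3)
        hi = lo.copy()
        hi[0, 0, channel] = min(255.0, hi[0, 0, channel] + bump)
        assert rgb_to_gray(hi)[0, 0] >= rgb_to_gray(lo)[0, 0]

    def test_range_preserved(self, rng):
        img = rng.uniform(0, 255, (8, 8, 3))
        g = rgb_to_gray(img)
        assert g.min() >= 0 and g.max() <= 255


class TestCropMargins:
    def test_default_crop_at_600dpi(self):
        img = np.arange(2380 * 3, dtype=float).reshape(2380, 3)
        out = crop_margins(img)
        assert out.shape == (1775, 3)
        np.testing.assert_array_equal(out, img[505:2280])

    def test_zero_crop_is_identity(self, rng):
        img = rng.uniform(size=(20, 5))
        np.testing.assert_array_equal(crop_margins(img, 0, 0), img)

    def test_too_small_image_raises(self):
        with pytest.raises(DimensionError):
            crop_margins(np.zeros((500, 3)))

    def test_dpi_scaling_doubles_at_1200(self):
        img = np.zeros((5000, 2))
        assert crop_margins(img, dpi=1200).shape[0] == 5000 - 2 * 505 - 2 * 100


class TestGeometry:
    def test_wmax_is_max_row_width(self):
        geo = LaneGeometry([0, 1, 0], [20, 19, 19], 0, 2)
        assert compute_wmax(geo) == 20

    def test_wmax_single_and_constant(self):
        assert compute_wmax(LaneGeometry([3], [10], 0, 5)) == 7
        assert compute_wmax(LaneGeometry([0] * 4, [20] * 4, 0, 3)) == 20

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            LaneGeometry([5], [5], 0, 1)
        with pytest.raises(ValueError):
            LaneGeometry([0], [5], 3, 2)

    def test_roundtrip_file(self, tmp_path):
        geo = LaneGeometry([0.5, 1.5], [10.0, 11.0], 0, 1)
        path = tmp_path / "geo.csv"
        geo.save(path)
        back = LaneGeometry.load(path)
        np.testing.assert_allclose(back.left_edge, geo.left_edge)
        np.testing.assert_allclose(back.right_edge, geo.right_edge)
        assert (back.roi_top, back.roi_bottom) == (0, 1)


class TestRectifyLane:
    def test_constant_edges_copy_unchanged(self, rng):
        img = rng.uniform(0, 255, (10, 30))
        geo = LaneGeometry([5] * 10, [25] * 10, 0, 9)
        lane = rectify_lane(img, geo)
        assert lane.shape == (10, 20)
        assert not lane.missing.any()
        np.testing.assert_allclose(lane.intensity, img[:, 5:25])

    def test_narrow_row_gets_missing_borders(self, rng):
        img = rng.uniform(0, 255, (5, 30))
        left = [5, 5, 6, 5, 5]
        right = [25, 25, 24, 25, 25]  # row 2 is 2 px narrower
        lane = rectify_lane(img, LaneGeometry(left, right, 0, 4))
        assert lane.missing[2].sum() == 2
        assert lane.missing[0].sum() == 0

    def test_row_valid_count_equals_width(self, rng):
        """Non-missing pixels per rectified row = xright - xleft."""
        img = rng.uniform(0, 255, (8, 40))
        left = np.array([4, 5, 6, 7, 8, 7, 6, 5])
        right = left + np.array([20, 18, 16, 20, 19, 17, 20, 18])
        lane = rectify_lane(img, LaneGeometry(left, right, 0, 7))
        np.testing.assert_array_equal(
            (~lane.missing).sum(axis=1), right - left
        )

    def test_midline_offset_translates_content(self, rng):
        """A +3 px midline offset shifts that row's content by -3 px."""
        img = rng.uniform(0, 255, (3, 40))
        left = [10, 13, 10]
        right = [30, 33, 30]  # row 1 midline shifted +3
        lane = rectify_lane(img, LaneGeometry(left, right, 0, 2))
        np.testing.assert_allclose(lane.intensity[0], img[0, 10:30])
        np.testing.assert_allclose(lane.intensity[1], img[1, 13:33])

    def test_roi_rows_dropped(self, rng):
        img = rng.uniform(0, 255, (10, 30))
        geo = LaneGeometry([5] * 10, [25] * 10, 2, 7)
        lane = rectify_lane(img, geo)
        assert lane.height == 6
        np.testing.assert_allclose(lane.intensity[0], img[2, 5:25])

    def test_row_mismatch_raises(self):
        with pytest.raises(DimensionError):
            rectify_lane(np.zeros((5, 10)), LaneGeometry([0] * 4, [5] * 4, 0, 3))

    def test_intensity_preserved_for_integer_shifts(self, rng):
        """Integer translations incur no resampling loss."""
        img = rng.uniform(0, 255, (4, 50))
        left = np.array([10, 12, 8, 10])
        right = left + 20
        lane = rectify_lane(img, LaneGeometry(left, right, 0, 3))
        for y in range(4):
            row = lane.intensity[y][~lane.missing[y]]
            np.testing.assert_allclose(row, img[y, left[y]:right[y]])


class TestArtifactMask:
    def test_all_false_is_identity(self, rng):
        from bandstraight.lane import LaneImage

        lane = LaneImage(rng.uniform(size=(6, 6)))
        out = apply_artifact_mask(lane, np.zeros((6, 6), bool))
        np.testing.assert_array_equal(out.missing, lane.missing)
        np.testing.assert_array_equal(out.intensity, lane.intensity)

    def test_disk_mask_exact_and_idempotent(self, rng):
        from bandstraight.lane import LaneImage

        lane = LaneImage(rng.uniform(size=(20, 20)))
        ys, xs = np.mgrid[0:20, 0:20]
        disk = (ys - 10) ** 2 + (xs - 10) ** 2 <= 25
        once = apply_artifact_mask(lane, disk)
        np.testing.assert_array_equal(once.missing, disk)
        twice = apply_artifact_mask(once, disk)
        np.testing.assert_array_equal(twice.missing, once.missing)

    def test_shape_mismatch_raises(self, rng):
        from bandstraight.lane import LaneImage

        lane = LaneImage(rng.uniform(size=(6, 6)))
        with pytest.raises(DimensionError):
            apply_artifact_mask(lane, np.zeros((5, 6), bool))
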