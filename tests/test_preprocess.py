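import numpy as np
import pytest
from scipy import ndimage

from exm_ruler import (
    ImageStack,
    SegmentationError,
    estimate_rotation,
    rescale_intensity,
    rotate_stack,
    segment_cube,
    select_analysis_planes,
    smooth_median,
)
from exm_ruler.preprocess import CubeMask


def _stack_of(plane: np.ndarray, n: int = 2, **sizes) -> ImageStack:
    sizes = {"dx": 0.1, "dy": 0.1, "dz": 0.3, **sizes}
    return ImageStack(np.stack([plane] * n), **sizes)


class TestEstimateRotation:
    def test_identity(self, square_plane):
        m = square_plane > 100
        assert estimate_rotation(m, m) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("theta", [10.0, -25.0, 30.0])
    def test_recovers_rotation_of_square(self, square_plane, theta):
        """Rotating the fiducial by +theta must be undone by -theta; checked
        against an exhaustive overlap-maximization oracle."""
        pre = square_plane > 100
        post_img = ndimage.rotate(square_plane.astype(float), theta, reshape=False, order=0)
        post = post_img > 100
        est = estimate_rotation(pre, post)
        assert est == pytest.approx(-theta, abs=1.0)
        # oracle: the angle maximizing mask overlap after rotating post back
        angles = np.arange(-40.0, 40.0, 0.5)
        overlaps = [
            np.sum(
                (ndimage.rotate(post.astype(float), a, reshape=False, order=0) > 0.5) & pre
            )
            for a in angles
        ]
        best = angles[int(np.argmax(overlaps))]
        assert est == pytest.approx(best, abs=1.0)

    @pytest.mark.parametrize("theta", [10.0, -25.0])
    def test_recovers_rotation_of_rectangle(self, theta):
        """Elongated fiducials exercise the moment-orientation path."""
        p = np.zeros((121, 121), np.uint16)
        p[40:80, 25:95] = 200
        post = ndimage.rotate(p.astype(float), theta, reshape=False, order=0) > 100
        assert estimate_rotation(p > 100, post) == pytest.approx(-theta, abs=1.0)

    def test_square_vs_diamond_is_45_with_positive_tie(self, square_plane):
        yy, xx = np.mgrid[0:121, 0:121]
        diamond = (np.abs(yy - 60) + np.abs(xx - 60)) <= 35
        est = estimate_rotation(square_plane > 100, diamond)
        assert abs(est) == pytest.approx(45.0, abs=0.5)
        assert est > 0  # the +/-45 tie resolves to +45

    def test_empty_mask_raises(self, square_plane):
        with pytest.raises(SegmentationError, match="empty"):
            estimate_rotation(square_plane > 100, np.zeros((121, 121), bool))

    def test_tiny_component_raises(self, square_plane):
        tiny = np.zeros((121, 121), bool)
        tiny[60:62, 60:62] = True
        with pytest.raises(SegmentationError, match="too small"):
            estimate_rotation(square_plane > 100, tiny)


class TestRotateStack:
    def test_zero_angle_is_identity(self, square_plane):
        s = _stack_of(square_plane)
        assert np.array_equal(rotate_stack(s, 0.0).voxels, s.voxels)

    def test_ninety_degrees_matches_permutation(self, square_plane):
        s = _stack_of(square_plane)
        r = rotate_stack(s, 90.0)
        exact = np.rot90(square_plane)
        assert np.abs(r.voxels[0].astype(int) - exact.astype(int)).max() <= 1

    def test_rotation_roundtrip_away_from_edges(self):
        rng = np.random.default_rng(1)
        smooth = ndimage.gaussian_filter(rng.random((2, 121, 121)) * 200, 5)
        s = ImageStack(smooth.astype(np.uint16), dx=0.1, dy=0.1, dz=0.3)
        back = rotate_stack(rotate_stack(s, 17.0), -17.0)
        inner = (slice(None), slice(30, 91), slice(30, 91))
        diff = back.voxels[inner].astype(int) - s.voxels[inner].astype(int)
        assert np.abs(diff).max() <= 3

    def test_nonfinite_angle_rejected(self, square_plane):
        with pytest.raises(ValueError):
            rotate_stack(_stack_of(square_plane), np.nan)


class TestRescaleIntensity:
    def test_full_range_identity(self):
        v = np.linspace(0, 255, 256).astype(np.uint8)
        s = ImageStack(np.tile(v, (2, 2, 1)), dx=1, dy=1, dz=1, bit_depth=8)
        out = rescale_intensity(s, 0, 100)
        assert np.array_equal(out.voxels, s.voxels)

    def test_two_point_map(self):
        v = np.zeros((2, 2, 2), np.uint8)
        v[..., 0] = 10
        v[..., 1] = 20
        s = ImageStack(v, dx=1, dy=1, dz=1, bit_depth=8)
        out = rescale_intensity(s, 0, 100)
        assert set(np.unique(out.voxels)) == {0, 255}

    def test_percentiles_hit_range_ends(self):
        rng = np.random.default_rng(2)
        v = rng.integers(100, 5000, size=(4, 32, 32)).astype(np.uint16)
        out = rescale_intensity(ImageStack(v, dx=1, dy=1, dz=1), 1, 99)
        nz = out.voxels[out.voxels > 0]
        assert np.percentile(nz, 99) >= 0.98 * 65535
        assert (out.voxels == 0).sum() >= (v <= np.percentile(v, 1)).sum() * 0.5

    def test_monotone(self):
        rng = np.random.default_rng(3)
        v = rng.integers(0, 1000, size=(2, 16, 16)).astype(np.uint16)
        out = rescale_intensity(ImageStack(v, dx=1, dy=1, dz=1), 0.5, 99.5)
        order = np.argsort(v.ravel())
        assert np.all(np.diff(out.voxels.ravel()[order].astype(int)) >= 0)

    def test_constant_image_rejected(self):
        s = ImageStack(np.full((2, 4, 4), 7, np.uint16), dx=1, dy=1, dz=1)
        with pytest.raises(ValueError, match="degenerate"):
            rescale_intensity(s, 0.5, 99.5)

    def test_bad_percentiles_rejected(self):
        s = ImageStack(np.zeros((2, 4, 4), np.uint16), dx=1, dy=1, dz=1)
        with pytest.raises(ValueError):
            rescale_intensity(s, 50, 10)


class TestSmoothMedian:
    def test_constant_unchanged(self):
        s = ImageStack(np.full((2, 8, 8), 42, np.uint16), dx=1, dy=1, dz=1)
        assert np.array_equal(smooth_median(s, 1).voxels, s.voxels)

    def test_salt_pixel_removed(self):
        v = np.full((2, 9, 9), 100, np.uint16)
        v[0, 4, 4] = 60000
        out = smooth_median(ImageStack(v, dx=1, dy=1, dz=1), 1)
        assert out.voxels[0, 4, 4] == 100

    def test_matches_brute_force_3x3(self):
        rng = np.random.default_rng(4)
        v = rng.integers(0, 65535, size=(2, 12, 12)).astype(np.uint16)
        out = smooth_median(ImageStack(v, dx=1, dy=1, dz=1), 1)
        for r in range(1, 11):
            for c in range(1, 11):
                window = v[0, r - 1 : r + 2, c - 1 : c + 2]
                assert out.voxels[0, r, c] == np.median(window)

    def test_planes_filtered_independently(self):
        v = np.zeros((3, 8, 8), np.uint16)
        v[1] = 500  # a bright plane must not leak into neighbors
        out = smooth_median(ImageStack(v, dx=1, dy=1, dz=1), 1)
        assert out.voxels[0].max() == 0 and out.voxels[2].max() == 0
        assert np.all(out.voxels[1] == 500)

    def test_invalid_radius(self):
        s = ImageStack(np.zeros((2, 4, 4), np.uint16), dx=1, dy=1, dz=1)
        with pytest.raises(ValueError):
            smooth_median(s, 0)


class TestSegmentCube:
    def test_exact_box_recovered(self, box_stack):
        m = segment_cube(box_stack, threshold=100)
        expected = np.zeros(box_stack.shape, bool)
        expected[6:11, 20:30, 25:35] = True
        assert np.array_equal(m.mask, expected)
        assert m.bbox == ((6, 10), (20, 29), (25, 34))
        assert m.middle_z == 8
        assert m.polarity == "below_threshold"

    def test_all_bright_raises(self):
        s = ImageStack(np.full((6, 16, 16), 200, np.uint16), dx=0.1, dy=0.1, dz=0.3)
        with pytest.raises(SegmentationError, match="no bleached cube"):
            segment_cube(s, threshold=100)

    def test_largest_component_wins(self):
        v = np.full((14, 32, 32), 200, np.uint16)
        v[2:7, 4:9, 4:9] = 20  # 125 voxels
        v[8:11, 20:23, 20:23] = 20  # 27 voxels
        m = segment_cube(ImageStack(v, dx=0.1, dy=0.1, dz=0.3), threshold=100)
        assert m.mask[4, 6, 6] and not m.mask[9, 21, 21]
        assert m.mask.sum() == 125

    def test_border_touching_component_excluded(self):
        v = np.full((8, 24, 24), 200, np.uint16)
        v[2:6, 0:8, 0:8] = 20  # touches the xy border
        with pytest.raises(SegmentationError, match="border"):
            segment_cube(ImageStack(v, dx=0.1, dy=0.1, dz=0.3), threshold=100)

    def test_auto_threshold_otsu(self):
        # auto-thresholding expects intensities on the detector scale
        # (it samples the nucleus as voxels above 10% of dtype max)
        v = np.full((16, 48, 52), 52000, dtype=np.uint16)
        v[6:11, 20:30, 25:35] = 8000
        s = ImageStack(v, dx=0.1, dy=0.1, dz=0.3)
        auto = segment_cube(s, threshold="auto")
        manual = segment_cube(s, threshold=30000)
        assert np.array_equal(auto.mask, manual.mask)
        # Otsu's convention puts the threshold at the top of the dark class
        assert 8000 <= auto.threshold < 52000

    def test_invert_polarity(self):
        v = np.full((14, 32, 32), 20, np.uint16)
        v[4:9, 10:20, 10:20] = 200  # bright blob in dark field
        m = segment_cube(ImageStack(v, dx=0.1, dy=0.1, dz=0.3), threshold=100,
                         invert_polarity=True)
        assert m.polarity == "above_threshold"
        assert m.mask.sum() == 5 * 10 * 10

    def test_idempotent_on_rendered_mask(self, box_stack):
        m1 = segment_cube(box_stack, threshold=100)
        rendered = np.where(m1.mask, 20, 200).astype(np.uint16)
        m2 = segment_cube(
            ImageStack(rendered, dx=0.1, dy=0.1, dz=0.3), threshold=100
        )
        assert np.array_equal(m1.mask, m2.mask)

    def test_threshold_equivariance_under_rescale(self, box_stack):
        """Segmenting after a linear rescale with the mapped threshold
        yields the same mask as segmenting the original."""
        scaled = rescale_intensity(box_stack, 0, 100)
        lo, hi = 20, 200  # the two intensity levels present
        thr_orig = 100.0
        thr_mapped = (thr_orig - lo) * 65535 / (hi - lo)
        m1 = segment_cube(box_stack, threshold=thr_orig)
        m2 = segment_cube(scaled, threshold=thr_mapped)
        assert np.array_equal(m1.mask, m2.mask)


class TestSelectAnalysisPlanes:
    def _mask(self, shape, zs, ys, xs, **sizes):
        m = np.zeros(shape, bool)
        m[zs, ys, xs] = True
        zz, yy, xx = np.nonzero(m)
        bbox = ((zz.min(), zz.max()), (yy.min(), yy.max()), (xx.min(), xx.max()))
        mid = int(np.floor(np.median(zz) + 0.5))
        sizes = {"dx": 0.1, "dy": 0.2, "dz": 0.3, **sizes}
        return CubeMask(mask=m, bbox=bbox, middle_z=mid, polarity="below_threshold",
                        threshold=100.0, **sizes)

    def test_middle_plane_is_median_z(self):
        m = self._mask((12, 10, 10), slice(4, 9), slice(2, 8), slice(3, 9))
        plane, (row, col) = select_analysis_planes(m, "x")
        assert m.middle_z == 6
        assert plane.shape == (10, 10)
        assert plane.sum() == 6 * 6
        assert (row, col) == (0.2, 0.1)  # (dy, dx)

    def test_z_plane_rectangle_dimensions(self):
        m = self._mask((12, 10, 10), slice(4, 9), slice(2, 8), slice(3, 9))
        plane, (row, col) = select_analysis_planes(m, "z", z_view="xz")
        assert (row, col) == (0.3, 0.1)  # (dz, dx)
        zz, xx = np.nonzero(plane)
        assert zz.max() - zz.min() + 1 == 5  # z extent
        assert xx.max() - xx.min() + 1 == 6  # x extent
        plane_yz, (row2, col2) = select_analysis_planes(m, "z", z_view="yz")
        assert (row2, col2) == (0.3, 0.2)  # (dz, dy)

    def test_single_voxel_mask(self):
        m = self._mask((4, 4, 4), 2, 1, 1)
        for axis in ("x", "y", "z"):
            plane, _ = select_analysis_planes(m, axis)
            assert plane.sum() == 1

    def test_invalid_axis(self):
        m = self._mask((4, 4, 4), 2, 1, 1)
        with pytest.raises(ValueError, match="axis"):
            select_analysis_planes(m, "w")
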