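import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesselfoci import detection as det
from vesselfoci.io import PlaneImage

from oracles import brute_force_median_pairwise, exhaustive_prominent_maxima


def _plane(arr, px=1.0):
    return PlaneImage(np.asarray(arr, dtype=float), pixel_size=px)


def _gaussian_spot(shape, cy, cx, sigma, amp):
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    return amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))


class TestDetectFoci:
    def test_flat_image_has_no_foci(self):
        img = _plane(np.full((16, 16), 7.0))
        assert det.detect_foci(img, np.ones((16, 16), bool), prominence=1.0) == []

    def test_single_gaussian_spot_gives_one_focus_at_center(self):
        img = _plane(_gaussian_spot((21, 21), 10, 10, 2.0, 100.0))
        foci = det.detect_foci(img, np.ones((21, 21), bool), prominence=10.0)
        assert len(foci) == 1
        assert abs(foci[0].peak[0] - 10) <= 1 and abs(foci[0].peak[1] - 10) <= 1

    def test_plateau_collapses_to_single_focus_at_centroid(self):
        arr = np.zeros((11, 11))
        arr[4:7, 4:7] = 5.0  # 3x3 plateau
        foci = det.detect_foci(_plane(arr), np.ones((11, 11), bool), prominence=1.0)
        assert len(foci) == 1
        assert foci[0].peak == (5.0, 5.0)

    def test_non_positive_prominence_rejected(self):
        img = _plane(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            det.detect_foci(img, np.ones((4, 4), bool), prominence=0.0)

    def test_ordering_by_peak_then_position(self):
        arr = np.zeros((16, 16))
        arr[2, 2] = 10.0
        arr[12, 12] = 10.0
        arr[7, 7] = 20.0
        foci = det.detect_foci(_plane(arr), np.ones((16, 16), bool), prominence=5.0)
        peaks = [f.peak for f in foci]
        assert peaks[0] == (7.0, 7.0)
        assert peaks[1] == (2.0, 2.0)  # value tie broken by (y, x)

    def test_invariant_to_constant_offset(self, rng):
        arr = rng.uniform(0, 30, (24, 24))
        mask = np.ones((24, 24), bool)
        base = det.detect_foci(_plane(arr), mask, prominence=4.0)
        shifted = det.detect_foci(_plane(arr + 100.0), mask, prominence=4.0)
        assert [f.peak for f in base] == [f.peak for f in shifted]
        for f0, f1 in zip(base, shifted):
            assert f1.prominence == pytest.approx(f0.prominence)

    def test_detection_restricted_to_mask(self):
        arr = np.zeros((16, 16))
        arr[3, 3] = 50.0
        arr[12, 12] = 50.0
        mask = np.zeros((16, 16), bool)
        mask[:8, :8] = True
        foci = det.detect_foci(_plane(arr), mask, prominence=5.0)
        assert [f.peak for f in foci] == [(3.0, 3.0)]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_prominence_oracle(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.integers(0, 12, (16, 16)).astype(float)
        mask = rng.random((16, 16)) < 0.8
        threshold = 2.5
        got = {f.peak for f in det.detect_foci(_plane(arr), mask, threshold)}
        expected = set(exhaustive_prominent_maxima(arr, mask, threshold))
        assert got == expected


class TestFocusSize:
    def test_single_pixel_spike_has_unit_area(self):
        arr = np.zeros((11, 11))
        arr[5, 5] = 40.0
        img = _plane(arr, px=0.5)
        foci = det.detect_foci(img, np.ones((11, 11), bool), prominence=10.0)
        det.measure_focus_sizes(img, foci, np.ones((11, 11), bool), prominence=10.0)
        assert foci[0].size == pytest.approx(1 * 0.5 ** 2)

    def test_uniform_disk_size_equals_disk_area(self):
        yy, xx = np.mgrid[:21, :21]
        disk = (yy - 10) ** 2 + (xx - 10) ** 2 <= 3 ** 2
        arr = np.where(disk, 30.0, 0.0)
        img = _plane(arr)
        foci = det.detect_foci(img, np.ones((21, 21), bool), prominence=10.0)
        assert len(foci) == 1
        det.measure_focus_sizes(img, foci, np.ones((21, 21), bool), prominence=10.0)
        assert foci[0].size == pytest.approx(float(disk.sum()))

    def test_size_grows_with_spot_width(self):
        sizes = []
        for sigma in (2.0, 4.0):
            arr = _gaussian_spot((41, 41), 20, 20, sigma, 100.0)
            img = _plane(arr)
            foci = det.detect_foci(img, np.ones((41, 41), bool), prominence=20.0)
            det.measure_focus_sizes(img, foci, np.ones((41, 41), bool), prominence=20.0)
            sizes.append(foci[0].size)
        assert sizes[1] > sizes[0]

    def test_contested_pixels_split_between_close_spots(self):
        arr = (_gaussian_spot((21, 31), 10, 10, 2.0, 100.0)
               + _gaussian_spot((21, 31), 10, 20, 2.0, 100.0))
        img = _plane(arr)
        mask = np.ones((21, 31), bool)
        foci = det.detect_foci(img, mask, prominence=30.0)
        assert len(foci) == 2
        det.measure_focus_sizes(img, foci, mask, prominence=30.0)
        assert foci[0].size == pytest.approx(foci[1].size, rel=0.3)


class TestMutualDistance:
    def test_single_pair(self):
        foci = [det.FocusRecord(1, (0.0, 0.0), 1.0, 1.0),
                det.FocusRecord(1, (3.0, 4.0), 1.0, 1.0)]
        assert det.mutual_foci_distance(foci, 1.0) == pytest.approx(5.0)

    def test_three_collinear_points(self):
        foci = [det.FocusRecord(1, (float(i), 0.0), 1.0, 1.0) for i in range(3)]
        # pairwise distances {1, 1, 2} -> median 1
        assert det.mutual_foci_distance(foci, 1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [0, 1])
    def test_undefined_below_two_foci(self, n):
        foci = [det.FocusRecord(1, (0.0, 0.0), 1.0, 1.0)] * n
        assert det.mutual_foci_distance(foci, 1.0) is None

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_over_all_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 25))
        pts = rng.uniform(0, 50, (n, 2))
        px = float(rng.uniform(0.1, 2.0))
        foci = [det.FocusRecord(1, (float(y), float(x)), 1.0, 1.0) for y, x in pts]
        expected = brute_force_median_pairwise(pts * px)
        assert det.mutual_foci_distance(foci, px) == pytest.approx(expected)

    def test_invariant_under_translation_and_rotation(self, rng):
        pts = rng.uniform(0, 20, (8, 2))
        base = [det.FocusRecord(1, tuple(p), 1.0, 1.0) for p in pts]
        shifted = [det.FocusRecord(1, (p[0] + 13, p[1] - 4), 1.0, 1.0) for p in pts]
        rotated = [det.FocusRecord(1, (p[1], -p[0]), 1.0, 1.0) for p in pts]
        d0 = det.mutual_foci_distance(base, 0.8)
        assert det.mutual_foci_distance(shifted, 0.8) == pytest.approx(d0)
        assert det.mutual_foci_distance(rotated, 0.8) == pytest.approx(d0)


class TestCorrectedFoci:
    def test_direct_formula(self):
        assert det.corrected_foci(4, 50.0, 100.0) == pytest.approx(8.0)

    def test_identity_when_area_equals_mean(self):
        assert det.corrected_foci(7, 88.0, 88.0) == pytest.approx(7.0)

    def test_zero_foci_gives_zero(self):
        assert det.corrected_foci(0, 123.0, 77.0) == 0.0

    @given(st.integers(min_value=0, max_value=100),
           st.floats(min_value=1.0, max_value=500.0),
           st.floats(min_value=1.0, max_value=500.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_linearity(self, n, area, mean_area):
        c = det.corrected_foci(n, area, mean_area)
        assert det.corrected_foci(2 * n, area, mean_area) == pytest.approx(2 * c)
        assert det.corrected_foci(n, 2 * area, mean_area) == pytest.approx(c / 2)

    @pytest.mark.parametrize("area,mean", [(0.0, 100.0), (-5.0, 100.0),
                                           (50.0, 0.0), (50.0, -1.0)])
    def test_non_positive_areas_rejected(self, area, mean):
        with pytest.raises(ValueError):
            det.corrected_foci(1, area, mean)


class TestCategoryMeanArea:
    def test_mean_of_two(self):
        assert det.category_mean_area([80.0, 120.0]) == pytest.approx(100.0)

    def test_single_nucleus(self):
        assert det.category_mean_area([90.0]) == pytest.approx(90.0)

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError, match="empty stratum"):
            det.category_mean_area([])
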