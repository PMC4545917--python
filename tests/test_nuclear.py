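import numpy as np
import pytest
from scipy import stats

from mammoscope.calibration import CalibratedImage, PixelCalibration
from mammoscope.nuclear import (
    NUCLEAR_FEATURE_NAMES,
    NucleusLabelMask,
    area_fraction,
    min_internuclear_distances,
    nuclear_density,
    nuclear_diameters,
    nuclear_feature_vector,
    summarize,
)


def mask_from_centers(centers, radius=4, shape=(200, 200)):
    lab = np.zeros(shape, np.int32)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for k, (r, c) in enumerate(centers, start=1):
        lab[np.hypot(yy - r, xx - c) <= radius] = k
    return NucleusLabelMask(lab)


class TestDensity:
    def test_closed_form_per_field(self, calib):
        lab = np.zeros((1000, 1000), np.int32)
        for k in range(100):
            lab[2 * (k // 10), 2 * (k % 10)] = k + 1
        assert nuclear_density(NucleusLabelMask(lab), calib) == pytest.approx(
            100 / 0.5625, rel=1e-6
        )

    def test_empty_mask_zero(self, calib):
        assert nuclear_density(NucleusLabelMask(np.zeros((10, 10), np.int32)), calib) == 0

    def test_quarters_when_pitch_doubles(self):
        lab = np.zeros((100, 100), np.int32)
        lab[5, 5] = 1
        d1 = nuclear_density(NucleusLabelMask(lab), PixelCalibration(pitch_um=0.75))
        d2 = nuclear_density(NucleusLabelMask(lab), PixelCalibration(pitch_um=1.5))
        assert d2 == pytest.approx(d1 / 4)


class TestAreaFraction:
    @pytest.mark.parametrize(
        "fg, total, expected", [(0, 100, 0.0), (100, 100, 1.0), (25, 100, 0.25)]
    )
    def test_pixel_counts(self, fg, total, expected):
        lab = np.zeros(total, np.int32)
        lab[:fg] = 1
        assert area_fraction(NucleusLabelMask(lab.reshape(10, -1))) == expected


class TestIND:
    def test_two_nuclei_symmetric(self, calib):
        # centers 10 um apart: 13.333 px at 0.75 um/px
        m = mask_from_centers([(50, 50), (50, 50 + 10 / 0.75)])
        d = min_internuclear_distances(m, calib)
        # centroid quantization of the rasterized disks is ~0.1 um
        assert d == pytest.approx([10.0, 10.0], abs=0.15)

    def test_three_collinear(self, calib):
        px = 1 / 0.75
        m = mask_from_centers([(50, 50), (50, 50 + 10 * px), (50, 50 + 25 * px)])
        d = min_internuclear_distances(m, calib)
        assert sorted(d) == pytest.approx([10.0, 10.0, 15.0], abs=0.15)

    def test_single_nucleus_errors(self, calib):
        with pytest.raises(ValueError):
            min_internuclear_distances(mask_from_centers([(50, 50)]), calib)

    def test_invariant_under_rotation(self, calib):
        m = mask_from_centers([(40, 60), (80, 30), (120, 140), (33, 150)])
        d0 = np.sort(min_internuclear_distances(m, calib))
        rot = NucleusLabelMask(np.rot90(m.labels).copy())
        assert np.sort(min_internuclear_distances(rot, calib)) == pytest.approx(d0)


class TestDiameters:
    def test_disk_major_axis_is_diameter(self, calib):
        m = mask_from_centers([(50, 50)], radius=5)
        # 2r = 10 px = 7.5 um, discretization within 5%
        assert nuclear_diameters(m, calib)[0] == pytest.approx(7.5, rel=0.05)

    def test_line_of_nine_pixels_segment_moment(self):
        lab = np.zeros((5, 11), np.int32)
        lab[2, 1:10] = 1
        m = NucleusLabelMask(lab)
        # continuous segment of length 9: 4 * sqrt(81/12) = 10.392
        assert m.major_axes_px[0] == pytest.approx(4 * np.sqrt(81 / 12), abs=1e-6)

    def test_single_pixel_degenerate_axis(self):
        lab = np.zeros((3, 3), np.int32)
        lab[1, 1] = 1
        # unit-square convention: 4 * sqrt(1/12)
        assert NucleusLabelMask(lab).major_axes_px[0] == pytest.approx(
            4 * np.sqrt(1 / 12)
        )

    def test_empty_mask_errors(self, calib):
        with pytest.raises(ValueError):
            nuclear_diameters(NucleusLabelMask(np.zeros((4, 4), np.int32)), calib)


class TestSummarize:
    def test_constant_vector(self):
        s = summarize([5, 5, 5])
        assert (s.mean, s.median, s.mode, s.iqr, s.std, s.range) == (5, 5, 5, 0, 0, 0)

    def test_reference_vector(self):
        s = summarize([1, 2, 3, 4, 5])
        assert s.mean == 3
        assert s.median == 3
        assert s.iqr == 2
        assert s.std == pytest.approx(1.5811, abs=1e-4)
        assert s.range == 4

    def test_mode_majority_bin(self):
        assert summarize([1, 1, 9]).mode == 1
        # tie between bins 1 and 9 -> smallest bin centre
        assert summarize([1, 1, 9, 9]).mode == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_scaling_law(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(5, 40, 60)
        s1, s3 = summarize(v), summarize(3 * v)
        for f in ("mean", "median", "std", "iqr", "range"):
            assert getattr(s3, f) == pytest.approx(3 * getattr(s1, f), rel=1e-9)
        assert abs(s3.mode - 3 * s1.mode) <= 3.0  # within one (scaled) bin


class TestFeatureVector:
    def test_two_nucleus_phantom(self, calib):
        img = np.full((200, 200), 20, np.uint8)
        yy, xx = np.mgrid[:200, :200]
        for c in [(100, 92), (100, 92 + 12 / 0.75)]:
            img[np.hypot(yy - c[0], xx - c[1]) <= 5] = 210
        fv = nuclear_feature_vector(CalibratedImage(img, calib))
        assert fv["std_ind"] == pytest.approx(0.0, abs=1e-9)
        assert fv["mean_ind"] == pytest.approx(12.0, abs=0.15)

    def test_regular_grid(self, calib):
        img = np.full((400, 400), 20, np.uint8)
        yy, xx = np.mgrid[:400, :400]
        step = 20 / 0.75  # 20 um spacing
        for i in range(1, 14):
            for j in range(1, 14):
                img[np.hypot(yy - i * step, xx - j * step) <= 5] = 210
        fv = nuclear_feature_vector(CalibratedImage(img, calib))
        assert fv["mean_ind"] == pytest.approx(20.0, abs=0.2)
        assert fv["std_ind"] < 0.2

    def test_empty_image_missing_ind(self, calib):
        fv = nuclear_feature_vector(
            CalibratedImage(np.full((64, 64), 15, np.uint8), calib)
        )
        assert fv["nuclear_density"] == 0
        assert np.isnan(fv["std_ind"]) and np.isnan(fv["mean_diameter"])
        assert set(fv) == set(NUCLEAR_FEATURE_NAMES)


def test_std_ind_tracks_generative_spread(calib):
    """Measured IND dispersion must rank-follow the generative jitter."""
    rng = np.random.default_rng(5)
    spreads = [0.5, 2.0, 4.0, 7.0, 11.0]
    measured = []
    for sd in spreads:
        step = 30 / 0.75
        centers = []
        for i in range(1, 9):
            for j in range(1, 9):
                centers.append(
                    (i * step + rng.normal(0, sd / 0.75), j * step + rng.normal(0, sd / 0.75))
                )
        m = mask_from_centers(centers, radius=4, shape=(400, 400))
        measured.append(np.std(min_internuclear_distances(m, calib), ddof=1))
    rho = stats.spearmanr(spreads, measured).statistic
    assert rho > 0.9
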