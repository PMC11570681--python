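"""Regional SNR/CNR formulas, PSNR/SSIM, and automatic ROI derivation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msrecon.errors import DegenerateRoiError, DimensionError
from msrecon.metrics import Roi, auto_rois, psnr, report_for_image, roi_cnr, roi_snr, ssim
from msrecon.phantom import LESION, default_contrast_model, render_contrast


def roi_from_values(values, shape=(4, 4), offset=0):
    """Embed a value list in an image corner and return (image, roi)."""
    img = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    flat_idx = np.arange(offset, offset + len(values))
    img.flat[flat_idx] = values
    mask.flat[flat_idx] = True
    return img, Roi(mask=mask, label=1, name="test")


class TestRoiSnr:
    def test_two_point_closed_form(self):
        img, roi = roi_from_values([1.0, 3.0])
        assert roi_snr(img, roi) == pytest.approx(np.sqrt(2), abs=1e-10)

    def test_four_point_hand_arithmetic(self):
        # mean 5, sample SD sqrt(20/3) = 2.58199 -> SNR 1.93649
        img, roi = roi_from_values([2.0, 4.0, 6.0, 8.0])
        assert roi_snr(img, roi) == pytest.approx(1.93649, abs=1e-5)

    def test_constant_roi_rejected(self):
        img, roi = roi_from_values([2.0, 2.0, 2.0])
        with pytest.raises(DegenerateRoiError):
            roi_snr(img, roi)

    def test_single_pixel_roi_rejected(self):
        img, roi = roi_from_values([2.0])
        with pytest.raises(DegenerateRoiError):
            roi_snr(img, roi)

    def test_zero_noise_phantom_roi_is_degenerate(self, tissue_map, noiseless_model):
        """A noiseless phantom has constant ROIs, so SNR is an error path."""
        img = np.abs(render_contrast(tissue_map, noiseless_model, "T2WI", seed=0))
        rois = auto_rois(tissue_map, erode=1)
        with pytest.raises(DegenerateRoiError):
            roi_snr(img, rois[0])


class TestRoiCnr:
    def test_direct_substitution(self):
        # SI1=5, SD1=1, SI2=2, SD2=1 -> 3/sqrt(2)
        rng = np.random.default_rng(0)
        img = np.zeros((2, 100))
        img[0] = 5.0 + rng.standard_normal(100)
        img[1] = 2.0 + rng.standard_normal(100)
        roi1 = Roi(mask=np.array([[True] * 100, [False] * 100]), label=1, name="a")
        roi2 = Roi(mask=np.array([[False] * 100, [True] * 100]), label=2, name="b")
        si1, sd1 = img[0].mean(), img[0].std(ddof=1)
        si2, sd2 = img[1].mean(), img[1].std(ddof=1)
        expected = abs(si1 - si2) / np.hypot(sd1, sd2)
        assert roi_cnr(img, roi1, roi2) == pytest.approx(expected, abs=1e-12)
        assert roi_cnr(img, roi2, roi1) == pytest.approx(expected, abs=1e-12)

    def test_exact_value_from_moments(self):
        # two-point ROIs with means 5 and 2, equal SDs sqrt(2): CNR = 3/2
        img, _ = roi_from_values([4.0, 6.0, 1.0, 3.0])
        roi1 = Roi(mask=img == 4.0, label=1, name="a")  # placeholder, rebuilt below
        m1 = np.zeros((4, 4), dtype=bool)
        m1.flat[[0, 1]] = True
        m2 = np.zeros((4, 4), dtype=bool)
        m2.flat[[2, 3]] = True
        roi1 = Roi(mask=m1, label=1, name="a")
        roi2 = Roi(mask=m2, label=2, name="b")
        assert roi_cnr(img, roi1, roi2) == pytest.approx(3.0 / 2.0, abs=1e-12)

    def test_identical_statistics_give_zero(self):
        img, _ = roi_from_values([1.0, 3.0, 1.0, 3.0])
        m1 = np.zeros((4, 4), dtype=bool)
        m1.flat[[0, 1]] = True
        m2 = np.zeros((4, 4), dtype=bool)
        m2.flat[[2, 3]] = True
        assert roi_cnr(img, Roi(m1, 1, "a"), Roi(m2, 2, "b")) == 0.0

    def test_both_constant_rejected(self):
        img = np.zeros((4, 4))
        img.flat[[0, 1]] = 1.0
        m1 = np.zeros((4, 4), dtype=bool)
        m1.flat[[0, 1]] = True
        m2 = np.zeros((4, 4), dtype=bool)
        m2.flat[[2, 3]] = True
        with pytest.raises(DegenerateRoiError):
            roi_cnr(img, Roi(m1, 1, "a"), Roi(m2, 2, "b"))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(scale=st.floats(1e-3, 1e3), seed=st.integers(0, 100))
def test_snr_cnr_scale_invariance(scale, seed):
    """Both formulas are ratios: global positive rescaling leaves them fixed."""
    rng = np.random.default_rng(seed)
    img = rng.normal(2.0, 0.3, size=(8, 8))
    m1 = np.zeros((8, 8), dtype=bool)
    m1[:4] = True
    m2 = ~m1
    r1, r2 = Roi(m1, 1, "a"), Roi(m2, 2, "b")
    assert roi_snr(img * scale, r1) == pytest.approx(roi_snr(img, r1), rel=1e-9)
    assert roi_cnr(img * scale, r1, r2) == pytest.approx(roi_cnr(img, r1, r2), rel=1e-9)


class TestPsnr:
    def test_identical_images_are_infinite(self, rng):
        x = rng.normal(size=(16, 16))
        assert psnr(x, x) == float("inf")

    def test_closed_forms(self):
        ref = np.zeros((10, 10))
        test = np.full((10, 10), 0.1)  # MSE = 0.01 -> 20 dB at peak 1
        assert psnr(ref, test, peak=1.0) == pytest.approx(20.0, abs=1e-10)
        test = np.ones((10, 10))  # MSE = 1 -> 0 dB
        assert psnr(ref, test, peak=1.0) == pytest.approx(0.0, abs=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            psnr(np.zeros((4, 4)), np.zeros((4, 5)))


class TestSsim:
    def test_identical_images(self, rng):
        x = rng.normal(size=(32, 32))
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_negation_of_locally_zero_mean_image(self, rng):
        # checkerboard modulation keeps every 7x7 window near zero mean, so
        # negation flips the structure term and drives SSIM negative
        i, j = np.mgrid[0:32, 0:32]
        x = (-1.0) ** (i + j) * (1.0 + 0.1 * rng.normal(size=(32, 32)))
        assert ssim(x, -x, data_range=float(x.max() - x.min())) <= 0

    def test_continuity_under_tiny_noise(self, rng):
        x = rng.normal(size=(32, 32))
        y = x + rng.normal(0, 1e-6, size=(32, 32))
        assert ssim(x, y, data_range=float(x.max() - x.min())) > 0.999


class TestAutoRois:
    def test_lesion_phantom_covers_all_labels(self, tissue_map):
        rois = auto_rois(tissue_map, erode=1)
        names = {r.name for r in rois}
        assert {
            "white_matter", "gray_matter", "csf", "fat", "muscle",
            "lesion", "pathology_surrounding",
        } <= names

    def test_no_erosion_matches_label_counts(self, tissue_map):
        rois = auto_rois(tissue_map, erode=0)
        for roi in rois:
            if roi.name == "pathology_surrounding":
                continue
            assert roi.size == (tissue_map.labels == roi.label).sum()

    def test_surrounding_ring_disjoint_from_lesion(self, tissue_map):
        rois = {r.name: r for r in auto_rois(tissue_map, erode=0)}
        lesion = tissue_map.labels == LESION
        ring = rois["pathology_surrounding"].mask
        assert not (ring & lesion).any()
        assert ring.any()

    def test_lesion_roi_covers_most_of_lesion(self, tissue_map):
        rois = {r.name: r for r in auto_rois(tissue_map, erode=1)}
        lesion = tissue_map.labels == LESION
        overlap = (rois["lesion"].mask & lesion).sum()
        assert overlap > 0.5 * lesion.sum()


class TestReport:
    def test_mean_matches_class_mean_on_noisy_phantom(self, tissue_map, contrast_model):
        img = np.abs(render_contrast(tissue_map, contrast_model, "T2WI", seed=4))
        rois = auto_rois(tissue_map, erode=1)
        rep = report_for_image(img, rois, case_id="c0", sequence="T2WI")
        for roi in rois:
            si, sd, snr = rep.roi_stats[roi.name]
            assert snr == pytest.approx(si / sd, rel=1e-12)
        # all ROI pairs measured
        n = len(rep.roi_stats)
        assert len(rep.cnr) == n * (n - 1) // 2
        rows = rep.rows()
        assert len(rows) == n + len(rep.cnr)
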