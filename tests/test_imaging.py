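"""Imaging chain: loading, ROI cropping, denoising, robust color
measurement and the standard-curve calibration fit."""

import numpy as np
import pytest
from PIL import Image

from urolab import colorspace, imaging
from urolab.imaging import (
    BitDepthError,
    CalibrationCurve,
    DenoiseConfig,
    GeometryError,
    ImageFormatError,
    ROISpec,
)


class TestLoadImage:
    def test_solid_png(self, tmp_path):
        path = tmp_path / "solid.png"
        Image.fromarray(np.full((64, 64, 3), (10, 200, 30), np.uint8)).save(path)
        arr = imaging.load_image(path)
        assert arr.shape == (64, 64, 3) and arr.dtype == np.uint8
        assert np.all(arr == (10, 200, 30))

    def test_sixteen_bit_tiff_rejected(self, tmp_path):
        path = tmp_path / "deep.tiff"
        Image.fromarray(np.zeros((8, 8), np.uint16)).save(path)
        with pytest.raises(BitDepthError):
            imaging.load_image(path)

    def test_grayscale_rejected(self, tmp_path):
        path = tmp_path / "gray.png"
        Image.fromarray(np.zeros((8, 8), np.uint8)).save(path)
        with pytest.raises(ImageFormatError):
            imaging.load_image(path)

    def test_alpha_dropped_with_warning(self, tmp_path):
        path = tmp_path / "rgba.png"
        Image.fromarray(np.full((8, 8, 4), 128, np.uint8)).save(path)
        with pytest.warns(UserWarning, match="alpha"):
            arr = imaging.load_image(path)
        assert arr.shape == (8, 8, 3)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            imaging.load_image(tmp_path / "nope.png")


class TestExtractRoi:
    def test_full_frame_identity(self, solid_image):
        crop = imaging.extract_roi(solid_image, ROISpec(0.5, 0.5, 1.0, 1.0))
        assert crop.shape == solid_image.shape
        assert np.array_equal(crop, solid_image)

    def test_center_half_crop(self):
        img = np.zeros((100, 100, 3), np.uint8)
        crop = imaging.extract_roi(img, ROISpec(0.5, 0.5, 0.5, 0.5))
        assert crop.shape == (50, 50, 3)

    def test_two_tone_off_center(self):
        img = np.zeros((100, 100, 3), np.uint8)
        img[:, 50:] = 200  # right half is the sample tone
        crop = imaging.extract_roi(img, ROISpec(0.75, 0.5, 0.4, 0.8))
        assert np.all(crop == 200)

    def test_out_of_bounds(self):
        img = np.zeros((100, 100, 3), np.uint8)
        with pytest.raises(GeometryError):
            imaging.extract_roi(img, ROISpec(0.9, 0.5, 0.5, 0.5))

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            ROISpec(width_frac=0.0)


class TestDenoise:
    def test_constant_image_fixed_point(self, solid_image):
        out = imaging.denoise(solid_image, DenoiseConfig(gaussian_sigma=2.0,
                                                         morphology_radius=1))
        np.testing.assert_allclose(out, solid_image.astype(float), atol=1e-6)

    def test_all_zero_config_is_identity(self, solid_image):
        out = imaging.denoise(solid_image, DenoiseConfig(0.0, 0.0, 0.0, 0))
        assert np.array_equal(out, solid_image.astype(float))

    def test_gaussian_noise_suppressed(self):
        rng = np.random.default_rng(11)
        noisy = np.clip(128.0 + rng.normal(0, 8, (64, 64, 3)), 0, 255)
        out = imaging.denoise(noisy, DenoiseConfig(gaussian_sigma=2.0))
        before = noisy.std(axis=(0, 1))
        after = out.std(axis=(0, 1))
        assert np.all(before / after >= 3.0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            DenoiseConfig(gaussian_sigma=-1.0)


class TestMeasureColor:
    def test_noiseless_solid_is_exact(self, solid_image):
        m = imaging.measure_color(solid_image)
        assert m.mean_rgb == (200, 180, 60)
        np.testing.assert_allclose(
            m.lab, colorspace.rgb_to_lab((200, 180, 60)), atol=1e-12
        )
        assert m.quality_flags == frozenset()
        assert m.roi_pixel_count == 60 * 80

    def test_deterministic_bit_identical(self, solid_image):
        rng = np.random.default_rng(3)
        noisy = np.clip(
            solid_image.astype(float) + rng.normal(0, 5, solid_image.shape), 0, 255
        ).astype(np.uint8)
        m1 = imaging.measure_color(noisy)
        m2 = imaging.measure_color(noisy)
        assert m1 == m2

    def test_clipped_flag(self, solid_image):
        img = solid_image.copy()
        rng = np.random.default_rng(9)
        mask = rng.random(img.shape[:2]) < 0.3
        img[mask] = 255  # 30% saturated everywhere, incl. the ROI
        m = imaging.measure_color(img)
        assert "clipped" in m.quality_flags

    def test_low_pixel_count_flag(self):
        img = np.full((12, 12, 3), 100, np.uint8)
        m = imaging.measure_color(img)  # 6×6 ROI → 36 px
        assert "low-pixel-count" in m.quality_flags

    def test_negative_b_flag(self):
        bluish = np.full((64, 64, 3), (40, 40, 200), np.uint8)
        m = imaging.measure_color(bluish)
        assert m.lab[2] < 0
        assert "negative-b-clamped" in m.quality_flags

    def test_trimmed_mean_rejects_salt_and_pepper(self, solid_image):
        m0 = imaging.measure_color(solid_image)
        rng = np.random.default_rng(5)
        corrupt = solid_image.copy()
        n = corrupt.shape[0] * corrupt.shape[1]
        idx = rng.choice(n, int(0.05 * n), replace=False)
        yy, xx = np.unravel_index(idx, corrupt.shape[:2])
        half = len(idx) // 2
        corrupt[yy[:half], xx[:half]] = 255
        corrupt[yy[half:], xx[half:]] = 0
        m1 = imaging.measure_color(corrupt)
        assert abs(m1.lab[2] - m0.lab[2]) < 0.3

    def test_identity_calibration_changes_nothing(self, solid_image):
        plain = imaging.measure_color(solid_image)
        calibrated = imaging.measure_color(solid_image, curve=CalibrationCurve.identity())
        assert plain == calibrated


class TestCalibrationFit:
    def test_identity_fit(self):
        pts = np.array([[10, 20, 30], [100, 120, 140], [200, 210, 220]], float)
        curve = imaging.fit_calibration(pts, pts)
        assert curve.gains == (1.0, 1.0, 1.0)
        assert curve.offsets == (0.0, 0.0, 0.0)

    def test_exact_affine_recovery(self):
        measured = np.array([[10, 20, 30], [50, 60, 70], [90, 100, 110]], float)
        reference = 2.0 * measured + 5.0
        curve = imaging.fit_calibration(measured, reference)
        np.testing.assert_allclose(curve.gains, (2.0, 2.0, 2.0), atol=1e-9)
        np.testing.assert_allclose(curve.offsets, (5.0, 5.0, 5.0), atol=1e-9)

    def test_noisy_recovery_within_5pct(self):
        rng = np.random.default_rng(21)
        measured = rng.uniform(20, 230, size=(10, 3))
        reference = 1.3 * measured - 4.0 + rng.normal(0, 1.0, measured.shape)
        curve = imaging.fit_calibration(measured, reference)
        np.testing.assert_allclose(curve.gains, (1.3, 1.3, 1.3), rtol=0.05)

    def test_too_few_samples(self):
        with pytest.raises(imaging.CalibrationFitError):
            imaging.fit_calibration([[1, 2, 3]], [[1, 2, 3]])

    def test_degenerate_measured(self):
        measured = np.array([[50, 50, 50], [50, 50, 50]], float)
        reference = np.array([[40, 40, 40], [60, 60, 60]], float)
        with pytest.raises(imaging.CalibrationFitError):
            imaging.fit_calibration(measured, reference)
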