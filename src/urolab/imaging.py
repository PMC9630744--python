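"""Cuvette-image loading, ROI extraction, denoising and color measurement.

Software stand-in for the device's image acquisition → processing →
recognition chain: load an 8-bit RGB image of the urine-filled cuvette,
crop the key area (by default the central 50% × 50% window, matching the
fixed cuvette/camera geometry), suppress sensor noise, estimate the
sample's representative RGB by a robust per-channel trimmed mean,
optionally apply a standard-curve correction, and convert once to
L*a*b*.

The denoising chain is Gaussian smoothing → bilateral filtering →
morphological opening/closing, each stage individually disableable. The
default configuration enables only the bilateral stage: it suppresses
Gaussian sensor noise while leaving impulse outliers (specular
highlights, debris) as outliers for the trimmed mean to reject, whereas
Gaussian pre-smoothing would smear them into the background first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage
from scipy.stats import trim_mean
from skimage.morphology import closing, disk, opening
from skimage.restoration import denoise_bilateral

from . import colorspace

__all__ = [
    "ROISpec",
    "DenoiseConfig",
    "QualityThresholds",
    "CalibrationCurve",
    "MeasurementResult",
    "ImageFormatError",
    "BitDepthError",
    "GeometryError",
    "CalibrationFitError",
    "load_image",
    "roi_slices",
    "extract_roi",
    "denoise",
    "measure_color",
    "fit_calibration",
]


class ImageFormatError(ValueError):
    """Image file is not an 8-bit RGB image (e.g. grayscale input)."""


class BitDepthError(ImageFormatError):
    """Image has a bit depth other than 8 bits per channel."""


class GeometryError(ValueError):
    """Region of interest falls outside the image bounds."""


class CalibrationFitError(ValueError):
    """Standard-curve fit is impossible (too few or degenerate samples)."""


@dataclass(frozen=True)
class ROISpec:
    """Key-area geometry in fractional image coordinates.

    ``center_*_frac`` locate the ROI center, ``width_frac``/
    ``height_frac`` its extent; all relative to the image size. The
    default is the central half of the frame — the cuvette window in the
    synthetic layout.
    """

    center_x_frac: float = 0.5
    center_y_frac: float = 0.5
    width_frac: float = 0.5
    height_frac: float = 0.5

    def __post_init__(self):
        for name in ("center_x_frac", "center_y_frac", "width_frac", "height_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v!r}")


@dataclass(frozen=True)
class DenoiseConfig:
    """Parameters of the three-stage denoising chain; zeros disable stages.

    gaussian_sigma : px — Gaussian smoothing (default off, see module note)
    bilateral_sigma_color : 8-bit counts — bilateral range kernel
    bilateral_sigma_space : px — bilateral spatial kernel
    morphology_radius : px — grayscale opening+closing footprint radius
    """

    gaussian_sigma: float = 0.0
    bilateral_sigma_color: float = 12.0
    bilateral_sigma_space: float = 2.5
    morphology_radius: int = 0

    def __post_init__(self):
        for name in (
            "gaussian_sigma",
            "bilateral_sigma_color",
            "bilateral_sigma_space",
            "morphology_radius",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class QualityThresholds:
    """Limits beyond which quality flags are raised on a measurement."""

    clipped_fraction: float = 0.10  # pixels saturated at 0 or 255
    min_pixel_count: int = 100
    max_channel_std: float = 20.0  # counts, after denoising


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-channel affine standard-curve correction in RGB space."""

    gains: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offsets: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if any(g <= 0 for g in self.gains):
            raise ValueError(f"calibration gains must be positive, got {self.gains}")

    @classmethod
    def identity(cls) -> "CalibrationCurve":
        return cls()

    def apply(self, rgb):
        rgb = np.asarray(rgb, dtype=float)
        return rgb * np.asarray(self.gains) + np.asarray(self.offsets)


@dataclass(frozen=True)
class MeasurementResult:
    """Representative color of one sample image plus quality diagnostics."""

    mean_rgb: tuple[int, int, int]
    lab: tuple[float, float, float]
    roi_pixel_count: int
    quality_flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def b_value(self) -> float:
        return self.lab[2]

    def to_dict(self) -> dict:
        return {
            "mean_rgb": list(self.mean_rgb),
            "lab": list(self.lab),
            "roi_pixel_count": self.roi_pixel_count,
            "quality_flags": sorted(self.quality_flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MeasurementResult":
        return cls(
            mean_rgb=tuple(int(v) for v in d["mean_rgb"]),
            lab=tuple(float(v) for v in d["lab"]),
            roi_pixel_count=int(d["roi_pixel_count"]),
            quality_flags=frozenset(d["quality_flags"]),
        )


def load_image(path) -> np.ndarray:
    """Load an 8-bit RGB PNG/TIFF as an (H, W, 3) uint8 array.

    Row-major, origin top-left. An alpha channel is dropped with a
    warning; palette images are expanded. Grayscale or deeper-than-8-bit
    input raises a distinct error.
    """
    try:
        img = Image.open(path)
        img.load()
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise ImageFormatError(f"cannot read image {path}: {exc}") from exc
    mode = img.mode
    if mode in ("I", "F") or mode.startswith("I;16"):
        raise BitDepthError(f"{path}: expected 8 bits per channel, got mode {mode!r}")
    if mode in ("1", "L", "LA"):
        raise ImageFormatError(f"{path}: grayscale input, expected RGB")
    if mode == "RGBA":
        warnings.warn(f"{path}: dropping alpha channel", stacklevel=2)
        img = img.convert("RGB")
    elif mode == "P":
        img = img.convert("RGB")
    elif mode != "RGB":
        raise ImageFormatError(f"{path}: unsupported image mode {mode!r}")
    arr = np.asarray(img)
    if arr.dtype != np.uint8 or arr.ndim != 3 or arr.shape[2] != 3:
        raise BitDepthError(f"{path}: expected 8-bit RGB data, got {arr.dtype}/{arr.shape}")
    return arr


def roi_slices(height: int, width: int, spec: ROISpec) -> tuple[slice, slice]:
    """Pixel slices (rows, cols) of the ROI on an image of the given size."""
    rw = max(1, round(spec.width_frac * width))
    rh = max(1, round(spec.height_frac * height))
    x0 = round(spec.center_x_frac * width - rw / 2)
    y0 = round(spec.center_y_frac * height - rh / 2)
    if x0 < 0 or y0 < 0 or x0 + rw > width or y0 + rh > height:
        raise GeometryError(
            f"ROI {spec} maps to [{y0}:{y0 + rh}, {x0}:{x0 + rw}] outside a "
            f"{height}×{width} image"
        )
    return slice(y0, y0 + rh), slice(x0, x0 + rw)


def extract_roi(image: np.ndarray, spec: ROISpec) -> np.ndarray:
    """Crop the key area from an (H, W, 3) image."""
    ys, xs = roi_slices(image.shape[0], image.shape[1], spec)
    return image[ys, xs]


def denoise(image: np.ndarray, config: DenoiseConfig = DenoiseConfig()) -> np.ndarray:
    """Run the denoising chain; returns float64 on the 0–255 scale.

    Constant images are fixed points of every stage; with all parameters
    zero the function is the identity (up to dtype).
    """
    out = np.asarray(image, dtype=float)
    if config.gaussian_sigma > 0:
        out = ndimage.gaussian_filter(
            out, sigma=(config.gaussian_sigma, config.gaussian_sigma, 0), mode="nearest"
        )
    if config.bilateral_sigma_color > 0 and config.bilateral_sigma_space > 0:
        out = (
            denoise_bilateral(
                np.clip(out, 0, 255) / 255.0,
                sigma_color=config.bilateral_sigma_color / 255.0,
                sigma_spatial=config.bilateral_sigma_space,
                channel_axis=-1,
            )
            * 255.0
        )
    if config.morphology_radius > 0:
        footprint = disk(config.morphology_radius)
        for c in range(out.shape[-1]):
            out[..., c] = closing(opening(out[..., c], footprint), footprint)
    return out


def measure_color(
    image: np.ndarray,
    roi: ROISpec = ROISpec(),
    config: DenoiseConfig = DenoiseConfig(),
    curve: CalibrationCurve | None = None,
    thresholds: QualityThresholds = QualityThresholds(),
    *,
    srgb_gamma: bool = False,
) -> MeasurementResult:
    """Measure the representative sample color of a cuvette image.

    Pipeline: crop ROI → denoise → per-channel 10% trimmed mean →
    optional affine calibration → round to 8-bit RGB → convert to Lab.
    Deterministic: identical input and configuration give bit-identical
    results. Quality flags: ``clipped`` (saturated-pixel fraction),
    ``low-pixel-count``, ``high-variance``, ``negative-b-clamped``
    (measured b* < 0; grading will clamp it to level 1).
    """
    crop = extract_roi(image, roi)
    if crop.size == 0:
        raise GeometryError("empty ROI")
    n = crop.shape[0] * crop.shape[1]
    flags = set()

    saturated = np.any((crop == 0) | (crop == 255), axis=-1)
    if saturated.mean() >= thresholds.clipped_fraction:
        flags.add("clipped")
    if n < thresholds.min_pixel_count:
        flags.add("low-pixel-count")

    den = denoise(crop, config)
    flat = den.reshape(-1, 3)
    mean = np.array([trim_mean(flat[:, c], 0.1) for c in range(3)])
    if np.any(flat.std(axis=0) > thresholds.max_channel_std):
        flags.add("high-variance")

    if curve is not None:
        mean = curve.apply(mean)
    rgb8 = np.clip(colorspace.round_half_away(mean), 0, 255).astype(int)
    lab = colorspace.rgb_to_lab(rgb8, srgb_gamma=srgb_gamma)
    if lab[2] < 0:
        flags.add("negative-b-clamped")
    return MeasurementResult(
        mean_rgb=tuple(int(v) for v in rgb8),
        lab=tuple(float(v) for v in lab),
        roi_pixel_count=n,
        quality_flags=frozenset(flags),
    )


def fit_calibration(measured, reference) -> CalibrationCurve:
    """Fit the per-channel affine standard curve mapping measured → reference.

    Least squares on ≥2 paired standard-sample colors (RGB triples).
    Returns the exact identity when measured equals reference.
    """
    m = np.asarray(measured, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.ndim != 2 or m.shape[1] != 3 or m.shape != r.shape:
        raise CalibrationFitError(
            f"measured/reference must be aligned (n, 3) arrays, got {m.shape} vs {r.shape}"
        )
    if m.shape[0] < 2:
        raise CalibrationFitError("need at least 2 standard samples")
    if np.array_equal(m, r):
        return CalibrationCurve.identity()
    gains, offsets = [], []
    for c in range(3):
        if np.ptp(m[:, c]) == 0:
            raise CalibrationFitError(f"measured channel {c} is constant; cannot fit gain")
        gain, offset = np.polyfit(m[:, c], r[:, c], 1)
        gains.append(float(gain))
        offsets.append(float(offset))
    if any(g <= 0 for g in gains):
        raise CalibrationFitError(f"non-positive fitted gain: {gains}")
    return CalibrationCurve(gains=tuple(gains), offsets=tuple(offsets))
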