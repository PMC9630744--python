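"""Synthetic cuvette-image generator with known ground-truth b*.

Inverse-renders a target b* value into a noisy 8-bit RGB image laid out
like the device's camera view: a central cuvette window (the default
measurement ROI) filled with the urine color, surrounded by a dark
border. Ground truth is defined on the b* axis only — the hydration
index — with lightness and redness following a plausible concentration
trajectory (urine darkens and reddens slightly as it concentrates):

    L* = 90 − 0.55·b*,   a* = 0.08·b*

unless overridden. The trajectory is arbitrary by design and carries no
meaning of its own.

Noise is additive Gaussian in 8-bit RGB space (clipped to [0, 255]), the
simplest model that exercises the denoising and trimmed-mean stages.
Optional radial vignetting emulates uneven illumination; the default
strength is 0 because the device lights samples with a uniform LED
surface source. Every random draw comes from a named stream seeded by
the spec, so identical specs produce byte-identical images.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import colorspace, grading
from .imaging import ROISpec, roi_slices

__all__ = [
    "GamutError",
    "SyntheticSampleSpec",
    "GroundTruth",
    "PanelEntry",
    "default_lightness",
    "default_redness",
    "render_sample",
    "render_panel",
]

_CHANNELS = ("r", "g", "b")


class GamutError(ValueError):
    """Target Lab color maps outside the 8-bit RGB gamut."""


def default_lightness(target_b: float) -> float:
    """Default L* trajectory: lighter when dilute, darker when concentrated."""
    return 90.0 - 0.55 * target_b


def default_redness(target_b: float) -> float:
    """Default a* trajectory: slight red shift with concentration."""
    return 0.08 * target_b


@dataclass(frozen=True)
class SyntheticSampleSpec:
    """Recipe for one synthetic cuvette image.

    ``seed`` is mandatory: reproducibility is the point of the
    generator. ``allow_clip=True`` permits out-of-gamut targets by
    clipping the rendered fill to the RGB cube (recorded in the ground
    truth) instead of raising ``GamutError``; the clip moves b* but for
    extreme targets keeps it inside the same wide grading interval.
    """

    target_b: float
    seed: int
    target_L: float | None = None
    target_a: float | None = None
    image_width: int = 160
    image_height: int = 120
    noise_sigma: float = 2.0
    vignette_strength: float = 0.0
    border_color: tuple[int, int, int] = (60, 60, 60)
    window: ROISpec = ROISpec()
    allow_clip: bool = False

    def __post_init__(self):
        if not 0 <= self.target_b < grading.B_AXIS_MAX:
            raise ValueError(
                f"target_b must be in [0, {grading.B_AXIS_MAX:g}), got {self.target_b!r}"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if not 0 <= self.vignette_strength < 1:
            raise ValueError("vignette_strength must be in [0, 1)")
        if self.image_width < 4 or self.image_height < 4:
            raise ValueError("image must be at least 4×4 pixels")

    @property
    def target_lab(self) -> tuple[float, float, float]:
        L = self.target_L if self.target_L is not None else default_lightness(self.target_b)
        a = self.target_a if self.target_a is not None else default_redness(self.target_b)
        return (L, a, self.target_b)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually put in the cuvette window."""

    target_b: float
    target_usg: float
    target_lab: tuple[float, float, float]
    fill_rgb: tuple[int, int, int]
    level: int
    gamut_clipped: bool = False


@dataclass(frozen=True)
class PanelEntry:
    image: np.ndarray
    truth: GroundTruth
    path: Path | None = None


def _fill_color(spec: SyntheticSampleSpec) -> tuple[tuple[int, int, int], bool]:
    scaled = colorspace.lab_to_rgb_float(spec.target_lab)
    bad = (scaled <= -0.5) | (scaled >= 255.5)
    if np.any(bad):
        if not spec.allow_clip:
            names = ", ".join(
                f"{_CHANNELS[i]}={scaled[i]:.2f}" for i in np.flatnonzero(bad)
            )
            raise GamutError(
                f"target Lab {spec.target_lab} is out of the RGB gamut ({names}); "
                "pass allow_clip=True to clip"
            )
        clipped = True
    else:
        clipped = False
    rgb8 = np.clip(colorspace.round_half_away(scaled), 0, 255).astype(int)
    return tuple(int(v) for v in rgb8), clipped


def render_sample(spec: SyntheticSampleSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one cuvette image and its ground-truth record.

    The cuvette window (``spec.window``, by default the central 50%×50%
    matching the measurement ROI) is filled with the RGB rendering of
    the target Lab; vignetting (if any) is applied to the clean image
    and seeded Gaussian noise is added last, as sensor noise would be.
    """
    fill, clipped = _fill_color(spec)
    h, w = spec.image_height, spec.image_width
    img = np.empty((h, w, 3), dtype=float)
    img[...] = np.asarray(spec.border_color, dtype=float)
    ys, xs = roi_slices(h, w, spec.window)
    img[ys, xs] = np.asarray(fill, dtype=float)

    if spec.vignette_strength > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        r2 = ((yy - cy) / cy) ** 2 + ((xx - cx) / cx) ** 2
        img *= (1.0 - spec.vignette_strength * r2 / r2.max())[..., None]

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img += rng.normal(0.0, spec.noise_sigma, img.shape)

    img = np.clip(colorspace.round_half_away(img), 0, 255).astype(np.uint8)

    table = grading.build_grading_table()
    truth = GroundTruth(
        target_b=spec.target_b,
        target_usg=grading.b_to_usg(spec.target_b),
        target_lab=spec.target_lab,
        fill_rgb=fill,
        level=grading.classify_b(spec.target_b, table).level,
        gamut_clipped=clipped,
    )
    return img, truth


def render_panel(
    b_values,
    out_dir=None,
    *,
    seed: int,
    **shared,
) -> list[PanelEntry]:
    """Render one image per target b*, with per-image seeds ``seed + i``.

    ``shared`` holds any other :class:`SyntheticSampleSpec` fields. When
    ``out_dir`` is given, images are written as PNGs plus a
    ``manifest.csv`` ground-truth table (filename, target_b, target_usg,
    level).
    """
    entries = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for i, b in enumerate(b_values):
        spec = SyntheticSampleSpec(target_b=float(b), seed=seed + i, **shared)
        img, truth = render_sample(spec)
        path = None
        if out_path is not None:
            path = out_path / f"sample_{i:04d}.png"
            Image.fromarray(img, mode="RGB").save(path)
        entries.append(PanelEntry(image=img, truth=truth, path=path))
    if out_path is not None:
        manifest = pd.DataFrame(
            {
                "filename": [e.path.name for e in entries],
                "target_b": [e.truth.target_b for e in entries],
                "target_usg": [e.truth.target_usg for e in entries],
                "level": [e.truth.level for e in entries],
            }
        )
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return entries


def spec_to_dict(spec: SyntheticSampleSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["window"] = dataclasses.asdict(spec.window)
    return d
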