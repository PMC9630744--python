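"""System configuration: ROI geometry, denoising, calibration, grading.

One YAML file drives the whole pipeline. Every key has a default that
reproduces the published system behavior, so an empty or missing config
is valid. Example::

    roi:            {center_x_frac: 0.5, center_y_frac: 0.5,
                     width_frac: 0.5, height_frac: 0.5}
    denoise:        {gaussian_sigma: 0.0, bilateral_sigma_color: 12.0,
                     bilateral_sigma_space: 2.5, morphology_radius: 0}
    quality:        {clipped_fraction: 0.10, min_pixel_count: 100,
                     max_channel_std: 20.0}
    regression:     {intercept: -1220.0, slope: 1220.0}
    usg_thresholds: [1.000, 1.005, 1.010, 1.015, 1.020, 1.025, 1.030, 1.035]
    srgb_gamma:     false
    calibration:    {gains: [1, 1, 1], offsets: [0, 0, 0]}   # optional
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .grading import USG_THRESHOLDS, HydrationGrade, RegressionParams, build_grading_table
from .imaging import CalibrationCurve, DenoiseConfig, QualityThresholds, ROISpec

__all__ = ["SystemConfig", "load_config"]


@dataclass(frozen=True)
class SystemConfig:
    roi: ROISpec = ROISpec()
    denoise: DenoiseConfig = DenoiseConfig()
    quality: QualityThresholds = QualityThresholds()
    regression: RegressionParams = RegressionParams()
    usg_thresholds: tuple = USG_THRESHOLDS
    srgb_gamma: bool = False
    calibration: CalibrationCurve | None = None

    def grading_table(self) -> list[HydrationGrade]:
        return build_grading_table(self.regression, self.usg_thresholds)

    @classmethod
    def from_dict(cls, d: dict) -> "SystemConfig":
        d = dict(d or {})
        kwargs = {}
        if "roi" in d:
            kwargs["roi"] = ROISpec(**d.pop("roi"))
        if "denoise" in d:
            kwargs["denoise"] = DenoiseConfig(**d.pop("denoise"))
        if "quality" in d:
            kwargs["quality"] = QualityThresholds(**d.pop("quality"))
        if "regression" in d:
            kwargs["regression"] = RegressionParams(**d.pop("regression"))
        if "usg_thresholds" in d:
            kwargs["usg_thresholds"] = tuple(d.pop("usg_thresholds"))
        if "srgb_gamma" in d:
            kwargs["srgb_gamma"] = bool(d.pop("srgb_gamma"))
        cal = d.pop("calibration", None)
        if cal is not None:
            kwargs["calibration"] = CalibrationCurve(
                gains=tuple(cal["gains"]), offsets=tuple(cal["offsets"])
            )
        if d:
            raise ValueError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = {
            "roi": dataclasses.asdict(self.roi),
            "denoise": dataclasses.asdict(self.denoise),
            "quality": dataclasses.asdict(self.quality),
            "regression": dataclasses.asdict(self.regression),
            "usg_thresholds": list(self.usg_thresholds),
            "srgb_gamma": self.srgb_gamma,
        }
        if self.calibration is not None:
            out["calibration"] = {
                "gains": list(self.calibration.gains),
                "offsets": list(self.calibration.offsets),
            }
        return out

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_config(path=None) -> SystemConfig:
    """Load a YAML config; ``None`` gives the defaults."""
    if path is None:
        return SystemConfig()
    data = yaml.safe_load(Path(path).read_text())
    return SystemConfig.from_dict(data or {})
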