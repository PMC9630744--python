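"""Eight-level hydration grading from the urine-color b* value.

The grading standard rests on a published linear regression between
urine specific gravity (Usg) and the urine color's b* value,

    b* = -1220 + 1220 · Usg,

fitted on 803 athlete urine samples (R² = 0.657). Substituting the
clinical Usg grade thresholds 1.000, 1.005, …, 1.035 into the
regression yields the b* interval bounds of the eight hydration levels
(0, 6.1, 12.2, 18.3, 24.4, 30.5, 36.6, 42.7, capped at 127 — the top
of the b* axis). Each level carries a hydration status and a
rehydration recommendation expressed as a percentage of body weight in
sports drink; the volume in ml uses a fluid density of 1 g/ml, so 1%
of body weight in kg is weight × 10 ml.

Intervals are half-open ``[b_low, b_high)`` so every b* maps to exactly
one level; b* = 127 belongs to level 8 and negative b* (blue-shifted
urine, e.g. dye interference) clamps to level 1 — callers can detect
the clamp via :func:`classify_b_ex`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "USG_THRESHOLDS",
    "B_AXIS_MAX",
    "SIPPING_NOTE",
    "RegressionParams",
    "HydrationGrade",
    "RehydrationAdvice",
    "usg_to_b",
    "b_to_usg",
    "build_grading_table",
    "classify_b",
    "classify_b_ex",
    "rehydration_volume",
    "grade_from_lab",
    "table_to_dataframe",
]

#: Usg thresholds bounding the eight hydration grades (lower bounds; the
#: eighth grade is open above 1.035).
USG_THRESHOLDS = (1.000, 1.005, 1.010, 1.015, 1.020, 1.025, 1.030, 1.035)

#: Top of the b* axis; upper bound of level 8.
B_AXIS_MAX = 127.0

_USG_MIN, _USG_MAX = 1.000, 1.060

_STATUS = (
    "Well hydrated",
    "Well hydrated",
    "Minimal dehydration",
    "Minimal dehydration",
    "Significant dehydration",
    "Significant dehydration",
    "Serious dehydration",
    "Serious dehydration",
)

_GUIDANCE = (
    "You are drinking enough.",
    "You are drinking enough.",
    "You can add up to 0.25% body weight in sports drinks.",
    "You can add up to 0.25% body weight in sports drinks.",
    "You need to add 0.25%–0.5% body weight in sports drink.",
    "You need to add 0.5%–1% body weight in sports drink.",
    "You need to add 1%–1.5% body weight in sports drink.",
    "You need to add 1.5%–2% body weight in sports drink.",
)

# Rehydration fractions in % body weight. "Up to 0.25%" reads as (0, 0.25).
_FRACTIONS = (
    (0.0, 0.0),
    (0.0, 0.0),
    (0.0, 0.25),
    (0.0, 0.25),
    (0.25, 0.5),
    (0.5, 1.0),
    (1.0, 1.5),
    (1.5, 2.0),
)

_STATUS_SENTENCE = {
    "Well hydrated": "You are drinking enough.",
    "Minimal dehydration": "You are minimally dehydrated.",
    "Significant dehydration": "You are significantly dehydrated.",
    "Serious dehydration": "You are seriously dehydrated.",
}

#: Extra caution appended for seriously dehydrated users (levels 7–8).
SIPPING_NOTE = (
    "Pay attention for a short period while rehydrating. "
    "You are recommended to take 100 ml–200 ml of sports drinks "
    "every 10 min–20 min. The amount of fluid supplementation can be "
    "adjusted appropriately in accordance with the actual situation."
)


@dataclass(frozen=True)
class RegressionParams:
    """Linear map from Usg to b*: ``b = intercept + slope * usg``."""

    intercept: float = -1220.0
    slope: float = 1220.0

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError(f"regression slope must be positive, got {self.slope}")


@dataclass(frozen=True)
class HydrationGrade:
    """One row of the grading standard."""

    level: int
    status: str
    usg_low: float
    usg_high: float  # NaN-free: level 8 uses the Usg of b=127
    b_low: float
    b_high: float
    frac_low: float  # % body weight
    frac_high: float
    guidance_template: str

    def __post_init__(self):
        if not 1 <= self.level <= 8:
            raise ValueError(f"level must be 1..8, got {self.level}")
        if self.frac_low > self.frac_high:
            raise ValueError("frac_low must not exceed frac_high")


@dataclass(frozen=True)
class RehydrationAdvice:
    """Body-weight-scaled fluid recommendation for one test."""

    level: int
    volume_low_ml: float
    volume_high_ml: float
    message: str
    sipping_note: str | None = None

    @property
    def full_text(self) -> str:
        if self.sipping_note:
            return f"{self.message} {self.sipping_note}"
        return self.message


def usg_to_b(usg: float, params: RegressionParams = RegressionParams()) -> float:
    """b* predicted by the regression at a given specific gravity."""
    if not _USG_MIN <= usg <= _USG_MAX:
        raise ValueError(
            f"Usg {usg!r} outside physiological range [{_USG_MIN}, {_USG_MAX}]"
        )
    return params.intercept + params.slope * usg


def b_to_usg(b: float, params: RegressionParams = RegressionParams()) -> float:
    """Specific gravity implied by a b* value (inverse of the regression)."""
    if b < 0:
        raise ValueError(f"b* must be nonnegative, got {b!r}")
    return (b - params.intercept) / params.slope


def build_grading_table(
    params: RegressionParams = RegressionParams(),
    usg_thresholds: Sequence[float] = USG_THRESHOLDS,
) -> list[HydrationGrade]:
    """Derive the eight-grade table from the regression and Usg thresholds.

    The b* bound of each grade boundary is ``usg_to_b`` of the
    corresponding Usg threshold; the last grade is capped at
    ``B_AXIS_MAX``. The table is re-derived, not hard-coded, so
    alternative regression parameters propagate consistently.
    """
    if len(usg_thresholds) != 8:
        raise ValueError(f"expected 8 Usg thresholds, got {len(usg_thresholds)}")
    if list(usg_thresholds) != sorted(usg_thresholds):
        raise ValueError("Usg thresholds must be increasing")
    b_bounds = [usg_to_b(u, params) for u in usg_thresholds] + [B_AXIS_MAX]
    usg_bounds = list(usg_thresholds) + [b_to_usg(B_AXIS_MAX, params)]
    table = []
    for i in range(8):
        table.append(
            HydrationGrade(
                level=i + 1,
                status=_STATUS[i],
                usg_low=usg_bounds[i],
                usg_high=usg_bounds[i + 1],
                b_low=b_bounds[i],
                b_high=b_bounds[i + 1],
                frac_low=_FRACTIONS[i][0],
                frac_high=_FRACTIONS[i][1],
                guidance_template=_GUIDANCE[i],
            )
        )
    return table


def classify_b_ex(b: float, table: Sequence[HydrationGrade]) -> tuple[HydrationGrade, bool]:
    """Classify a b* value; also report whether a negative b* was clamped.

    Intervals are half-open ``[b_low, b_high)``; ``b == b_high`` of the
    last grade (127) still maps to level 8, and anything above the axis
    top stays level 8.
    """
    clamped = b < 0
    if clamped:
        b = 0.0
    for grade in table:
        if grade.b_low <= b < grade.b_high:
            return grade, clamped
    return table[-1], clamped


def classify_b(b: float, table: Sequence[HydrationGrade]) -> HydrationGrade:
    """Hydration grade whose half-open b* interval contains ``b``."""
    return classify_b_ex(b, table)[0]


def _fmt_ml(v: float) -> str:
    return f"{v:,.6g}"


def rehydration_volume(grade: HydrationGrade, weight_kg: float) -> RehydrationAdvice:
    """Fluid-volume advice for a grade, scaled by body weight.

    Volumes are ``frac% × weight_kg × 1000 ml`` per kg (fluid density
    1 g/ml), unrounded; e.g. level 7 at 80 kg gives 800–1200 ml.
    """
    if not 20 < weight_kg < 250:
        raise ValueError(f"weight {weight_kg!r} kg outside plausible range (20, 250)")
    # frac% of body weight at 1 g/ml ≡ frac × weight × 10 ml
    low = grade.frac_low * weight_kg * 10.0
    high = grade.frac_high * weight_kg * 10.0
    status_sentence = _STATUS_SENTENCE[grade.status]
    if high <= 0:
        message = status_sentence
    elif low <= 0:
        message = (
            f"{status_sentence} {grade.guidance_template} You are recommended "
            f"to take up to {_fmt_ml(high)} ml of sports drinks."
        )
    else:
        message = (
            f"{status_sentence} {grade.guidance_template} You are recommended "
            f"to take {_fmt_ml(low)} ml–{_fmt_ml(high)} ml of sports drinks."
        )
    note = SIPPING_NOTE if grade.level >= 7 else None
    return RehydrationAdvice(
        level=grade.level,
        volume_low_ml=low,
        volume_high_ml=high,
        message=message,
        sipping_note=note,
    )


def grade_from_lab(
    lab, table: Sequence[HydrationGrade], weight_kg: float
) -> tuple[HydrationGrade, RehydrationAdvice]:
    """Classify a measured Lab triple by its b* and compute advice."""
    b = float(lab[2])
    grade = classify_b(b, table)
    return grade, rehydration_volume(grade, weight_kg)


def table_to_dataframe(table: Sequence[HydrationGrade]) -> pd.DataFrame:
    """Grading table as a DataFrame (for display and CSV/JSON export)."""
    return pd.DataFrame(
        {
            "level": [g.level for g in table],
            "status": [g.status for g in table],
            "usg_low": [g.usg_low for g in table],
            "usg_high": [g.usg_high for g in table],
            "b_low": [g.b_low for g in table],
            "b_high": [g.b_high for g in table],
            "frac_low_pct": [g.frac_low for g in table],
            "frac_high_pct": [g.frac_high for g in table],
            "guidance": [g.guidance_template for g in table],
        }
    )
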