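"""User profiles, test records, local persistence and report rendering.

Mirrors the device's operation flow — enter the user's details, test a
sample, review and export history — with a single append-only JSON-lines
store standing in for the host database, and CSV/JSON export standing in
for the cloud upload.
"""

from __future__ import annotations

import csv
import json
import uuid
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

from . import grading, imaging
from .config import SystemConfig
from .grading import RehydrationAdvice
from .imaging import MeasurementResult

__all__ = [
    "UserProfile",
    "TestRecord",
    "RecordStore",
    "StoreIntegrityError",
    "analyze",
    "review",
    "export_records",
    "import_records",
    "render_report",
]


class StoreIntegrityError(ValueError):
    """The record store contains a line that is not a valid record."""


@dataclass(frozen=True)
class UserProfile:
    full_name: str
    height_cm: float
    weight_kg: float
    gender: str = ""
    date_of_birth: date | None = None
    sport_event: str = ""

    def __post_init__(self):
        if not 20 < self.weight_kg < 250:
            raise ValueError(f"weight {self.weight_kg!r} kg outside plausible range (20, 250)")
        if not 80 < self.height_cm < 250:
            raise ValueError(f"height {self.height_cm!r} cm outside plausible range (80, 250)")

    def to_dict(self) -> dict:
        return {
            "full_name": self.full_name,
            "height_cm": self.height_cm,
            "weight_kg": self.weight_kg,
            "gender": self.gender,
            "date_of_birth": self.date_of_birth.isoformat() if self.date_of_birth else None,
            "sport_event": self.sport_event,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UserProfile":
        dob = d.get("date_of_birth")
        return cls(
            full_name=d["full_name"],
            height_cm=float(d["height_cm"]),
            weight_kg=float(d["weight_kg"]),
            gender=d.get("gender", ""),
            date_of_birth=date.fromisoformat(dob) if dob else None,
            sport_event=d.get("sport_event", ""),
        )


@dataclass(frozen=True)
class TestRecord:
    """One analysis event: who, when, where, what was measured, what to do."""

    record_id: str
    user: UserProfile
    timestamp: datetime
    location: str
    measurement: MeasurementResult
    level: int
    advice: RehydrationAdvice

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "user": self.user.to_dict(),
            "timestamp": self.timestamp.isoformat(),
            "location": self.location,
            "measurement": self.measurement.to_dict(),
            "level": self.level,
            "advice": {
                "level": self.advice.level,
                "volume_low_ml": self.advice.volume_low_ml,
                "volume_high_ml": self.advice.volume_high_ml,
                "message": self.advice.message,
                "sipping_note": self.advice.sipping_note,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TestRecord":
        adv = d["advice"]
        return cls(
            record_id=d["record_id"],
            user=UserProfile.from_dict(d["user"]),
            timestamp=datetime.fromisoformat(d["timestamp"]),
            location=d.get("location", ""),
            measurement=MeasurementResult.from_dict(d["measurement"]),
            level=int(d["level"]),
            advice=RehydrationAdvice(
                level=int(adv["level"]),
                volume_low_ml=float(adv["volume_low_ml"]),
                volume_high_ml=float(adv["volume_high_ml"]),
                message=adv["message"],
                sipping_note=adv.get("sipping_note"),
            ),
        )


class RecordStore:
    """Append-only JSON-lines record store."""

    def __init__(self, path):
        self.path = Path(path)

    def append(self, record: TestRecord) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        with self.path.open("a", encoding="utf-8") as fh:
            fh.write(json.dumps(record.to_dict()) + "\n")

    def load(self) -> list[TestRecord]:
        if not self.path.exists():
            return []
        records = []
        for lineno, line in enumerate(self.path.read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip():
                continue
            try:
                records.append(TestRecord.from_dict(json.loads(line)))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise StoreIntegrityError(
                    f"{self.path}:{lineno}: corrupt record ({exc})"
                ) from exc
        return records


def analyze(
    image_path,
    user: UserProfile,
    config: SystemConfig | None = None,
    store: RecordStore | None = None,
    *,
    location: str = "",
    timestamp: datetime | None = None,
) -> TestRecord:
    """Run the full pipeline on one image and (optionally) persist a record.

    measure_color → classify by b* → body-weight-scaled advice. Errors
    from imaging or grading propagate with the file path as context, and
    nothing is written to the store on failure.
    """
    if config is None:
        config = SystemConfig()
    image = imaging.load_image(image_path)
    try:
        measurement = imaging.measure_color(
            image,
            roi=config.roi,
            config=config.denoise,
            curve=config.calibration,
            thresholds=config.quality,
            srgb_gamma=config.srgb_gamma,
        )
        table = config.grading_table()
        grade, advice = grading.grade_from_lab(
            measurement.lab, table, user.weight_kg
        )
    except ValueError as exc:
        raise type(exc)(f"{image_path}: {exc}") from exc
    record = TestRecord(
        record_id=str(uuid.uuid4()),
        user=user,
        timestamp=timestamp or datetime.now(),
        location=location,
        measurement=measurement,
        level=grade.level,
        advice=advice,
    )
    if store is not None:
        store.append(record)
    return record


def review(
    store: RecordStore | list[TestRecord],
    *,
    sport_event: str | None = None,
    location: str | None = None,
    start: datetime | None = None,
    end: datetime | None = None,
) -> list[TestRecord]:
    """Records matching every given filter, sorted by timestamp."""
    records = store.load() if isinstance(store, RecordStore) else list(store)
    out = []
    for r in records:
        if sport_event is not None and r.user.sport_event != sport_event:
            continue
        if location is not None and r.location != location:
            continue
        if start is not None and r.timestamp < start:
            continue
        if end is not None and r.timestamp > end:
            continue
        out.append(r)
    out.sort(key=lambda r: r.timestamp)
    return out


_CSV_FIELDS = [
    "record_id", "full_name", "height_cm", "weight_kg", "gender",
    "date_of_birth", "sport_event", "timestamp", "location",
    "mean_r", "mean_g", "mean_b", "lab_L", "lab_a", "lab_b",
    "roi_pixel_count", "quality_flags", "level",
    "volume_low_ml", "volume_high_ml", "message", "sipping_note",
]


def _record_to_row(r: TestRecord) -> dict:
    return {
        "record_id": r.record_id,
        "full_name": r.user.full_name,
        "height_cm": repr(r.user.height_cm),
        "weight_kg": repr(r.user.weight_kg),
        "gender": r.user.gender,
        "date_of_birth": r.user.date_of_birth.isoformat() if r.user.date_of_birth else "",
        "sport_event": r.user.sport_event,
        "timestamp": r.timestamp.isoformat(),
        "location": r.location,
        "mean_r": r.measurement.mean_rgb[0],
        "mean_g": r.measurement.mean_rgb[1],
        "mean_b": r.measurement.mean_rgb[2],
        "lab_L": repr(r.measurement.lab[0]),
        "lab_a": repr(r.measurement.lab[1]),
        "lab_b": repr(r.measurement.lab[2]),
        "roi_pixel_count": r.measurement.roi_pixel_count,
        "quality_flags": ";".join(sorted(r.measurement.quality_flags)),
        "level": r.level,
        "volume_low_ml": repr(r.advice.volume_low_ml),
        "volume_high_ml": repr(r.advice.volume_high_ml),
        "message": r.advice.message,
        "sipping_note": r.advice.sipping_note or "",
    }


def _row_to_record(row: dict) -> TestRecord:
    user = UserProfile(
        full_name=row["full_name"],
        height_cm=float(row["height_cm"]),
        weight_kg=float(row["weight_kg"]),
        gender=row["gender"],
        date_of_birth=date.fromisoformat(row["date_of_birth"]) if row["date_of_birth"] else None,
        sport_event=row["sport_event"],
    )
    measurement = MeasurementResult(
        mean_rgb=(int(row["mean_r"]), int(row["mean_g"]), int(row["mean_b"])),
        lab=(float(row["lab_L"]), float(row["lab_a"]), float(row["lab_b"])),
        roi_pixel_count=int(row["roi_pixel_count"]),
        quality_flags=frozenset(f for f in row["quality_flags"].split(";") if f),
    )
    advice = RehydrationAdvice(
        level=int(row["level"]),
        volume_low_ml=float(row["volume_low_ml"]),
        volume_high_ml=float(row["volume_high_ml"]),
        message=row["message"],
        sipping_note=row["sipping_note"] or None,
    )
    return TestRecord(
        record_id=row["record_id"],
        user=user,
        timestamp=datetime.fromisoformat(row["timestamp"]),
        location=row["location"],
        measurement=measurement,
        level=int(row["level"]),
        advice=advice,
    )


def export_records(store: RecordStore | list[TestRecord], fmt: str, path) -> Path:
    """Serialize all records to ``csv`` or ``json``; round-trips losslessly."""
    records = store.load() if isinstance(store, RecordStore) else list(store)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        path.write_text(json.dumps([r.to_dict() for r in records], indent=2))
    elif fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
            writer.writeheader()
            for r in records:
                writer.writerow(_record_to_row(r))
    else:
        raise ValueError(f"unknown export format {fmt!r} (expected 'csv' or 'json')")
    return path


def import_records(path) -> list[TestRecord]:
    """Read records back from a CSV or JSON export."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return [TestRecord.from_dict(d) for d in json.loads(path.read_text())]
    with path.open(newline="", encoding="utf-8") as fh:
        return [_row_to_record(row) for row in csv.DictReader(fh)]


def render_report(record: TestRecord) -> str:
    """Human-readable result report for one test."""
    m = record.measurement
    lines = [
        f"Hydration test report — {record.user.full_name}",
        f"Time: {record.timestamp.isoformat()}   Location: {record.location or '-'}",
        f"Measured color: RGB {m.mean_rgb}  L*={m.lab[0]:.2f} a*={m.lab[1]:.2f} b*={m.lab[2]:.2f}",
        f"Hydration level: {record.level}",
        record.advice.full_text,
    ]
    if m.quality_flags:
        lines.append("Quality flags: " + ", ".join(sorted(m.quality_flags)))
    return "\n".join(lines)
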