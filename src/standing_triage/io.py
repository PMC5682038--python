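"""Reading and writing cohorts of findings records.

One unambiguous CSV dialect: comma-delimited, UTF-8, header required, enum
values as upper-snake-case strings, booleans as ``true``/``false``, absent
optional fields empty.  JSON cohorts are arrays of objects with identical
keys.  Every row is validated on read; a malformed file is rejected with
row-numbered diagnostics rather than silently dropping records.  Unknown
columns are preserved on the file object but ignored by the validator.

A missing ``true_diagnosis`` is allowed (classification-only use);
evaluation against the reference standard refuses such rows explicitly at
the point of confusion-table construction.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable

import yaml

from .algorithm import (
    ClassifierConfig,
    Diagnosis,
    HitPolicy,
    HitResult,
    NystagmusMode,
    PatientFindings,
    PositionalType,
    SpontaneousDirection,
    StandingResult,
)
from .errors import FormatError, ValidationError

__all__ = [
    "CohortFile",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
    "results_to_rows",
    "load_classifier_config",
    "logger",
]

logger = logging.getLogger("standing_triage")

FIELDNAMES = (
    "nystagmus_mode",
    "spontaneous_direction",
    "positional_type",
    "hit_result",
    "can_stand_walk_unassisted",
    "true_diagnosis",
)


@dataclass
class CohortFile:
    path: Path | None
    records: list[PatientFindings]
    extra_columns: tuple[str, ...] = ()


def _parse_bool(value: str, row: int) -> bool:
    v = value.strip().lower()
    if v in ("true", "1"):
        return True
    if v in ("false", "0"):
        return False
    raise ValidationError(
        f"cannot parse boolean from '{value}'", field="can_stand_walk_unassisted", row=row
    )


def _parse_enum(enum_cls, value: str | None, field: str, row: int, default=None):
    if value is None or str(value).strip() == "":
        return default
    try:
        return enum_cls(str(value).strip().upper())
    except ValueError:
        raise ValidationError(
            f"'{value}' is not one of {[e.value for e in enum_cls]}", field=field, row=row
        ) from None


def _record_from_mapping(raw: dict[str, Any], row: int) -> PatientFindings:
    gait = raw.get("can_stand_walk_unassisted")
    if isinstance(gait, bool):
        gait_val = gait
    elif gait is None or str(gait).strip() == "":
        raise ValidationError("missing value", field="can_stand_walk_unassisted", row=row)
    else:
        gait_val = _parse_bool(str(gait), row)
    mode = _parse_enum(NystagmusMode, raw.get("nystagmus_mode"), "nystagmus_mode", row)
    if mode is None:
        raise ValidationError("missing value", field="nystagmus_mode", row=row)
    try:
        return PatientFindings(
            nystagmus_mode=mode,
            spontaneous_direction=_parse_enum(
                SpontaneousDirection, raw.get("spontaneous_direction"),
                "spontaneous_direction", row,
            ),
            positional_type=_parse_enum(
                PositionalType, raw.get("positional_type"), "positional_type", row
            ),
            hit_result=_parse_enum(
                HitResult, raw.get("hit_result"), "hit_result", row,
                default=HitResult.NOT_PERFORMED,
            ),
            can_stand_walk_unassisted=gait_val,
            true_diagnosis=_parse_enum(
                Diagnosis, raw.get("true_diagnosis"), "true_diagnosis", row,
                default=Diagnosis.UNKNOWN,
            ),
        )
    except ValidationError as exc:
        if exc.row is None:
            raise ValidationError(str(exc), field=exc.field, row=row) from None
        raise


def read_cohort(path: str | Path) -> CohortFile:
    """Read a findings cohort from CSV or JSON (by file extension)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(rows, list):
            raise FormatError("JSON cohort must be an array of objects")
        extra: tuple[str, ...] = ()
    else:
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise FormatError(f"{path}: empty file, header required")
            missing = [f for f in FIELDNAMES if f not in reader.fieldnames]
            if missing:
                raise FormatError(f"{path}: header missing columns {missing}")
            extra = tuple(c for c in reader.fieldnames if c not in FIELDNAMES)
            rows = list(reader)
    records = []
    for i, raw in enumerate(rows):
        records.append(_record_from_mapping(raw, row=i + 1))
    logger.info("read %d records from %s", len(records), path)
    return CohortFile(path=path, records=records, extra_columns=extra)


def _record_to_row(rec: PatientFindings) -> dict[str, str]:
    return {
        "nystagmus_mode": rec.nystagmus_mode.value,
        "spontaneous_direction": rec.spontaneous_direction.value
        if rec.spontaneous_direction
        else "",
        "positional_type": rec.positional_type.value if rec.positional_type else "",
        "hit_result": rec.hit_result.value,
        "can_stand_walk_unassisted": "true" if rec.can_stand_walk_unassisted else "false",
        "true_diagnosis": rec.true_diagnosis.value,
    }


def write_cohort(cohort: CohortFile | Iterable[PatientFindings], path: str | Path) -> None:
    """Write a cohort as CSV or JSON (by file extension); round-trip safe."""
    path = Path(path)
    records = cohort.records if isinstance(cohort, CohortFile) else list(cohort)
    rows = [_record_to_row(r) for r in records]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1) + "\n", encoding="utf-8")
    else:
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(FIELDNAMES))
            writer.writeheader()
            writer.writerows(rows)
    logger.info("wrote %d records to %s", len(rows), path)


def records_to_frame(records: Iterable[PatientFindings]):
    """Cohort as a pandas DataFrame (string/bool columns, one row per patient)."""
    import pandas as pd

    return pd.DataFrame([_record_to_row(r) for r in records])


def results_to_rows(results: Iterable[StandingResult]) -> list[dict[str, Any]]:
    """Serialize classifier outputs for tabular export."""
    return [
        {
            "worrisome": r.worrisome,
            "label": r.label.value,
            "criterion": r.criterion.value,
            "steps_traversed": "|".join(s.value for s in r.steps_traversed),
        }
        for r in results
    ]


def load_classifier_config(path: str | Path) -> ClassifierConfig:
    """Classifier flags from a YAML mapping (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise FormatError("config must be a YAML mapping")
    known = {"gait_only_when_no_nystagmus", "atypical_positional_is_worrisome", "hit_policy"}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    if "hit_policy" in raw:
        raw["hit_policy"] = HitPolicy(str(raw["hit_policy"]).upper())
    return ClassifierConfig(**raw)
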