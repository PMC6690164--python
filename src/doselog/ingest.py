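"""Domain types of the study database and CSV/JSON readers/writers.

The on-disk layout mirrors the study database schema exactly: one table of
per-injection events and one table of per-patient records, with the original
column names.  Timestamps are ISO-8601 and always UTC (the columns are named
``..._utc``); naive timestamps are interpreted as UTC, and no local-time
conversion happens anywhere in the pipeline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from doselog.errors import IntegrityError, RowValidationError, SchemaError

DOSE_LEVELS = (0.25, 0.5, 0.75, 1.0)
NEEDLE_DEPTHS = (8, 10, 12)
INJECTION_SPEEDS = ("low", "medium", "high")
SOURCES = ("autoinjector", "manual")
UNKNOWN_SITE = "unknown"

INJECTION_COLUMNS = (
    "patient_id",
    "injection_date_timestamp_utc",
    "dose",
    "injection_site",
    "flag_manual_autoinjector",
    "needle_depth",
    "injection_speed",
)
PATIENT_COLUMNS = (
    "patient_id",
    "acceptance_date_utc",
    "first_injection_date_utc",
    "age",
    "gender",
    "complete_wellness_number",
)

Dialect = Literal["csv", "json"]


@dataclass(frozen=True)
class InjectionRecord:
    """One raw injection event, device-recorded or manually entered.

    ``needle_depth`` and ``injection_speed`` are device parameters and may be
    absent on manually entered records.  ``injection_site`` uses the sentinel
    ``"unknown"`` when the device could not record a site.
    """

    patient_id: str
    timestamp: datetime
    dose: float
    injection_site: str = UNKNOWN_SITE
    source: str = "autoinjector"
    needle_depth: Optional[int] = None
    injection_speed: Optional[str] = None

    def __post_init__(self) -> None:
        if self.timestamp.tzinfo is None:
            object.__setattr__(
                self, "timestamp", self.timestamp.replace(tzinfo=timezone.utc)
            )
        else:
            object.__setattr__(
                self, "timestamp", self.timestamp.astimezone(timezone.utc)
            )
        if self.dose not in DOSE_LEVELS:
            raise ValueError(f"dose {self.dose!r} not in {DOSE_LEVELS}")
        if self.source not in SOURCES:
            raise ValueError(f"source {self.source!r} not in {SOURCES}")
        if self.needle_depth is not None and self.needle_depth not in NEEDLE_DEPTHS:
            raise ValueError(f"needle_depth {self.needle_depth!r} not in {NEEDLE_DEPTHS}")
        if self.injection_speed is not None and self.injection_speed not in INJECTION_SPEEDS:
            raise ValueError(
                f"injection_speed {self.injection_speed!r} not in {INJECTION_SPEEDS}"
            )

    @property
    def day(self) -> date:
        """UTC calendar day of the event."""
        return self.timestamp.date()

    @property
    def site_known(self) -> bool:
        return self.injection_site.strip().lower() not in ("", UNKNOWN_SITE)


@dataclass(frozen=True)
class PatientRecord:
    """Consent date, demographics and wellness-tracker entry count.

    ``first_injection_date`` is carried through from the database schema but
    is never consumed by any computation.
    """

    patient_id: str
    acceptance_date: date
    age: int
    gender: str
    complete_wellness_number: int
    first_injection_date: Optional[date] = None

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValueError(f"age {self.age} < 18 (adult patients only)")
        if self.gender not in ("M", "F"):
            raise ValueError(f"gender {self.gender!r} not in ('M', 'F')")
        if self.complete_wellness_number < 0:
            raise ValueError("complete_wellness_number must be >= 0")


@dataclass
class Cohort:
    """Patients plus their injection events, keyed consistently."""

    patients: list[PatientRecord] = field(default_factory=list)
    injections: list[InjectionRecord] = field(default_factory=list)

    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def injections_for(self, patient_id: str) -> list[InjectionRecord]:
        return [r for r in self.injections if r.patient_id == patient_id]


# ---------------------------------------------------------------------------
# parsing helpers

_FLAG_TO_SOURCE = {"autoinjector": "autoinjector", "manual": "manual"}
_SOURCE_TO_FLAG = {"autoinjector": "Autoinjector", "manual": "Manual"}


def _parse_timestamp(raw: str, row: int) -> datetime:
    try:
        ts = datetime.fromisoformat(raw.replace("Z", "+00:00"))
    except ValueError as exc:
        raise RowValidationError(row, f"unparseable timestamp {raw!r}") from exc
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _parse_date(raw: str, row: int, column: str) -> date:
    try:
        return date.fromisoformat(raw[:10])
    except ValueError as exc:
        raise RowValidationError(row, f"unparseable {column} {raw!r}") from exc


def _parse_injection_row(row_num: int, row: dict[str, str]) -> InjectionRecord:
    raw_dose = row["dose"].strip()
    try:
        dose = float(raw_dose)
    except ValueError:
        raise RowValidationError(row_num, f"unparseable dose {raw_dose!r}")
    flag = row["flag_manual_autoinjector"].strip().lower()
    if flag not in _FLAG_TO_SOURCE:
        raise RowValidationError(
            row_num, f"flag_manual_autoinjector {row['flag_manual_autoinjector']!r}"
        )
    depth_raw = row.get("needle_depth", "").strip()
    speed_raw = row.get("injection_speed", "").strip()
    try:
        return InjectionRecord(
            patient_id=row["patient_id"].strip(),
            timestamp=_parse_timestamp(row["injection_date_timestamp_utc"].strip(), row_num),
            dose=dose,
            injection_site=row["injection_site"].strip() or UNKNOWN_SITE,
            source=_FLAG_TO_SOURCE[flag],
            needle_depth=int(depth_raw) if depth_raw else None,
            injection_speed=speed_raw.lower() if speed_raw else None,
        )
    except ValueError as exc:
        raise RowValidationError(row_num, str(exc)) from exc


def _parse_patient_row(row_num: int, row: dict[str, str]) -> PatientRecord:
    try:
        age = int(row["age"].strip())
        wellness = int(row["complete_wellness_number"].strip() or "0")
    except ValueError as exc:
        raise RowValidationError(row_num, str(exc)) from exc
    first_raw = row.get("first_injection_date_utc", "").strip()
    try:
        return PatientRecord(
            patient_id=row["patient_id"].strip(),
            acceptance_date=_parse_date(row["acceptance_date_utc"].strip(), row_num,
                                        "acceptance_date_utc"),
            first_injection_date=(
                _parse_date(first_raw, row_num, "first_injection_date_utc")
                if first_raw else None
            ),
            age=age,
            gender=row["gender"].strip(),
            complete_wellness_number=wellness,
        )
    except ValueError as exc:
        raise RowValidationError(row_num, str(exc)) from exc


def _load_rows(path: Path, dialect: Dialect, required: Sequence[str]) -> list[dict[str, str]]:
    if dialect == "csv":
        try:
            frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        except pd.errors.EmptyDataError:
            raise SchemaError(f"{path}: file has no header row")
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        return frame.to_dict(orient="records")
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(payload, list):
        raise SchemaError(f"{path}: JSON payload must be an array of objects")
    rows: list[dict[str, str]] = []
    for obj in payload:
        missing = [c for c in required if c not in obj]
        if missing:
            raise SchemaError(f"{path}: object missing required key(s) {missing}")
        rows.append({k: ("" if v is None else str(v)) for k, v in obj.items()})
    return rows


def _infer_dialect(path: Path, dialect: Optional[Dialect]) -> Dialect:
    if dialect is not None:
        return dialect
    return "json" if Path(path).suffix.lower() == ".json" else "csv"


# ---------------------------------------------------------------------------
# public readers / writers


def read_injections(path, dialect: Optional[Dialect] = None) -> list[InjectionRecord]:
    """Read injection events from a CSV or JSON file, order-preserving.

    Raises :class:`SchemaError` for missing columns and
    :class:`RowValidationError` (with the 1-based data-row number) for bad
    values.  A header-only file yields an empty list.
    """
    path = Path(path)
    rows = _load_rows(path, _infer_dialect(path, dialect), INJECTION_COLUMNS)
    return [_parse_injection_row(i, row) for i, row in enumerate(rows, start=1)]


def read_patients(path, dialect: Optional[Dialect] = None) -> list[PatientRecord]:
    """Read patient records; duplicate ``patient_id`` raises IntegrityError."""
    path = Path(path)
    rows = _load_rows(path, _infer_dialect(path, dialect), PATIENT_COLUMNS)
    patients = [_parse_patient_row(i, row) for i, row in enumerate(rows, start=1)]
    seen: set[str] = set()
    dupes = sorted({p.patient_id for p in patients
                    if p.patient_id in seen or seen.add(p.patient_id)})
    if dupes:
        raise IntegrityError(f"duplicate patient_id(s): {dupes}")
    return patients


def _injection_to_row(rec: InjectionRecord) -> dict[str, str]:
    return {
        "patient_id": rec.patient_id,
        "injection_date_timestamp_utc": rec.timestamp.strftime("%Y-%m-%dT%H:%M:%SZ"),
        "dose": f"{rec.dose:.2f}",
        "injection_site": rec.injection_site,
        "flag_manual_autoinjector": _SOURCE_TO_FLAG[rec.source],
        "needle_depth": "" if rec.needle_depth is None else str(rec.needle_depth),
        "injection_speed": rec.injection_speed or "",
    }


def _patient_to_row(rec: PatientRecord) -> dict[str, str]:
    return {
        "patient_id": rec.patient_id,
        "acceptance_date_utc": rec.acceptance_date.isoformat(),
        "first_injection_date_utc": (
            "" if rec.first_injection_date is None else rec.first_injection_date.isoformat()
        ),
        "age": str(rec.age),
        "gender": rec.gender,
        "complete_wellness_number": str(rec.complete_wellness_number),
    }


def _write_rows(rows: list[dict[str, str]], columns: Sequence[str], path,
                dialect: Optional[Dialect]) -> None:
    path = Path(path)
    resolved = _infer_dialect(path, dialect)
    if resolved == "csv":
        pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False)
    else:
        path.write_text(json.dumps(rows, indent=1) + "\n", encoding="utf-8")


def write_injections(records: Iterable[InjectionRecord], path,
                     dialect: Optional[Dialect] = None) -> None:
    """Write injection events in the study-database column layout."""
    _write_rows([_injection_to_row(r) for r in records], INJECTION_COLUMNS, path, dialect)


def write_patients(records: Iterable[PatientRecord], path,
                   dialect: Optional[Dialect] = None) -> None:
    """Write patient records in the study-database column layout."""
    _write_rows([_patient_to_row(r) for r in records], PATIENT_COLUMNS, path, dialect)


def assemble_cohort(patients: Sequence[PatientRecord],
                    injections: Sequence[InjectionRecord]) -> Cohort:
    """Join patients with their injections.

    Injections whose ``patient_id`` does not resolve to a patient are
    excluded with a warning (not an error): orphan events can arise from
    withdrawal of consent after data export.
    """
    known = {p.patient_id for p in patients}
    kept = [r for r in injections if r.patient_id in known]
    n_dropped = len(injections) - len(kept)
    if n_dropped:
        warnings.warn(
            f"excluded {n_dropped} injection record(s) with unknown patient_id",
            stacklevel=2,
        )
    return Cohort(patients=list(patients), injections=kept)
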