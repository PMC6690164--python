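"""Observation windows, dose schedules and per-patient adherence metrics.

Definitions (the study's per-patient outcomes):

* **Persistence** — the patient was still injecting at the end of the
  6-month observation window.  Event logs cannot distinguish stopping
  therapy from stopping documentation, so persistence is operationalised as
  at least one cleaned injection day within the final ``gap_days`` (default
  14, i.e. 7 scheduled doses of slack) of the window.
* **Compliance** — percentage of expected doses actually injected:
  ``100 × injected_days / expected_doses``.  The numerator counts distinct
  cleaned injection days inside the window, including off-schedule days, so
  compliance can exceed 100%.
* **Adherence** — persistent AND compliance ≥ 80% (boundary inclusive).

The window is anchored at the first cleaned injection day and spans a fixed
180 days (6 months); the every-other-day regimen gives
``ceil(180 / 2) = 90`` expected doses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta

from doselog.cleaning import CleanedLog
from doselog.errors import EmptyLogError, ParameterError, UndefinedMetricError

DEFAULT_MEDICATION_DAYS = 180
DEFAULT_WELLNESS_DAYS = 90
DEFAULT_INTERVAL_DAYS = 2
DEFAULT_GAP_DAYS = 14
DEFAULT_ADHERENCE_THRESHOLD = 80.0


@dataclass(frozen=True)
class ObservationWindow:
    """Half-open per-patient interval [start_day, end_day)."""

    start_day: date
    medication_days: int = DEFAULT_MEDICATION_DAYS
    wellness_days: int = DEFAULT_WELLNESS_DAYS

    def __post_init__(self) -> None:
        if self.medication_days <= 0:
            raise ParameterError("medication_days must be > 0")
        if self.wellness_days > self.medication_days:
            raise ParameterError("wellness_days must be <= medication_days")

    @property
    def end_day(self) -> date:
        return self.start_day + timedelta(days=self.medication_days)

    def contains(self, day: date) -> bool:
        return self.start_day <= day < self.end_day


@dataclass(frozen=True)
class ScheduleModel:
    """Dosing schedule: a dose every ``interval_days``, anchored at day 0.

    ``anchor_policy`` may be ``window_start`` or ``first_injection``; the two
    coincide here because the window starts at the first injection day.
    """

    interval_days: int = DEFAULT_INTERVAL_DAYS
    anchor_policy: str = "window_start"

    def __post_init__(self) -> None:
        if self.interval_days < 1:
            raise ParameterError("interval_days must be >= 1")
        if self.anchor_policy not in ("window_start", "first_injection"):
            raise ParameterError(f"unknown anchor_policy {self.anchor_policy!r}")

    def scheduled_days(self, window: ObservationWindow) -> list[date]:
        """Enumerate the scheduled calendar days inside the window."""
        return [
            window.start_day + timedelta(days=k)
            for k in range(0, window.medication_days, self.interval_days)
        ]


@dataclass(frozen=True)
class AdherenceResult:
    """Per-patient outcome bundle."""

    patient_id: str
    persistent: bool
    compliance_pct: float
    adherent: bool
    injected_days: int
    expected_doses: int


def build_window(
    cleaned_log: CleanedLog,
    medication_days: int = DEFAULT_MEDICATION_DAYS,
    wellness_days: int = DEFAULT_WELLNESS_DAYS,
) -> ObservationWindow:
    """Anchor a fixed-length window at the earliest cleaned injection day."""
    if not cleaned_log.entries:
        raise EmptyLogError(
            f"patient {cleaned_log.patient_id}: no injection days; no window"
        )
    return ObservationWindow(
        start_day=min(cleaned_log.entries),
        medication_days=medication_days,
        wellness_days=wellness_days,
    )


def expected_doses(window: ObservationWindow, schedule: ScheduleModel) -> int:
    """Number of scheduled days in [start, end): ceil(length / interval)."""
    return math.ceil(window.medication_days / schedule.interval_days)


def injected_days_in_window(cleaned_log: CleanedLog, window: ObservationWindow) -> int:
    return sum(1 for day in cleaned_log.entries if window.contains(day))


def compliance(
    cleaned_log: CleanedLog, window: ObservationWindow, schedule: ScheduleModel
) -> float:
    """Percentage of expected doses injected; NOT capped at 100."""
    n_expected = expected_doses(window, schedule)
    if n_expected <= 0:
        raise UndefinedMetricError("zero expected doses")
    return 100.0 * injected_days_in_window(cleaned_log, window) / n_expected


def persistence(
    cleaned_log: CleanedLog,
    window: ObservationWindow,
    gap_days: int = DEFAULT_GAP_DAYS,
) -> bool:
    """True iff some injection day lies in the terminal [end−gap, end)."""
    cutoff = window.end_day - timedelta(days=gap_days)
    return any(
        cutoff <= day < window.end_day
        for day in cleaned_log.entries
        if window.contains(day)
    )


def adherence(
    persistent: bool,
    compliance_pct: float,
    threshold: float = DEFAULT_ADHERENCE_THRESHOLD,
) -> bool:
    """Persistent and at least ``threshold``% compliant (inclusive)."""
    return bool(persistent and compliance_pct >= threshold)


def compute_adherence(
    cleaned_log: CleanedLog,
    medication_days: int = DEFAULT_MEDICATION_DAYS,
    wellness_days: int = DEFAULT_WELLNESS_DAYS,
    schedule: ScheduleModel | None = None,
    gap_days: int = DEFAULT_GAP_DAYS,
    threshold: float = DEFAULT_ADHERENCE_THRESHOLD,
) -> AdherenceResult:
    """Full per-patient pipeline: window → expected doses → the three metrics."""
    schedule = schedule or ScheduleModel()
    window = build_window(cleaned_log, medication_days, wellness_days)
    n_expected = expected_doses(window, schedule)
    comp = compliance(cleaned_log, window, schedule)
    persist = persistence(cleaned_log, window, gap_days)
    return AdherenceResult(
        patient_id=cleaned_log.patient_id,
        persistent=persist,
        compliance_pct=comp,
        adherent=adherence(persist, comp, threshold),
        injected_days=injected_days_in_window(cleaned_log, window),
        expected_doses=n_expected,
    )
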