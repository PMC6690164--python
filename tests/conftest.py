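"""Shared fixtures and record builders."""

from __future__ import annotations

from datetime import datetime, timezone

import pytest

from doselog.ingest import InjectionRecord, PatientRecord


def make_injection(
    patient_id: str = "p1",
    when: str = "2017-09-01T08:00:00",
    dose: float = 1.0,
    site: str = "unknown",
    source: str = "autoinjector",
    needle_depth: int | None = 10,
    injection_speed: str | None = "medium",
) -> InjectionRecord:
    if source == "manual":
        needle_depth = None
        injection_speed = None
    return InjectionRecord(
        patient_id=patient_id,
        timestamp=datetime.fromisoformat(when).replace(tzinfo=timezone.utc),
        dose=dose,
        injection_site=site,
        source=source,
        needle_depth=needle_depth,
        injection_speed=injection_speed,
    )


def make_patient(
    patient_id: str = "p1",
    age: int = 46,
    gender: str = "F",
    wellness: int = 0,
) -> PatientRecord:
    from datetime import date

    return PatientRecord(
        patient_id=patient_id,
        acceptance_date=date(2017, 9, 15),
        age=age,
        gender=gender,
        complete_wellness_number=wellness,
    )


@pytest.fixture
def three_rule_fixture() -> list[InjectionRecord]:
    """A raw log exercising all three cleaning rules at once.

    Patient p1:
      day 1 — exact duplicate pair (rule 1 removes one);
      day 2 — three autoinjector entries at 08:00/09:00/21:00 (rule 2 keeps
              21:00);
      day 3 — autoinjector with unknown site + manual naming a site
              (rule 3 keeps the device record, substitutes the site).
    Patient p2: a single manual record, untouched.
    """
    return [
        make_injection("p1", "2017-09-01T08:00:00", site="abdomen left"),
        make_injection("p1", "2017-09-01T08:00:00", site="abdomen left"),
        make_injection("p1", "2017-09-02T08:00:00", site="left arm"),
        make_injection("p1", "2017-09-02T09:00:00", site="right arm"),
        make_injection("p1", "2017-09-02T21:00:00", site="left thigh"),
        make_injection("p1", "2017-09-03T07:30:00", site="unknown"),
        make_injection("p1", "2017-09-03T08:00:00", site="right thigh", source="manual"),
        make_injection("p2", "2017-09-02T10:00:00", site="abdomen right", source="manual"),
    ]
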