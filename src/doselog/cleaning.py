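"""Deterministic cleaning of raw injection event logs.

Multiple records can exist for one patient-day: re-synchronisation of the
autoinjector can replay events, and patients may document an injection
manually on top of the device record.  Cleaning reduces the raw log to at
most one record per patient per UTC calendar day by applying, in order:

1. **Exact duplicates** — records identical in every field collapse to one.
2. **Multiple entries per day and source** — within each
   (patient, day, source) group, only the last entry ordered by time is
   kept.  Timestamp ties keep the later record in input order.
3. **Mixed sources on one day** — the autoinjector record wins over the
   manual one; if the device recorded the site as "unknown" and the manual
   record names a site, that site is substituted into the retained record.
   A known device site is kept even when the manual site differs.

No cleaning happens beyond these rules: near-duplicates or implausible
records pass through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date
from typing import Iterable, Sequence

from doselog.errors import InvariantError
from doselog.ingest import InjectionRecord

PROVENANCE_AUTOINJECTOR_ONLY = "autoinjector_only"
PROVENANCE_MANUAL_ONLY = "manual_only"
PROVENANCE_MIXED = "mixed"


@dataclass
class CleanedLog:
    """Per-patient cleaned injection series: exactly one record per day.

    ``provenance_summary`` classifies the patient's ORIGINAL (pre-cleaning)
    records as autoinjector-only, manual-only or mixed; the sensitivity
    analysis selects on it.
    """

    patient_id: str
    entries: dict[date, InjectionRecord] = field(default_factory=dict)
    provenance_summary: str = PROVENANCE_AUTOINJECTOR_ONLY

    def days(self) -> list[date]:
        return sorted(self.entries)

    def records(self) -> list[InjectionRecord]:
        return [self.entries[d] for d in self.days()]


@dataclass
class CleaningReport:
    """Counts of records removed by each cleaning rule."""

    n_input: int = 0
    removed_duplicates: int = 0
    removed_same_day: int = 0
    removed_merge: int = 0

    @property
    def n_output(self) -> int:
        return (self.n_input - self.removed_duplicates
                - self.removed_same_day - self.removed_merge)


def drop_exact_duplicates(records: Sequence[InjectionRecord]) -> list[InjectionRecord]:
    """Collapse field-identical records to their first occurrence."""
    seen: set[InjectionRecord] = set()
    out: list[InjectionRecord] = []
    for rec in records:
        if rec not in seen:
            seen.add(rec)
            out.append(rec)
    return out


def last_entry_per_day(records: Sequence[InjectionRecord]) -> list[InjectionRecord]:
    """Keep only the latest entry per (patient, UTC day, source) group.

    Ties on timestamp keep the record appearing later in input order, so the
    result is deterministic for any input.  Output preserves the input order
    of the surviving records.
    """
    best: dict[tuple[str, date, str], tuple[int, InjectionRecord]] = {}
    for idx, rec in enumerate(records):
        key = (rec.patient_id, rec.day, rec.source)
        incumbent = best.get(key)
        # >= implements the later-in-input-order tie-break
        if incumbent is None or rec.timestamp >= incumbent[1].timestamp:
            best[key] = (idx, rec)
    return [rec for _, rec in sorted(best.values(), key=lambda t: t[0])]


def provenance_summary(records: Sequence[InjectionRecord]) -> str:
    """Classify a patient's records by source over the whole period."""
    sources = {rec.source for rec in records}
    if sources == {"autoinjector"}:
        return PROVENANCE_AUTOINJECTOR_ONLY
    if sources == {"manual"}:
        return PROVENANCE_MANUAL_ONLY
    return PROVENANCE_MIXED


def merge_sources(
    records: Sequence[InjectionRecord],
    original_records: Sequence[InjectionRecord] | None = None,
) -> dict[str, CleanedLog]:
    """Resolve mixed-source days and build per-patient cleaned logs.

    Expects at most one autoinjector and one manual record per patient-day
    (the earlier stages guarantee this).  ``original_records`` supplies the
    pre-cleaning records used for the provenance summary; it defaults to the
    input itself.
    """
    grouped: dict[tuple[str, date], dict[str, InjectionRecord]] = {}
    for rec in records:
        slot = grouped.setdefault((rec.patient_id, rec.day), {})
        if rec.source in slot:
            raise InvariantError(
                f"two {rec.source} records for {rec.patient_id} on {rec.day}; "
                "run last_entry_per_day first"
            )
        slot[rec.source] = rec

    logs: dict[str, CleanedLog] = {}
    for (patient_id, day), slot in grouped.items():
        if "autoinjector" in slot:
            kept = slot["autoinjector"]
            manual = slot.get("manual")
            if manual is not None and not kept.site_known and manual.site_known:
                kept = replace(kept, injection_site=manual.injection_site)
        else:
            kept = slot["manual"]
        logs.setdefault(patient_id, CleanedLog(patient_id=patient_id)).entries[day] = kept

    for patient_id, log in logs.items():
        pool = original_records if original_records is not None else records
        log.provenance_summary = provenance_summary(
            [r for r in pool if r.patient_id == patient_id]
        )
    return logs


def clean(
    records: Sequence[InjectionRecord],
    report: CleaningReport | None = None,
) -> dict[str, CleanedLog]:
    """Apply the full three-rule cleaning procedure.

    Returns cleaned logs keyed by patient id.  Pass a
    :class:`CleaningReport` to collect per-rule removal counts.
    """
    records = list(records)
    deduped = drop_exact_duplicates(records)
    last = last_entry_per_day(deduped)
    logs = merge_sources(last, original_records=records)
    if report is not None:
        report.n_input = len(records)
        report.removed_duplicates = len(records) - len(deduped)
        report.removed_same_day = len(deduped) - len(last)
        report.removed_merge = len(last) - sum(len(l.entries) for l in logs.values())
    return logs


def cleaned_records(logs: dict[str, CleanedLog]) -> list[InjectionRecord]:
    """Flatten cleaned logs back to a record list (patient, then day order)."""
    out: list[InjectionRecord] = []
    for patient_id in sorted(logs):
        out.extend(logs[patient_id].records())
    return out


def flatten_and_reclean(logs: Iterable[CleanedLog]) -> dict[str, CleanedLog]:
    """Re-run cleaning on already-cleaned logs (used to check idempotence)."""
    records = [rec for log in logs for rec in log.records()]
    return clean(records)
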