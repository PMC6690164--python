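"""Brute-force cleaning oracle, independent of the library implementation.

Applies the three cleaning rules by literal enumeration over
(patient, day) groups; used to cross-check ``doselog.cleaning.clean`` on
arbitrary inputs.  Deliberately naive: quadratic scans, no shared helpers.
"""

from __future__ import annotations

from dataclasses import replace
from datetime import date

from doselog.ingest import InjectionRecord


def brute_force_clean(records: list[InjectionRecord]) -> dict[tuple[str, date], InjectionRecord]:
    # rule 1: exact duplicates -> first occurrence
    deduped: list[InjectionRecord] = []
    for rec in records:
        if not any(rec == kept for kept in deduped):
            deduped.append(rec)

    # rule 2: per (patient, day, source) keep the max-timestamp entry,
    # later input position winning ties
    survivors: list[InjectionRecord] = []
    for idx, rec in enumerate(deduped):
        beaten = False
        for jdx, other in enumerate(deduped):
            if (other.patient_id, other.day, other.source) != (
                rec.patient_id, rec.day, rec.source
            ):
                continue
            if other.timestamp > rec.timestamp:
                beaten = True
            elif other.timestamp == rec.timestamp and jdx > idx:
                beaten = True
        if not beaten:
            survivors.append(rec)

    # rule 3: autoinjector beats manual; substitute site only if device
    # site is unknown and the manual site is known
    out: dict[tuple[str, date], InjectionRecord] = {}
    days = {(r.patient_id, r.day) for r in survivors}
    for key in days:
        group = [r for r in survivors if (r.patient_id, r.day) == key]
        autos = [r for r in group if r.source == "autoinjector"]
        manuals = [r for r in group if r.source == "manual"]
        assert len(autos) <= 1 and len(manuals) <= 1
        if autos:
            kept = autos[0]
            if manuals and not kept.site_known and manuals[0].site_known:
                kept = replace(kept, injection_site=manuals[0].injection_site)
        else:
            kept = manuals[0]
        out[key] = kept
    return out
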