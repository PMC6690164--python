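"""Persistence, compliance and adherence for two contrasting patients.

Patient A injects on every scheduled day plus six extra days (compliance
above 100%); patient B stops injecting after day 120 (not persistent, so
not adherent regardless of compliance).
"""

from datetime import date, datetime, timedelta, timezone

from doselog import InjectionRecord, clean, compute_adherence

START = date(2017, 9, 1)


def day_record(pid, offset):
    day = START + timedelta(days=offset)
    return InjectionRecord(
        patient_id=pid,
        timestamp=datetime(day.year, day.month, day.day, 8, tzinfo=timezone.utc),
        dose=1.0,
        needle_depth=10,
        injection_speed="medium",
    )


records = [day_record("A", k) for k in list(range(0, 180, 2)) + [1, 3, 5, 7, 9, 11]]
records += [day_record("B", k) for k in range(0, 120, 2)]

for pid, log in sorted(clean(records).items()):
    r = compute_adherence(log)  # 180-day window, every-other-day, gap 14, 80%
    print(f"patient {pid}: {r.injected_days} injection days / "
          f"{r.expected_doses} expected doses")
    print(f"  compliance {r.compliance_pct:.1f}%  persistent={r.persistent}  "
          f"adherent={r.adherent}")

# A: 96/90 -> 106.7% compliant, persistent, adherent.  B: 60/90 -> 66.7%,
# no injection in the final 14 days -> not persistent, hence not adherent.
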