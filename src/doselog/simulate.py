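"""Synthetic cohort generator.

Emulates the behavioural and data-quality structure of an app-based
injection-log database so that every pipeline stage can be exercised
without access to real patient data:

* every-other-day dosing with a per-dose miss probability;
* permanent treatment discontinuation (geometric stopping day) and,
  separately, documentation abandonment (the patient keeps injecting but
  the log stops — the two are indistinguishable in the data, which is
  exactly the confound the persistence metric inherits);
* occasional off-schedule extra injections (compliance can exceed 100%);
* exact duplicates and same-day re-synchronisation records from the device;
* mixed autoinjector/manual documentation, manual-only patients, and
  "unknown" injection sites on device records;
* sparse wellness-tracker usage with a zero-truncated entry count.

All randomness flows from a single seed through per-patient substreams, so
cohorts are bit-reproducible and individual patients can be re-simulated in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone

import numpy as np

from doselog.errors import ParameterError
from doselog.ingest import Cohort, InjectionRecord, PatientRecord, UNKNOWN_SITE

INJECTION_SITES = (
    "left thigh", "right thigh", "left arm", "right arm",
    "abdomen left", "abdomen right", "left buttock", "right buttock",
)

# Age-band mixture and band bounds used by the default demographic generator.
_AGE_BANDS = ((18, 30), (30, 40), (40, 50), (50, 60), (60, 75))
_AGE_BAND_PROBS = (0.11, 0.24, 0.34, 0.16, 0.15)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a cohort like the one the pipeline was designed for:
    high compliance (per-dose injection probability 0.93), rare permanent
    discontinuation (per-day hazard 2.5e-4, ≈96% still active two weeks
    before the 180-day window closes), 53% female, 57%/15%/28%
    autoinjector-only / manual-only / mixed documentation, 21% wellness
    users with a mean of ~3.1 entries.
    """

    n_patients: int = 94
    p_inject: float = 0.93
    discontinuation_hazard: float = 0.00025
    documentation_stop_hazard: float = 0.0
    p_offschedule: float = 0.02
    duplicate_rate: float = 0.05
    resync_rate: float = 0.05
    p_manual_user: float = 26 / 80  # among non-(manual-only) patients → 28% mixed overall
    p_manual_only: float = 14 / 94
    p_manual_doc: float = 0.3  # per-day manual documentation prob for mixed users
    p_site_unknown: float = 0.3
    wellness_user_prob: float = 20 / 94
    wellness_mean: float = 3.1  # mean of the zero-truncated geometric entry count
    age_dist: tuple[float, ...] = _AGE_BAND_PROBS
    gender_prob: float = 50 / 94  # probability of female
    medication_days: int = 180
    start_window: tuple[str, str] = ("2017-06-01", "2017-12-01")
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "p_inject": self.p_inject,
            "p_offschedule": self.p_offschedule,
            "duplicate_rate": self.duplicate_rate,
            "resync_rate": self.resync_rate,
            "p_manual_user": self.p_manual_user,
            "p_manual_only": self.p_manual_only,
            "p_manual_doc": self.p_manual_doc,
            "p_site_unknown": self.p_site_unknown,
            "wellness_user_prob": self.wellness_user_prob,
            "gender_prob": self.gender_prob,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ParameterError(f"{name}={value} outside [0, 1]")
        for name in ("discontinuation_hazard", "documentation_stop_hazard"):
            value = getattr(self, name)
            if not 0.0 <= value < 1.0:
                raise ParameterError(f"{name}={value} outside [0, 1)")
        if self.n_patients < 0:
            raise ParameterError("n_patients must be >= 0")
        if self.medication_days <= 0:
            raise ParameterError("medication_days must be > 0")
        if abs(sum(self.age_dist) - 1.0) > 1e-9:
            raise ParameterError("age_dist must sum to 1")
        if self.wellness_mean < 1.0:
            raise ParameterError("wellness_mean must be >= 1 (zero-truncated count)")


def _stop_day(hazard: float, rng: np.random.Generator) -> float:
    """Geometric stopping day: P(stop day > d) = (1 - hazard)^d; ∞ if hazard 0."""
    if hazard <= 0.0:
        return np.inf
    return float(rng.geometric(hazard))


def _timestamp(day: date, rng: np.random.Generator) -> datetime:
    """A time of day between 06:00 and 22:59 UTC."""
    return datetime(
        day.year, day.month, day.day,
        int(rng.integers(6, 23)), int(rng.integers(0, 60)), int(rng.integers(0, 60)),
        tzinfo=timezone.utc,
    )


def _device_record(pid: str, day: date, cfg: SimulationConfig,
                   rng: np.random.Generator) -> InjectionRecord:
    site = (UNKNOWN_SITE if rng.random() < cfg.p_site_unknown
            else INJECTION_SITES[int(rng.integers(len(INJECTION_SITES)))])
    return InjectionRecord(
        patient_id=pid,
        timestamp=_timestamp(day, rng),
        dose=1.0,
        injection_site=site,
        source="autoinjector",
        needle_depth=int(rng.choice([8, 10, 12])),
        injection_speed=str(rng.choice(["low", "medium", "high"])),
    )


def _manual_record(pid: str, day: date, rng: np.random.Generator) -> InjectionRecord:
    return InjectionRecord(
        patient_id=pid,
        timestamp=_timestamp(day, rng),
        dose=1.0,
        injection_site=INJECTION_SITES[int(rng.integers(len(INJECTION_SITES)))],
        source="manual",
    )


def simulate_patient(
    config: SimulationConfig,
    rng: np.random.Generator,
    patient_id: str = "p001",
) -> tuple[PatientRecord, list[InjectionRecord]]:
    """Simulate one patient: demographics, wellness count and raw event log.

    The raw log contains the contamination the cleaning stage exists for
    (exact duplicates, same-day re-sync records, redundant manual entries);
    none of it adds injection *days*, so cleaned metrics reflect only the
    latent behaviour (misses, discontinuation, off-schedule extras).
    """
    band = _AGE_BANDS[int(rng.choice(len(_AGE_BANDS), p=list(config.age_dist)))]
    age = int(rng.integers(band[0], band[1]))
    gender = "F" if rng.random() < config.gender_prob else "M"

    lo = date.fromisoformat(config.start_window[0])
    hi = date.fromisoformat(config.start_window[1])
    start = lo + timedelta(days=int(rng.integers(0, max((hi - lo).days, 1))))

    manual_only = rng.random() < config.p_manual_only
    mixed = (not manual_only) and rng.random() < config.p_manual_user

    stop = min(_stop_day(config.discontinuation_hazard, rng),
               _stop_day(config.documentation_stop_hazard, rng))

    records: list[InjectionRecord] = []
    for t in range(config.medication_days):
        if t >= stop:
            break
        scheduled = t % 2 == 0
        if scheduled:
            injected = rng.random() < config.p_inject
        else:
            injected = rng.random() < config.p_offschedule
        if not injected:
            continue
        day = start + timedelta(days=t)
        if manual_only:
            records.append(_manual_record(patient_id, day, rng))
        else:
            rec = _device_record(patient_id, day, config, rng)
            records.append(rec)
            if rng.random() < config.resync_rate:
                # re-sync replays the day with a later upload timestamp
                later = rec.timestamp + timedelta(minutes=int(rng.integers(1, 60)))
                records.append(InjectionRecord(
                    patient_id=patient_id, timestamp=later, dose=rec.dose,
                    injection_site=rec.injection_site, source="autoinjector",
                    needle_depth=rec.needle_depth, injection_speed=rec.injection_speed,
                ))
            if mixed and rng.random() < config.p_manual_doc:
                records.append(_manual_record(patient_id, day, rng))
        if rng.random() < config.duplicate_rate:
            records.append(records[-1])

    wellness = 0
    if rng.random() < config.wellness_user_prob:
        # zero-truncated geometric: support {1, 2, ...}, mean = wellness_mean
        wellness = int(rng.geometric(1.0 / config.wellness_mean))

    patient = PatientRecord(
        patient_id=patient_id,
        acceptance_date=start + timedelta(days=int(rng.integers(0, 90))),
        first_injection_date=records[0].day if records else None,
        age=age,
        gender=gender,
        complete_wellness_number=wellness,
    )
    return patient, records


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate ``n_patients`` independent patients from per-patient substreams."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    patients: list[PatientRecord] = []
    injections: list[InjectionRecord] = []
    width = max(3, len(str(max(config.n_patients, 1))))
    for i, seq in enumerate(seeds, start=1):
        pid = f"p{i:0{width}d}"
        patient, records = simulate_patient(config, np.random.default_rng(seq), pid)
        patients.append(patient)
        injections.extend(records)
    return Cohort(patients=patients, injections=injections)
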