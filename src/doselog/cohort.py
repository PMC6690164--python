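"""Stratified cohort summaries, sensitivity subset and study-size assurance.

Produces the study's three report tables in machine-readable form:

* demographics by age band and gender;
* data-collection patterns (injection provenance, injection-site recording,
  wellness-tracker usage with an entry-count summary among users);
* persistence / compliance / adherence for the main analysis set and the
  autoinjector-only sensitivity set, each stratified Total / Female / Male.

Percentages are rounded half-up — integer display for proportions, one
decimal for compliance — matching the conventions of descriptive cohort
reporting.  Quartiles use linear interpolation of order statistics (the
"type 7" convention); the sample SD uses the n−1 denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from doselog.cleaning import PROVENANCE_AUTOINJECTOR_ONLY, CleanedLog
from doselog.errors import ParameterError, UndefinedMetricError
from doselog.ingest import Cohort, PatientRecord
from doselog.metrics import AdherenceResult

AGE_BIN_LABELS = ("<30", "30-39", "40-49", "50-59", ">=60")
_AGE_BIN_BOUNDS = ((0, 30), (30, 40), (40, 50), (50, 60), (60, 200))


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round half away from zero at ``decimals`` places (display convention)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int, decimals: int = 0) -> float:
    """Percentage ``100·num/den`` rounded half-up to ``decimals`` places."""
    if denominator == 0:
        raise UndefinedMetricError("pct: zero denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)


def assign_age_bin(age: int) -> str:
    """Map an adult age to its reporting band."""
    for label, (lo, hi) in zip(AGE_BIN_LABELS, _AGE_BIN_BOUNDS):
        if lo <= age < hi:
            return label
    raise ParameterError(f"age {age} outside supported range")


@dataclass(frozen=True)
class SevenNumberSummary:
    """Mean (SD) plus the five-number spread of a distribution.

    ``degenerate`` flags n==1 strata, where the SD is reported as 0 by
    convention rather than left undefined.
    """

    n: int
    mean: float
    sd: float
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "n": self.n, "mean": self.mean, "sd": self.sd,
            "minimum": self.minimum, "q1": self.q1, "median": self.median,
            "q3": self.q3, "maximum": self.maximum,
        }


def summarize_compliance(values: Sequence[float]) -> SevenNumberSummary:
    """Seven-number summary: mean, sample SD, min, Q1, median, Q3, max."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise UndefinedMetricError("summarize_compliance: empty input")
    degenerate = arr.size == 1
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return SevenNumberSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=0.0 if degenerate else float(arr.std(ddof=1)),
        minimum=float(arr.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(arr.max()),
        degenerate=degenerate,
    )


def sensitivity_subset(
    cohort: Cohort, cleaned_logs: Mapping[str, CleanedLog]
) -> list[PatientRecord]:
    """Patients whose entire record comes from the autoinjector.

    The sensitivity analysis keeps exactly the patients with a pre-cleaning
    provenance of autoinjector-only; a single manual entry excludes a
    patient.
    """
    subset = [
        p for p in cohort.patients
        if p.patient_id in cleaned_logs
        and cleaned_logs[p.patient_id].provenance_summary == PROVENANCE_AUTOINJECTOR_ONLY
    ]
    if not subset:
        warnings.warn("sensitivity subset is empty: no autoinjector-only patients",
                      stacklevel=2)
    return subset


def wellness_summary(patients: Sequence[PatientRecord]) -> dict:
    """Wellness-tracker usage: users (count ≥ 1) and entries among users."""
    counts = [p.complete_wellness_number for p in patients]
    users = [c for c in counts if c >= 1]
    out: dict = {
        "n_patients": len(patients),
        "n_users": len(users),
        "pct_users": pct(len(users), len(patients)) if patients else None,
        "entries": None,
    }
    if users:
        out["entries"] = summarize_compliance(users).as_dict()
    return out


def precision_assurance(
    n: int,
    sd_assumed: float,
    halfwidth_target: float,
    ci_level: float = 0.95,
) -> float:
    """Probability a planned CI for a mean is at least as narrow as targeted.

    Under a normal model with true SD ``sd_assumed``, the planned two-sided
    ``ci_level`` CI for the mean has half-width z·S/√n with S the sample SD.
    Since (n−1)S²/σ² ~ χ²(n−1), the assurance

        P(z · S/√n ≤ h) = P(χ²(n−1) ≤ (n−1)·n·h² / (z²·σ²))

    is available in closed form.  Returned as a probability in [0, 1].
    """
    if n < 2:
        raise ParameterError("precision_assurance requires n >= 2")
    if sd_assumed <= 0 or halfwidth_target <= 0:
        raise ParameterError("sd_assumed and halfwidth_target must be > 0")
    if not 0 < ci_level < 1:
        raise ParameterError("ci_level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    bound = (n - 1) * n * halfwidth_target**2 / (z**2 * sd_assumed**2)
    return float(stats.chi2.cdf(bound, df=n - 1))


# ---------------------------------------------------------------------------
# report assembly


@dataclass
class CohortReport:
    """Machine-readable report tables plus per-stratum bar-chart data."""

    demographics: pd.DataFrame
    data_patterns: pd.DataFrame
    outcomes: pd.DataFrame
    figure_data: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "demographics": self.demographics,
            "data_patterns": self.data_patterns,
            "outcomes": self.outcomes,
            "figure_data": self.figure_data,
        }

    def to_csv(self, out_dir) -> list[str]:
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, frame in self.tables().items():
            path = out_dir / f"{name}.csv"
            frame.to_csv(path, index=False)
            written.append(str(path))
        return written

    def to_json(self) -> dict:
        return {name: frame.to_dict(orient="records")
                for name, frame in self.tables().items()}

    def render_text(self) -> str:
        blocks = []
        for name, frame in self.tables().items():
            blocks.append(f"== {name} ==\n{frame.to_string(index=False)}")
        return "\n\n".join(blocks)


def _gender_strata(patients: Sequence[PatientRecord]) -> dict[str, list[PatientRecord]]:
    return {
        "Total": list(patients),
        "Female": [p for p in patients if p.gender == "F"],
        "Male": [p for p in patients if p.gender == "M"],
    }


def _demographics_table(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    strata = _gender_strata(patients)
    rows = []
    for label in AGE_BIN_LABELS:
        row: dict = {"age_group": label}
        for stratum, members in strata.items():
            in_bin = [p for p in members if assign_age_bin(p.age) == label]
            row[f"{stratum}_n"] = len(in_bin)
            row[f"{stratum}_pct"] = pct(len(in_bin), len(members)) if members else None
        rows.append(row)
    return pd.DataFrame(rows)


def _patterns_table(
    patients: Sequence[PatientRecord], cleaned_logs: Mapping[str, CleanedLog]
) -> pd.DataFrame:
    strata = _gender_strata(patients)
    rows = []

    def add(section: str, item: str, counter) -> None:
        row: dict = {"section": section, "item": item}
        for stratum, members in strata.items():
            n = sum(1 for p in members if counter(p))
            row[f"{stratum}_n"] = n
            row[f"{stratum}_pct"] = pct(n, len(members)) if members else None
        rows.append(row)

    def prov(p: PatientRecord) -> str | None:
        log = cleaned_logs.get(p.patient_id)
        return log.provenance_summary if log else None

    add("injection_patterns", "autoinjector_only", lambda p: prov(p) == "autoinjector_only")
    add("injection_patterns", "manual_only", lambda p: prov(p) == "manual_only")
    add("injection_patterns", "mixed", lambda p: prov(p) == "mixed")

    def has_site(p: PatientRecord) -> bool:
        log = cleaned_logs.get(p.patient_id)
        return bool(log) and any(r.site_known for r in log.entries.values())

    add("injection_location", "recorded", has_site)
    add("injection_location", "not_recorded", lambda p: not has_site(p))
    add("wellness_tracker", "user", lambda p: p.complete_wellness_number >= 1)
    add("wellness_tracker", "non_user", lambda p: p.complete_wellness_number == 0)

    for stratum, members in strata.items():
        summary = wellness_summary(members)
        entry_row: dict = {"section": "wellness_entries_per_user", "item": "summary",
                           f"{stratum}_n": summary["n_users"]}
        if summary["entries"]:
            e = summary["entries"]
            entry_row[f"{stratum}_detail"] = (
                f"mean {round_half_up(e['mean'], 1)} (SD {round_half_up(e['sd'], 1)}), "
                f"min {e['minimum']:g}, Q1 {e['q1']:g}, median {e['median']:g}, "
                f"Q3 {e['q3']:g}, max {e['maximum']:g}"
            )
        rows.append(entry_row)
    return pd.DataFrame(rows)


def _outcomes_rows(
    analysis_set: str,
    patients: Sequence[PatientRecord],
    results: Mapping[str, AdherenceResult],
) -> list[dict]:
    rows = []
    for stratum, members in _gender_strata(patients).items():
        res = [results[p.patient_id] for p in members if p.patient_id in results]
        row: dict = {"analysis_set": analysis_set, "stratum": stratum, "n": len(res)}
        if not res:
            rows.append(row)
            continue
        n_persist = sum(r.persistent for r in res)
        n_adhere = sum(r.adherent for r in res)
        summary = summarize_compliance([r.compliance_pct for r in res])
        row.update(
            persistent_n=n_persist,
            persistent_pct=pct(n_persist, len(res)),
            compliance_mean=round_half_up(summary.mean, 1),
            compliance_sd=round_half_up(summary.sd, 1),
            compliance_min=round_half_up(summary.minimum, 1),
            compliance_q1=round_half_up(summary.q1, 1),
            compliance_median=round_half_up(summary.median, 1),
            compliance_q3=round_half_up(summary.q3, 1),
            compliance_max=round_half_up(summary.maximum, 1),
            adherent_n=n_adhere,
            adherent_pct=pct(n_adhere, len(res)),
        )
        rows.append(row)
    return rows


def _figure_rows(
    patients: Sequence[PatientRecord], results: Mapping[str, AdherenceResult]
) -> list[dict]:
    strata: dict[str, list[PatientRecord]] = _gender_strata(patients)
    for label in AGE_BIN_LABELS:
        strata[label] = [p for p in patients if assign_age_bin(p.age) == label]
    rows = []
    for stratum, members in strata.items():
        res = [results[p.patient_id] for p in members if p.patient_id in results]
        row: dict = {"stratum": stratum, "n": len(res)}
        if res:
            comp = summarize_compliance([r.compliance_pct for r in res])
            row["mean_compliance"] = round_half_up(comp.mean, 1)
            row["sd_compliance"] = round_half_up(comp.sd, 1)
            row["adherence_pct"] = pct(sum(r.adherent for r in res), len(res))
        rows.append(row)
    return rows


def build_report(
    cohort: Cohort,
    cleaned_logs: Mapping[str, CleanedLog],
    results: Mapping[str, AdherenceResult],
    sensitivity: Sequence[PatientRecord] | None = None,
) -> CohortReport:
    """Assemble all report tables for the main and sensitivity analysis sets.

    ``results`` holds per-patient adherence outcomes for every patient with
    a non-empty cleaned log; patients without results contribute to the
    demographics but not to the outcome summaries.
    """
    if sensitivity is None:
        sensitivity = sensitivity_subset(cohort, cleaned_logs) if cleaned_logs else []
    outcome_rows = _outcomes_rows("main", cohort.patients, results)
    outcome_rows += _outcomes_rows("sensitivity", sensitivity, results)
    return CohortReport(
        demographics=_demographics_table(cohort.patients),
        data_patterns=_patterns_table(cohort.patients, cleaned_logs),
        outcomes=pd.DataFrame(outcome_rows),
        figure_data=pd.DataFrame(_figure_rows(cohort.patients, results)),
    )
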