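"""Stratified summaries, quartiles, sensitivity subset and assurance."""

from __future__ import annotations

import numpy as np
import pytest

from doselog.cleaning import clean
from doselog.cohort import (
    assign_age_bin,
    build_report,
    pct,
    precision_assurance,
    round_half_up,
    sensitivity_subset,
    summarize_compliance,
    wellness_summary,
)
from doselog.errors import ParameterError, UndefinedMetricError
from doselog.ingest import Cohort
from doselog.metrics import compute_adherence

from conftest import make_injection, make_patient


class TestPct:
    @pytest.mark.parametrize(
        "num, den, decimals, expected",
        [
            (96, 1334, 1, 7.2),
            (84, 94, 0, 89),
            (50, 94, 0, 53),
            (0, 94, 0, 0),
        ],
    )
    def test_printed_arithmetic(self, num, den, decimals, expected):
        assert pct(num, den, decimals) == expected

    def test_zero_denominator(self):
        with pytest.raises(UndefinedMetricError):
            pct(1, 0)

    def test_half_up_not_bankers(self):
        # round() would give 0.5 -> 0; display convention is half-up
        assert round_half_up(0.5) == 1
        assert round_half_up(106.65, 1) == 106.7
        assert pct(1, 8, 0) == 13  # 12.5 rounds up


class TestAgeBins:
    @pytest.mark.parametrize(
        "age, label",
        [(18, "<30"), (29, "<30"), (30, "30-39"), (39, "30-39"), (40, "40-49"),
         (49, "40-49"), (50, "50-59"), (59, "50-59"), (60, ">=60"), (85, ">=60")],
    )
    def test_boundaries(self, age, label):
        assert assign_age_bin(age) == label

    def test_bins_partition_adult_ages(self):
        labels = [assign_age_bin(age) for age in range(18, 120)]
        assert all(labels)  # exactly one bin per age, no gaps


class TestSevenNumberSummary:
    def test_constant_data(self):
        s = summarize_compliance([100, 100, 100])
        assert s.mean == 100 and s.sd == 0
        assert (s.minimum, s.q1, s.median, s.q3, s.maximum) == (100,) * 5

    def test_median_by_interpolation(self):
        assert summarize_compliance([80, 90, 100, 110]).median == 95

    def test_single_value_degenerate(self):
        s = summarize_compliance([50])
        assert s.degenerate and s.sd == 0
        assert s.mean == s.minimum == s.maximum == 50

    def test_empty_input(self):
        with pytest.raises(UndefinedMetricError):
            summarize_compliance([])

    def test_sample_sd_uses_n_minus_1(self):
        s = summarize_compliance([1, 2, 3])
        assert s.sd == pytest.approx(1.0)

    def test_quartiles_match_sorting_interpolation_oracle(self):
        """Linear order-statistic interpolation, checked on all short lists."""
        rng = np.random.default_rng(7)
        for n in range(1, 9):
            for _ in range(20):
                values = rng.integers(0, 100, size=n).astype(float).tolist()
                s = summarize_compliance(values)
                v = sorted(values)
                for q, got in ((0.25, s.q1), (0.5, s.median), (0.75, s.q3)):
                    pos = q * (n - 1)
                    lo, frac = int(pos // 1), pos % 1
                    expect = v[lo] if frac == 0 else v[lo] + frac * (v[lo + 1] - v[lo])
                    assert got == pytest.approx(expect)


class TestSensitivitySubset:
    def test_single_manual_record_excludes_patient(self):
        auto_days = [make_injection("p1", when=f"2017-09-{d:02d}T08:00:00")
                     for d in range(1, 20, 2)]
        manual = make_injection("p1", when="2017-09-21T08:00:00", source="manual")
        pure = [make_injection("p2", when=f"2017-09-{d:02d}T08:00:00")
                for d in range(1, 20, 2)]
        logs = clean(auto_days + [manual] + pure)
        cohort = Cohort(patients=[make_patient("p1"), make_patient("p2")],
                        injections=auto_days + [manual] + pure)
        subset = sensitivity_subset(cohort, logs)
        assert [p.patient_id for p in subset] == ["p2"]

    def test_empty_subset_warns(self):
        rec = make_injection("p1", source="manual")
        logs = clean([rec])
        cohort = Cohort(patients=[make_patient("p1")], injections=[rec])
        with pytest.warns(UserWarning, match="empty"):
            assert sensitivity_subset(cohort, logs) == []


class TestWellnessSummary:
    def test_users_and_entry_summary(self):
        patients = [make_patient(f"p{i}", wellness=w)
                    for i, w in enumerate([1, 1, 2, 17, 0, 0, 0, 0, 0, 0])]
        out = wellness_summary(patients)
        assert out["n_users"] == 4
        assert out["pct_users"] == 40
        assert out["entries"]["maximum"] == 17
        assert out["entries"]["mean"] == pytest.approx((1 + 1 + 2 + 17) / 4)

    def test_all_zero_counts(self):
        patients = [make_patient(f"p{i}") for i in range(3)]
        out = wellness_summary(patients)
        assert out["n_users"] == 0 and out["entries"] is None

    def test_single_user_degenerate(self):
        out = wellness_summary([make_patient("p1", wellness=3)])
        assert out["entries"]["mean"] == 3 and out["entries"]["sd"] == 0


class TestPrecisionAssurance:
    def test_planned_study_exceeds_99_percent(self):
        assert precision_assurance(40, 20, 10, 0.95) > 0.99

    def test_monotone_in_n_and_sd(self):
        base = precision_assurance(40, 20, 10, 0.95)
        assert precision_assurance(40, 15, 10, 0.95) >= base
        assert precision_assurance(60, 20, 10, 0.95) >= base
        assert precision_assurance(10, 20, 10, 0.95) <= base

    @pytest.mark.parametrize("n, sd", [(2, 20), (5, 25), (40, 20)])
    def test_agrees_with_monte_carlo_oracle(self, n, sd):
        """Closed form vs simulating the sample SD directly, 1e5 replicates."""
        from scipy import stats

        rng = np.random.default_rng(11)
        reps = 100_000
        samples = rng.normal(0.0, sd, size=(reps, n))
        s_hat = samples.std(ddof=1, axis=1)
        z = stats.norm.ppf(0.975)
        hits = np.mean(z * s_hat / np.sqrt(n) <= 10.0)
        closed = precision_assurance(n, sd, 10.0, 0.95)
        # binomial SE under the closed-form value (observed-hits SE collapses
        # to 0 when the probability is within 1/reps of 1)
        se = np.sqrt(closed * (1 - closed) / reps)
        assert abs(closed - hits) <= 3 * se + 1.0 / reps

    def test_parameter_validation(self):
        for bad in [dict(n=1, sd_assumed=20, halfwidth_target=10),
                    dict(n=40, sd_assumed=0, halfwidth_target=10),
                    dict(n=40, sd_assumed=20, halfwidth_target=-1),
                    dict(n=40, sd_assumed=20, halfwidth_target=10, ci_level=1.2)]:
            with pytest.raises(ParameterError):
                precision_assurance(**bad)


class TestBuildReport:
    @pytest.fixture
    def small_cohort(self):
        patients = [
            make_patient("p1", age=28, gender="F", wellness=2),
            make_patient("p2", age=35, gender="M"),
            make_patient("p3", age=62, gender="F"),
        ]
        injections = []
        for pid in ("p1", "p2", "p3"):
            injections += [
                make_injection(pid, when=f"2017-09-{d:02d}T08:00:00", site="left arm")
                for d in range(1, 28, 2)
            ]
        injections.append(
            make_injection("p2", when="2017-09-02T09:00:00", source="manual"))
        return Cohort(patients=patients, injections=injections)

    def test_shapes_and_stratum_sums(self, small_cohort):
        logs = clean(small_cohort.injections)
        results = {pid: compute_adherence(log, medication_days=28, wellness_days=28)
                   for pid, log in logs.items()}
        report = build_report(small_cohort, logs, results)

        demo = report.demographics
        assert demo["Total_n"].sum() == 3
        assert demo["Female_n"].sum() + demo["Male_n"].sum() == demo["Total_n"].sum()

        outcomes = report.outcomes
        main = outcomes[outcomes.analysis_set == "main"]
        assert list(main.stratum) == ["Total", "Female", "Male"]
        total = main[main.stratum == "Total"].iloc[0]
        assert total.n == 3
        # sensitivity block excludes the mixed-provenance patient p2
        sens = outcomes[(outcomes.analysis_set == "sensitivity")
                        & (outcomes.stratum == "Total")].iloc[0]
        assert sens.n == 2

        patterns = report.data_patterns
        prov = patterns[patterns.section == "injection_patterns"]
        assert prov["Total_n"].sum() == 3

        fig = report.figure_data
        assert set(fig.stratum) >= {"Total", "Female", "Male", "<30"}

    def test_empty_stratum_row_has_n_zero(self):
        patients = [make_patient("p1", age=28, gender="F")]
        inj = [make_injection("p1", when=f"2017-09-{d:02d}T08:00:00")
               for d in range(1, 28, 2)]
        cohort = Cohort(patients=patients, injections=inj)
        logs = clean(inj)
        results = {pid: compute_adherence(log, medication_days=28, wellness_days=28)
                   for pid, log in logs.items()}
        report = build_report(cohort, logs, results)
        male = report.outcomes[(report.outcomes.analysis_set == "main")
                               & (report.outcomes.stratum == "Male")].iloc[0]
        assert male.n == 0
        assert "compliance_mean" not in male.dropna()

    def test_export_round_trip(self, small_cohort, tmp_path):
        logs = clean(small_cohort.injections)
        results = {pid: compute_adherence(log, medication_days=28, wellness_days=28)
                   for pid, log in logs.items()}
        report = build_report(small_cohort, logs, results)
        written = report.to_csv(tmp_path)
        assert len(written) == 4
        as_json = report.to_json()
        assert set(as_json) == {"demographics", "data_patterns", "outcomes",
                                "figure_data"}
        assert "== outcomes ==" in report.render_text()
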