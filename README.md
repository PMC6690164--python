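# doselog

Cleaning and adherence analysis of electronic-autoinjector injection logs.

`doselog` implements the computational pipeline of an app-based digital
observational study of medication usage among patients with multiple
sclerosis on interferon beta-1b. Every injection made with the electronic
autoinjector is recorded automatically (timestamp, dose, needle depth,
injection speed); patients may additionally document injections by hand in
the companion app and, optionally, log well-being entries in a wellness
tracker. Exports of such a database are messy — re-synchronisation replays
events, manual and device records describe the same injection, sites are
sometimes "unknown" — and this package turns them into per-patient adherence
outcomes and stratified cohort tables. It is written for biostatisticians
and epidemiologists analysing electronic medication-event monitoring data.

## The model

Each patient's observation window is the half-open interval
`[t0, t0 + 180)` days, anchored at the first recorded injection day. With an
every-other-day regimen the number of *expected doses* is
`ceil(180 / 2) = 90`. Writing `D` for the number of distinct cleaned
injection days inside the window:

- **compliance** `C = 100 · D / 90` (%), not capped — off-schedule
  injections can push it past 100%;
- **persistence** — at least one injection day in the final 14 days of the
  window, `[t0 + 166, t0 + 180)`;
- **adherence** — persistent **and** `C ≥ 80` (boundary inclusive).

Before any of that, raw records pass through a three-rule cleaning
procedure: exact duplicates are deleted; within each
(patient, UTC day, source) group only the last entry ordered by time is
kept; and on days with both a device and a manual record the device record
wins, inheriting the manual injection site only when its own site is
"unknown".

The cohort layer produces stratified (total / gender / age-band) summary
tables, the autoinjector-only sensitivity subset, wellness-tracker usage
summaries, and the study-size *assurance*: with sample SD `S` from `n`
patients, the planned two-sided 95% CI for mean compliance has half-width
`z₀.₉₇₅·S/√n`, and since `(n−1)S²/σ² ~ χ²(n−1)` the probability that the
half-width stays within a target is available in closed form.

Because no real per-patient data are distributable, the package includes a
first-class synthetic-cohort generator (`doselog.simulate`) with per-dose
miss probability, geometric treatment discontinuation, off-schedule
injections, duplicate/re-sync contamination, mixed manual/device
documentation and sparse wellness usage — all seeded and bit-reproducible.

## Worked example

```python
from doselog import SimulationConfig, simulate_cohort, clean, compute_adherence

cohort = simulate_cohort(SimulationConfig(n_patients=94, seed=1))
logs = clean(cohort.injections)
r = compute_adherence(logs["p001"])
print(r.injected_days, r.expected_doses, round(r.compliance_pct, 1),
      r.persistent, r.adherent)
```

prints `87 90 96.7 True True`: patient `p001` injected on 87 distinct days
of 90 expected, for 96.7% compliance; an injection in the final two weeks
makes them persistent, and 96.7 ≥ 80 makes them adherent. Running
`python examples/02_per_patient_metrics.py` shows the two boundary cases:

```
patient A: 96 injection days / 90 expected doses
  compliance 106.7%  persistent=True  adherent=True
patient B: 60 injection days / 90 expected doses
  compliance 66.7%  persistent=False  adherent=False
```

Patient A injected on six off-schedule days, so compliance exceeds 100%;
patient B stopped at day 120 and fails persistence outright. The other
scripts in `examples/` cover cleaning (`01`), the full simulate→report
pipeline (`03`) and the assurance curve (`04`).

A thin CLI wraps the same stages for shell use:

```sh
doselog simulate --n-patients 94 --seed 1 --out-dir raw/
doselog clean    --injections raw/injections.csv --out-dir cleaned/
doselog analyze  --injections raw/injections.csv --patients raw/patients.csv \
                 --out-dir report/
```

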