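# Methods

## Data model

The pipeline operates on two tables mirroring the study-database schema.
Injection events carry `patient_id`, a UTC timestamp, a dose level from
{0.25, 0.5, 0.75, 1.00}, a free-text injection site (sentinel `"unknown"`),
a provenance flag (`Autoinjector` / `Manual`), and — for device records —
needle depth ∈ {8, 10, 12} mm and injection speed ∈ {low, medium, high}.
Manual records legitimately lack the device parameters, so those fields are
optional rather than errors. Patient records carry consent date, age
(≥ 18), gender ∈ {M, F}, a wellness-tracker entry count, and a
`first_injection_date` field that is carried through I/O for schema
fidelity but consumed by no computation.

All timestamps are UTC end to end. The source columns are explicitly named
`..._utc`, and keeping a single clock avoids daylight-saving ambiguity in
day-boundary decisions; "same day" therefore always means the same UTC
calendar day. Naive timestamps on input are interpreted as UTC; zoned ones
are converted.

## Cleaning

Three rules, applied in order, reduce the raw log to at most one record per
patient-day:

1. exact duplicates (all fields identical) collapse to the first occurrence;
2. within each (patient, day, source) group the last entry ordered by time
   survives;
3. on mixed days the autoinjector record is retained; if its site is
   "unknown" (case-insensitive; empty counts as unknown) and the manual
   record names a site, that site is substituted into the retained record —
   a known device site is never overwritten.

Two underdetermined corners needed decisions. Timestamp ties within a
day-source group keep the record appearing later in the input file — a
deterministic rule exercised directly by tests over both orderings. And no
cleaning happens beyond the three rules: near-duplicates (same day, slightly
different timestamps from distinct sync batches survive rule 2 only if they
differ in source) and implausible values pass through untouched, so the
pipeline's output is a pure function of the rules rather than of editorial
judgement.

Each patient's provenance classification (autoinjector-only / manual-only /
mixed), which drives the sensitivity analysis, is computed from the
*pre-cleaning* records: a patient whose only manual entries are discarded by
rule 3 still counts as mixed, because they did manually document.

Cleaning is idempotent, and its output is checked record-for-record against
an independent brute-force enumeration of the rules on randomized inputs
(hypothesis, derandomized).

## Windows, schedule and outcome metrics

The observation window is the half-open interval `[t0, t0+180)` days
anchored at the earliest cleaned injection day, with a 90-day wellness
window. Fixed 180/90-day lengths (rather than calendar months) were chosen
because they give exactly 90 expected doses under the every-other-day
regimen, the denominator consistent with a printed compliance maximum of
106.7% = 100·96/90; calendar-month windows would make the denominator vary
by start date. The every-other-day interval itself is the licensed regimen
for this therapy and is a configurable parameter (`interval_days`,
default 2). The schedule is anchored at the window start (day 0 is
scheduled); anchoring at the first injection is accepted as a policy value
but coincides by construction.

- **Expected doses** = `ceil(medication_days / interval_days)`, verified
  against explicit enumeration for all window lengths 1–400 and intervals
  1–7.
- **Compliance** = 100 × (distinct cleaned injection days in the window) /
  expected doses, uncapped. Off-schedule days count: after cleaning there is
  at most one record per day, so the numerator cannot exceed
  `medication_days`, bounding compliance by 200% at interval 2.
- **Persistence**: the conceptual definition — still on therapy at window
  end — is not computable from an event log, which also cannot distinguish
  discontinuation from documentation stop. It is operationalised as ≥ 1
  injection day in the terminal `[end−gap_days, end)`, with `gap_days = 14`
  (seven scheduled doses of slack) exposed as a parameter. The boundary day
  `end − gap_days` is inside the grace interval.
- **Adherence** = persistent AND compliance ≥ 80.0 (inclusive threshold,
  configurable).

A patient with an empty cleaned log has no window and is excluded from the
metrics with an explicit error, mirroring participants for whom no injection
data could be recorded.

## Cohort summaries and reporting conventions

Strata are Total / Female / Male plus age bands <30, 30–39, 40–49, 50–59,
≥60 (ASCII label `>=60` in machine-readable output). Compliance and
wellness-entry distributions are reported as mean, sample SD (n−1
denominator; an n=1 stratum reports SD 0 with a degeneracy flag), minimum,
Q1, median, Q3, maximum. Quartiles use linear interpolation of order
statistics (numpy's `linear`, the "type 7" convention); no convention can be
validated against the source tables without raw data, so the common default
was chosen and is checked against an explicit sorting-plus-interpolation
oracle. Display rounding is half-up (not banker's): zero decimals for
proportions, one decimal for compliance. A wellness-tracker *user* is a
patient with entry count ≥ 1; entry summaries are computed over users only.

The sensitivity analysis set retains exactly the patients with
autoinjector-only provenance. Report output is four machine-readable tables
(demographics, data patterns, main+sensitivity outcomes, per-stratum
bar-chart data) exportable as CSV, JSON or plain text.

## Study-size assurance

For a planned cohort of `n` patients, the two-sided `1−α` CI for mean
compliance has half-width `z₁₋α/₂·S/√n`. Treating compliance as normal with
true SD σ, `(n−1)S²/σ² ~ χ²(n−1)`, so

    P(half-width ≤ h) = P(χ²(n−1) ≤ (n−1)·n·h² / (z² σ²)),

implemented via `scipy.stats.chi2` and cross-checked against a Monte-Carlo
simulation of the sample SD. A simpler plug-in bound (treat S as known,
check `z·σ/√n ≤ h`) would return 0 or 1; the chi-square form is the one that
can produce a ">99%" statement, and it is monotone increasing in `n` and
decreasing in σ. At n=40, σ=20, h=10 the assurance is 0.9999998.

## Synthetic cohorts

The generator emulates the data-generating process the pipeline assumes.
Per patient: a geometric discontinuation day (per-day hazard; P(stop day >
d) = (1−h)^d; ∞ at hazard 0), injections on scheduled days with probability
`p_inject` and on off-schedule days with probability `p_offschedule`;
exact-duplicate and same-day re-sync contamination; a documentation mode
(autoinjector-only / manual-only / mixed, with mixed users co-documenting
days manually at rate `p_manual_doc`); "unknown" device sites at rate
`p_site_unknown`; demographics from an age-band mixture and a gender
probability; wellness usage as a Bernoulli user indicator with a
zero-truncated geometric entry count. Randomness flows from one seed through
per-patient `SeedSequence` substreams, so cohorts are bit-reproducible and
individual patients can be re-simulated in isolation; record order within a
patient is generation order.

Defaults describe the cohort the pipeline was designed around: `p_inject`
0.93 and `p_offschedule` 0.02 put mean compliance in the mid-90s;
discontinuation hazard 2.5e-4 gives ≈96% persistence
((1−h)^166 ≈ 0.96); 53% female, age mixture 11/24/34/16/15% across the five
bands, 57/15/28% autoinjector-only/manual-only/mixed, 21% wellness users
with mean 3.1 entries. These margins make fixtures realistic; they are
exercised by parameter-recovery tests (mean compliance ≈ 100·p_inject,
persistence ≈ the geometric closed form, both within 3 Monte-Carlo standard
errors at 200 patients), never asserted as outputs in their own right.

What the generator does *not* emulate: relapses or any outcome process,
dose titration (doses are constant), within-day timing behaviour beyond a
uniform draw, seasonal or weekday patterns, and correlated missingness
(each dose is missed independently). Passing tests therefore show the
pipeline recovers the parameters of *this* behavioural model, not that real
cohorts satisfy it; in particular real "nonpersistence" conflates stopping
therapy with stopping documentation, which the generator makes explicit via
a separate `documentation_stop_hazard` that is indistinguishable from
discontinuation in the emitted data.

## Numerical and edge-case choices

- Half-up rounding is implemented with `decimal` on `repr(value)`;
  floating-point `round()` is banker's and disagrees on printed half-way
  displays.
- Problem sizes in tests are deliberately desk-scale: 200-patient recovery
  runs, 1e5-replicate Monte-Carlo oracles, exhaustive 400×7 schedule
  enumeration — the full suite runs in well under a minute.
- Duplicate `patient_id`s in the patient table are an integrity error;
  orphan injections (no matching patient) are excluded with a warning, not
  an error.
- Empty input files with a valid header parse to empty collections.
- `pct` and the seven-number summary raise on empty denominators/sets rather
  than returning NaN, so report code must handle empty strata explicitly
  (they render as n=0 rows with blank summaries).

## Known limitations

Persistence is a proxy with a tunable grace period; there is no ground
truth to calibrate `gap_days` against. The quartile and rounding
conventions are choices among several defensible ones and affect printed
values at the margin. The cleaning rules are faithful but minimal: records
that are wrong in ways the rules do not address (e.g. duplicated events
with drifting timestamps across sources) survive. The CLI holds entire
files in memory; logs of this kind are small (tens of thousands of rows),
and no streaming path is provided.
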