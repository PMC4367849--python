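# Methods

## The index

The Glucose Ketone Index (GKI) is the dimensionless molar ratio of blood
glucose to blood β-hydroxybutyrate (β-OHB):

    GKI = [glucose (mM)] / [β-OHB (mM)]

It condenses two fluctuating biomarkers into one number that tracks depth of
therapeutic ketosis during metabolic therapy (ketogenic diets, calorie
restriction, fasting).  Lower is deeper: a fed, non-ketotic adult sits around
20–40; the zone of metabolic management proposed for glucose-dependent brain
tumors is roughly 1–2, optimally approaching 1.0.

### Units

Consumer glucose meters report mg/dL in much of the world while ketone meters
report mM, so the ratio is computed on millimolar values and every input
carries an explicit analyte and unit.  The mg/dL ↔ mM conversion factor for an
analyte is its molar mass divided by ten (mg/dL × 10 = mg/L; ÷ g/mol = mmol/L):

| analyte | molar mass (g/mol) | mg/dL per mM |
|---|---|---|
| glucose | 180.16 | 18.016 |
| β-OHB   | 104.1  | 10.41  |

These are physical constants of the molecules, hard-coded rather than
configurable.  Units are never inferred from magnitude — 5.5 is a plausible
glucose reading in both systems — so an input without a unit is a hard error.
The internal canonical unit is mM because the index is defined on molar
values.

### Numerical conventions

- **Display rounding** is one decimal, half away from zero, implemented with
  decimal arithmetic on the float's shortest repr so binary representation
  noise cannot flip a boundary case.  Full precision is kept everywhere else;
  rounding happens only at presentation (and in the verification routine,
  whose job is to compare against printed one-decimal values).
- **Zero ketones** raise a domain error rather than yielding infinity: the
  ratio is undefined there, and blood-ketone meters have a minimum
  quantifiable value, so a stored zero indicates a data problem.
- **Zero glucose** is physiologically implausible and rejected by default; a
  caller that genuinely wants the degenerate 0.0 index can opt in.

## Tracking and the target zone

A tracking log is a time-ordered sequence of paired glucose/ketone readings
for one subject (duplicate timestamps rejected; day boundaries are the
calendar date of the timestamp as given, with no timezone conversion, since
consumer-meter exports carry no reliable zone information).

Multiple same-day readings collapse to one daily GKI under a configurable
rule: `mean` (default — the natural reading of "daily GKI"), or
`all_readings`, which takes the day's maximum so a day counts as in-zone only
when every reading is.  The strict rule can never report more in-zone days
than the mean rule (max ≥ mean).  Whether a partially-in-zone day should
count is genuinely underdetermined; both rules are first-class rather than
asserting one as canonical.

A day is **in the zone** iff its daily GKI is ≤ the target (default 1.0).
The boundary is inclusive so the rule is deterministic on exact hits.  The
broader 1–2 management band is carried as `upper_band` (default 2.0, raised
to the target if the target is set above 2); it is reporting context and does
not affect the in-zone test.  The zone report lists per-day values, the
days-in-zone count, and entry dates (out-of-zone → in-zone transitions).

**Urinary ketones.**  One bundled study measured urinary rather than blood
ketones.  Urine strips measure acetoacetate, not β-OHB, so such readings get
a GKI arithmetically but carry a non-comparable flag that propagates into
series, zone reports and the CLI output.

**Pairing.**  Meters often export glucose and ketone rows separately.  The
interleaved CSV reader pairs each glucose row with the nearest unpaired
ketone row within a window (default 10 minutes, configurable); unpaired rows
are dropped with row-numbered warnings, and the paired measurement takes the
glucose row's timestamp.

## Bundled published studies

The package ships a frozen CSV transcription of the group means from five
published human and mouse brain-tumor diet studies (20 glucose/ketone/GKI
triplets: 4 pediatric-astrocytoma timepoints, 2 glioblastoma timepoints, 4
CT-2A mouse arms, 6 arms across CT-2A and U87-MG, 4 GL261 ± radiation arms).
Freezing the transcription in a versioned data file — rather than parsing
source documents at runtime — keeps verification reproducible offline.
`verify_table1()` recomputes every row's GKI by plain division plus display
rounding and reports mismatches; the shipped transcription verifies with
zero.

A second bundled table gives ad-libitum vs calorie-restricted group means for
the VM-M3 glioblastoma model.  Its printed GKIs (15.3 ± 0.9, 6.5 ± 0.9) are
means of per-animal ratios, and the underlying per-animal data are
unpublished; the ratio of the printed group means gives 16.0 and ≈6.3
instead.  A ratio of means is not a mean of ratios (a Jensen-type
inequality), so the two conventions are exposed as separate fields
(`gki_of_means`, `mean_of_gkis`) and never conflated.  Only the mean of
ratios is guaranteed to lie between the per-subject extremes, and only that
bound is asserted in tests.

## Synthetic logs

The generator emulates a subject starting a ketogenic diet partway through a
monitoring period.  Defaults mirror the bundled human data: baseline 5.5 mM
glucose / 0.2 mM β-OHB (GKI 27.5, the non-ketotic state both pediatric
patients started from) relaxing to 4.0 / 4.0 mM (GKI → 1, the deep-ketosis
range those patients reached after ~8 weeks).  The mean trajectory is an
exponential relaxation beginning at the diet-start day with a 3-day
half-life — the few-week transition tempo reported clinically — and each
reading multiplies the mean by an independent lognormal factor with unit mean
and 10% coefficient of variation (σ² = ln(1 + cv²), μ = −σ²/2).
Multiplicative lognormal noise keeps concentrations strictly positive with no
clipping artifacts.  Readings default to twice daily at fixed clock times
(08:00, 20:00), marked 2.5 h postprandial.

This is a test harness, not a physiological model: no meals, no circadian
structure, no glucose–insulin coupling, and glucose/ketone noise are
independent.  Tests that pass on synthetic logs therefore demonstrate the
correctness of the bookkeeping (aggregation, zone accounting, serialization),
not fidelity to real patient dynamics.

Problem sizes used in the test suite — 60-day logs, 20 seeds for the
parameter-recovery check, brute-force oracle comparison on logs of up to 100
measurements — are chosen so the whole suite runs in seconds while leaving
the stochastic checks well-powered (the recovery check pools ~280 late-window
readings per analyte).

## Interfaces

The library is the primary surface; the `gki` CLI is a thin wrapper
(`convert`, `compute`, `track`, `verify-studies`, `simulate`), exiting 0 on
success and 2 on validation errors.  An optional YAML configuration file can
set the target, daily rule, band edge and pairing window, with explicit flags
taking precedence.  Measurement CSVs are comma-separated UTF-8 with a header
row, ISO-8601 timestamps and mandatory unit columns; numbers serialize at
full precision to avoid double-rounding drift.  The monthly chart renders
daily GKI as a black line against a horizontal red target line; its
companion CSV (day, daily GKI, constant target) is the testable surface,
the image content deliberately untested.

## Known limitations

- Acetoacetate and total-ketone arithmetic are out of scope; the index is
  defined on β-OHB only.
- No whole-blood vs plasma correction factors.
- No forecasting, alerting, or diet-recommendation logic.
- The urinary-ketone flag warns but does not attempt any acetoacetate→β-OHB
  conversion (none is defensible without calibration data).
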