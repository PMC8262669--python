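# emafit

A headless ecological-momentary-assessment (EMA) engine for home-based
monitoring of Parkinson disease, built around a tablet-style protocol of
four daily assessment sessions: patient-reported scales, a keyboard tapping
test, and a nightly sleep diary, collected over a 14-night home period.
It is aimed at digital-health researchers who need the *behavioural
machinery* of such a study — session scheduling with expiry, all-or-nothing
task capture, offline-first persistence, and compliance/usability
analytics — fully testable at desk scale without any patient data: a
synthetic-patient simulator with known ground truth drives every stage.

## What it computes

**Session scheduling.** Sessions are anchored on patient-generated events:
*on waking* is due 30 min after the wake anchor, *after medications* 60 min
after the first dopaminergic dose, *afternoon* at the pre-dose anchor,
*evening* at the bedtime anchor, plus on-demand *nap* sessions. Each session
expires after its window; an expired task cannot be performed again that
day. The once-daily sleep diary is designated to the after-medications
session and carries over to any later open session.

**Workload accounting.** An `n`-night home period spans `n + 1` calendar
days (arrival evening, `n − 1` full days, final morning), giving
`4n − 1` scheduled sessions. For the default 14 nights: 55 subjective-scale
tasks, 55 tapping tests and 14 diaries = 124 tasks, i.e. 55 × 11 + 14 × 24 =
941 questions (68 on a full mid-study day).

**Tapping-test scoring.** Each 30-s alternating two-key trial per hand
yields the four classic bradykinesia–akinesia–incoordination parameters:

- kinesia score `KS = #keystrokes` (per 30 s),
- akinesia time `AT = mean(up − down)` over keystrokes (ms),
- incoordination score `IS = s²(travel)` — sample variance of
  key-up→next-key-down travel times (ms²),
- dysmetria score `DS = Σw/KS` with weight 0 / 1 / 2 for target /
  adjacent / distant keys.

**Compliance.** `C = 100 · completed / expected`, half-up to 2 decimals, by
version × session × task, with nap sessions excluded. Version improvements
are assessed by the classical one-tailed two-proportion z-test with pooled
variance `z = (p̂₂ − p̂₁)/√(p̂(1−p̂)(1/n₁ + 1/n₂))`.

**Usability.** The target ratio — percent of screen touches landing on
button regions — is averaged per patient over the sessions of fully
completed days, then averaged unweighted across patients.

**Store and forward.** Records are durable in an append-only local journal
before any connectivity, then synced at-least-once with `record_id`
deduplication; portal-style conjunctive filters (patient, date range,
session, record type, tapping hand, H/V0/V1 categorization) feed a lossless
CSV export.

## Worked example

```bash
$ python examples/04_simulate_cohort_compliance.py
events replayed      : 1017
tasks completed      : 676 of 744 expected
overall compliance   : 90.86%
ground-truth check   : 676 tasks implied by the draws
  v2.0 after_medications  fit_test            88.10%
  ...
```

Six simulated patients follow the 14-night protocol with ~0.92 per-session
adherence and a mild within-day decline; the replayed store's compliance
report (676/744 = 90.86%) equals the count implied by the simulator's own
adherence draws — the pipeline loses nothing between simulated behaviour and
reported compliance. The other examples (`examples/01…06`) walk the
workload ledger, tapping scoring, a scheduled day, target-ratio recovery and
failure-tolerant sync the same way.

A thin CLI wires the same stages together:

```bash
ema simulate --seed 7 --out sim/
ema run --manifest manifest.yaml
ema report --store run/journal.ndjson
ema export --store run/journal.ndjson --type fit_test --hand left --out left.csv
```

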