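# Methods

## The assessment model

The engine models a home EMA study in which a patient completes four daily
sessions anchored to their own physiology and medication schedule rather
than to wall-clock times. Anchors are explicit events (wake time, first
medication intake, pre-afternoon-dose, bedtime, nap end); a session becomes
due at `anchor + offset` and expires at `due + window`. Offsets are fixed by
the protocol (30 min after waking; 60 min after the first dose; 0 for the
afternoon and evening anchors). Expiry enforces the ecological premise:
a momentary assessment answered hours late is a different measurement, so
an expired session can never be completed later the same day.

Task capture is all-or-nothing: a questionnaire is stored only if every
question has an in-domain answer, and a tapping test only with a valid trial
per hand. Rejected submissions leave no partial state. The once-daily sleep
diary is designated to the after-medications session; while it is pending it
is offered again in every later open session of the day, including a session
whose per-session tasks are already finished. A session's `completed` state
therefore refers to its per-session tasks (scales + tapping); the diary is
accounted per day, not per session.

The scheduler is a pure function of its event stream: replaying identical
anchors, clock readings and completions reproduces the serialized state (and
the derived store) byte for byte, which is what the replay-determinism tests
assert.

## Expected workload

A home period of `n` nights spans `n + 1` calendar days: the arrival evening
(day 0), `n − 1` full four-session days, and the final morning's on-waking +
after-medications sessions — `4n − 1` scheduled sessions, each carrying one
scales task and one tapping test, plus `n` diaries (one per night, reported
the following morning). For the default `n = 14` this gives 55 + 55 + 14 =
124 tasks and 55 × 11 + 14 × 24 = 941 questions. On-demand nap sessions are
excluded from all expectations since they cannot be scheduled a priori.

The alpha-version question bank has 5 scale questions, giving 4 × 5 + 24 =
44 questions per full day and 611 over 14 nights from this enumeration.
Historical alpha deployments reported larger per-day question totals that
are not derivable from these counts; the bank is therefore configuration,
and no claim is made about alpha question totals.

## Tapping-test parameters

Each 30-s alternating two-key trial is validated (events inside the window,
no overlapping key holds, ≥ 1 keystroke) and scored:

- **KS** — keystroke count, all keys. Wrong-key strikes are keystrokes.
- **AT** — arithmetic mean dwell (`up − down`) in ms.
- **IS** — sample variance (n−1 denominator) of travel times, defined
  key-up → next-key-down; needs ≥ 3 keystrokes. `down→down` is available as
  an option.
- **DS** — mean strike weight (0 target / 1 adjacent / 2 distant) over all
  keystrokes, in [0, 2]. Adjacency comes from a configurable keyboard map
  (a plain QWERTY grid by default); physical key spacing cannot be inferred
  from key codes, so geometry is always configuration.

Wrong-key strikes are excluded from the dwell/travel statistics by default
(`include_errors=True` reverses this): a stray hit should not contaminate
the dwell estimate, while the long bridged travel it leaves behind *is*
rhythm disruption and legitimately inflates IS. Scores are reported per
30-s trial without rescaling.

## Compliance and version comparison

Compliance is `100 × completed / expected` with half-up rounding to two
decimals, computed per version × session × task. Expected counts come from
the workload ledger times the number of patients on each version; completed
counts are deduplicated home records whose `(study day, session)` falls in
the analysis window (arrival evening through final after-medications).
Missing tasks count as non-compliant regardless of cause.

The version comparison is a classical one-tailed two-sample proportion test
with pooled variance and no continuity correction (a Yates-corrected variant
is exposed); p-values are reported raw and at 4 decimals. Satisfaction
tallies (categorical 1–4) are reported as whole percents, half-up, per
question and pooled across the three usability questions. All rounding goes
through one module so printed-style outputs are consistent.

## Target ratio

A touch is a hit iff it lands in a button rectangle (half-open
`[x0,x1)×[y0,y1)`, first-declared wins on overlap). The session target ratio
is `100 × hits/touches`; zero-touch sessions have no ratio and are skipped.
The cohort value averages per-session ratios within patient over included
sessions, then averages patient means unweighted — *not* pooled touches; a
test constructs a case where the two differ and pins the former. Included
sessions are those of fully completed days: the day-0 evening and the final
morning's two sessions are excluded (exactly 3 of the 55 slots at n = 14).

## Store and forward

The journal is append-only, file-backed as newline-delimited JSON, durable
before acknowledgment, and deduplicates on `record_id`. Sync pushes
unacknowledged records in order through a transport that can fail after any
number of deliveries; each record is acknowledged individually, so the
high-water mark always equals the last acknowledged record and a retry
pushes exactly the remainder. Delivery is at-least-once; the remote
deduplicates, so replaying the journal from empty reproduces the remote
exactly for any prefix of failures. The remote is an in-process pluggable
interface; network transport is out of scope, the contract is what is
tested. CSV export is RFC-4180-style (comma, double-quote escaping, UTF-8,
header, ISO-8601 timestamps); tapping records get dedicated
hand/KS/AT/IS/DS columns, other payloads travel as a canonical JSON column,
and export → import → export is byte-identical.

## The simulator and what passing tests mean

The simulator generates anchors (wake ≈ 07:00 ± 30 min, first dose ≈ wake +
45 ± 15 min, afternoon ≈ 15:00 ± 20 min, bedtime ≈ 22:00 ± 40 min, all in a
fixed +01:00 zone), per-session adherence draws, complete in-domain
questionnaire answers following smooth per-patient latent trajectories,
tapping streams (dwell ~ N(120, 10²) ms, travel ~ N(480, 30²) ms → ≈ 50
strikes per trial, 5% wrong keys of which 80% adjacent, with between-patient
spread on the means), touch logs (90% accuracy, ~40 touches/session), and
task durations (scales 55 s, tapping 70 s, diary 180 s, ±15%), so a fully
adherent day costs ≈ 11 min. Defaults for adherence are 0.92 per session
kind with a ×0.985 decline per within-day session ordinal, reproducing the
morning-to-evening adherence gradient such studies report.

Two structural choices matter for interpretation. The first dose is taken
only after an adhered on-waking session (the medication anchor closes the
pre-dose window), so simulated completions are never invalidated by their
own schedule. The diary rides deterministically on the after-medications
adherence draw; with uniform adherence `p` every one of the 124 expected
tasks is then Bernoulli(`p`), which is exactly the binomial expectation the
end-to-end check uses. Patients are independent substreams
(`SeedSequence.spawn`) of one root seed, so a cohort is reproducible and any
patient regenerable alone.

The simulator emulates behaviour, not disease: no pharmacokinetics, no
symptom progression, no realistic answer distributions. Passing tests show
the *engine* is correct — scheduling, capture, persistence and analytics
faithfully transform behaviour into statistics — not that any clinical
finding would replicate.

## Numerical and design choices

- Expiry windows are unpublished for the original study; the engine uses
  180 min per session (60 min for naps), plus early closure of on-waking at
  the medication anchor, all configuration, and makes no claim they match
  the original deployment.
- Study days are bounded at local midnight; the diary is attributed to the
  night ending that morning. Timestamps are timezone-aware throughout.
- Session availability windows are half-open `[due, expires)`; expiry at
  exactly `expires` wins. Simultaneously due sessions order as on-waking <
  after-medications < afternoon < evening < nap.
- Percent rounding is decimal half-up (never banker's): 2 decimals for
  compliance, integers for satisfaction.
- The proportion test uses the pooled-variance normal approximation; no
  exact/mid-p variant is implemented.
- Undefined statistics (IS with < 3 keystrokes, target ratio of an empty
  log, compliance with zero expected) raise rather than return sentinels,
  and the analytics exclude such cells explicitly.

## Problem sizes

Unit and property tests run on 1–8 simulated patients over 2–14 nights;
oracle-equivalence checks use ≥ 100 random trials and parameter recovery
200 trials per setting; the end-to-end cohort check uses 26 patients ×
14 nights (≈ 3200 tasks). The acceptance script's cohort is the same size
with ~12 touches per session. These sizes give binomial standard errors
small enough for 3-SE checks while the full suite stays fast.

## Known limitations

- The scheduler trusts anchor plausibility beyond per-kind monotonicity;
  it does not cross-validate anchors against each other (a bedtime before
  the same day's wake anchor is accepted).
- The journal's durability is per-process file append; no fsync or
  write-ahead checksum.
- The alpha per-version session-task matrix is configurable but its
  historical values are unknown; defaults give every session both tasks for
  every version.
- Satisfaction analysis summarises supplied tallies; the engine does not
  administer the survey.
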