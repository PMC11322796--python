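# Methods

This note documents the models, rules, and numerical choices behind
`weartrial`, and what the synthetic-data tests do and do not establish
about real deployments.

## Event-sourced registry

The participant registry is a derived view over an append-only
`StudyEvent` log; every operation (registration, screening decision,
randomization, device link, withdrawal, assessment, payment) appends an
event, and replaying the log reconstructs the registry exactly. Event
timestamps must be non-decreasing *per participant*; cross-participant
interleaving is free, which is why CONSORT aggregation is
order-insensitive across participants. Two consequences worth noting:

- Study IDs are a study prefix plus a zero-padded counter in
  registration order (`SM0001`, ...). Duplicate registrations are
  detected by a salted SHA-256 hash of the normalized contact email;
  the clear email never enters the event log.
- Device tokens are held as `SecretStr` in memory and appear in the
  persisted log only as salted fingerprints, so replay reconstructs
  participants exactly and device links up to token secrecy. This is a
  deliberate trade: token vault persistence is out of scope.

## Questionnaire engine

Branch predicates are single-item conditions (`=, ≠, <, ≤, >, ≥, in`);
multi-item logic belongs in flag rules. The first matching branch rule
in declaration order wins. The traversal graph (document-order edges
plus branch edges) must be acyclic, checked with a networkx DAG test at
publish time; the walker additionally carries a step guard so an
unvalidated cyclic definition fails loudly rather than looping.

Items skipped by a branch are *not presented* — distinct from *missing*
(presented but unanswered) — and are excluded from scoring: `sum` and
`count` aggregate only presented-and-answered items, and a direct item
reference to an absent answer reads as 0. Score arithmetic is a small
declarative AST (`sum`, `count`, `add`, `sub`, `mul`, `div`, constants);
free-form code is deliberately unsupported. Flags are evaluated after
all scores. Submission tokens are deterministic digests of
(questionnaire, issuance sequence, salt): opaque, reproducible in
simulation, and meaningless outside the registry.

## Screening

Eligibility criteria are declarative range/set predicates over an
answer or a derived quantity. BMI is computed as kg/m² from
self-reported weight and height with 1 lb = 0.45359237 kg and
1 in = 0.0254 m; both window bounds are inclusive (27.0 and 43.0 pass),
mirroring the ≥ 18 age bound. A criterion whose inputs are unanswered
routes the decision to `needs_manual_review` naming the criterion,
rather than silently failing the candidate. Eligibility is a pure
conjunction, so adding a criterion can only shrink the eligible set.
Phase-3 (food-diary) decisions require coordinator sign-off; the diary
summary counts distinct window dates with ≥ 1 entry, with the pass
threshold (default 5 of 5 days) and an optional entries-per-day minimum
(default none) exposed as configuration.

## Minimization

Pocock–Simon minimization with the range method and equal factor
weights by default. For candidate arm $a$ the score is the weighted sum
over factors of the across-arm spread of the participant's
factor-level marginal counts *after* hypothetically adding them to $a$;
population variance is available as an alternative spread. The biased
coin takes the minimizing arm with probability 0.8 by default (a common
practice value; 1.0 gives deterministic minimization for tests), ties
are broken by a fair draw from the same seeded generator — never by arm
order, which would bias allocation. Replaying an ordered participant
stream with the same seed reproduces the identical arm sequence; the
audit log records the per-arm scores and the coin for every allocation.
Prognostic factors are entirely configuration; the fixtures use
sex × BMI category.

## Synchronization and rate limiting

The cost model is one API call per (endpoint, day); endpoints are
activity (steps + heart rate), food, sleep, and weight. The pull window
is half-open, `[today − 7, today)` in the study timezone, so it always
spans exactly 7 calendar dates (DST transitions included — the window is
computed on calendar dates, not 24-hour offsets).

The hourly quota (100 calls/account) is enforced as a **sliding**
3600-second window over granted-call timestamps — the conservative
reading of a per-hour limit: no instant may have a trailing hour with
more than 100 grants. Calendar-hour buckets would admit bursts of up to
200 calls straddling a boundary. Planning is idempotent per
(account, endpoint, day); jobs beyond the remaining budget are deferred
with the budget's next-eligible time (the instant its oldest in-window
call ages out) and promoted FIFO, so no job starves while the simulated
clock advances.

Observations are keyed `(participant, metric, date, source)`. Exact
duplicates are skipped; same-key value conflicts resolve to the record
with the latest `retrieved_at` (last writer wins), on the reasoning
that a vendor re-serving a day's value is correcting it. Weight is
stored internally in kg; alert thresholds are expressed in lb as in
consumer-scale protocols.

## Adherence alerts

Four rules, each evaluated on the 7 calendar dates ending at the scan
date: food gap, weighing gap, tracker gap (steps, heart rate, and sleep
*jointly* absent — a worn tracker produces all three), and a recorded
weight change strictly exceeding 5 lb within the window (max − min over
the window's records, either direction; the signed direction is
reported in the details). A change of exactly 5.0 lb does not fire; a
1e-9 lb guard absorbs lb→kg→lb float round-trip error so the strict
boundary is exact in practice.

Window-ending-at-scan-date semantics give two properties: scans never
look ahead (records dated after the scan date cannot change its
result), and daily scanning finds every qualifying weight-change pair,
since a pair ≤ 6 days apart lies wholly inside the window ending at its
later date. Scanning is restricted to randomized, non-withdrawn
participants. Daily evaluation would re-raise a long gap every day, so
the stateful scanner applies a per-(participant, rule) cool-down of 7
days (configurable): a three-week gap alerts roughly weekly.

Whether the weighing-gap rule should use consecutive calendar days or
any 7-day span is not distinguishable in the protocol language;
consecutive was chosen for symmetry with the food and tracker rules.

## Reporting

Retention for an assessment uses denominator
`randomized − withdrawn before that assessment`: formally withdrawn
participants are no longer expected at follow-up. "Withdrawn before"
is derived from the log as withdrawn participants lacking that
assessment's completion event. Rates are half-up rounded to 2 decimals
via `decimal` (floating-point rounding would mis-round exact
midpoints). Worked example: 394 completers of 502 randomized with 9
prior withdrawals → 394/493 = 79.92%. Note that the companion
423/498 case computes to 84.9398 → **84.94**; a published figure of
84.93 for the same fraction cannot be produced by any standard rounding
and is presumably a typo — the package reports 84.94.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions the engine is
evaluated under:

- **Cohort** (n = 1741 registrants): age ~ Normal(45, 14) rounded and
  clipped to [14, 90]; BMI ~ Normal(34, 6) clipped to [15, 60]; height
  ~ Normal(66, 4) inches; weight derived from BMI and height so the
  questionnaire answers and the derived BMI agree exactly; smartphone
  use at 95%. These distributions straddle every eligibility boundary,
  so phase-1 eligibility (≈ 3 in 4) *emerges* from demographics rather
  than a coin flip. Later phases are scripted Bernoulli draws at the
  observed funnel ratios: 0.725 (phase 2), 0.653 (phase-3 diary), 0.849
  (baseline → randomized).
- **Streams**: daily steps ~ negative binomial (mean 7500, dispersion
  10); resting heart rate ~ Normal(70, 6); sleep ~ Normal(420, 50) min;
  food entries/day ~ max(1, Poisson(3)) on adherent days; weight =
  baseline + trend (−0.25 lb/week default) + Normal(0, 0.8 lb) noise,
  stored in kg. Adherence is an alternating renewal process with
  geometric run lengths (mean 20 adherent / 3 missing days),
  reproducing exactly the multi-day gaps the alert rules target. Each
  record may carry an upload delay (10% of records, geometric mean
  2 days), emulating devices that sync late.
- **Mock vendor server**: answers (account, endpoint, day) queries from
  the generated streams, refuses calls beyond the rolling-hour quota
  with an explicit retry time the scheduler honors, and withholds
  records whose upload delay has not elapsed.

Passing tests therefore demonstrate internal correctness and
reproducibility — rule logic against independent oracles, quota
invariants under exhaustive window scans, deterministic replay — not
fidelity to any real cohort. Real wearable data have intraday
structure, device-specific biases, and informative (non-renewal)
missingness that the generator does not model; screening-funnel counts
and retention rates from the simulator are volume fixtures, not
estimates.

## Problem sizes and determinism

Default problem sizes: 1741-registrant funnel; ~500 randomized
participants monitored for 28 days (the pipeline default) with daily
sync at 02:00 study time; 1000 random 30-day streams for the alert
oracle comparison; 200 paired replicates of 500 allocations for the
randomization comparison. All randomness flows from one integer seed
through spawned `numpy.random.SeedSequence` children (per-participant
stream seeds, allocation stream, follow-up draws), so the full pipeline
is bit-reproducible: two runs with the same seed produce byte-identical
report files, which the test suite asserts.

## Known limitations

- Live vendor OAuth, push-style subscriptions, and intraday series are
  out of scope; the connector protocol defines the seam where a real
  vendor client would plug in.
- Message *content* tailoring is a pluggable hook; only scheduling,
  category tagging, and delivery-status bookkeeping are modeled.
- Coordinator authentication, encryption at rest, and compliance
  infrastructure are not modeled.
- The event log stores device-token fingerprints, not tokens, so
  replaying a persisted log yields links that must be re-authorized
  before a real sync could run.
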