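# weartrial

A headless, offline-testable engine for running the *operational* side of
a digital behavioral trial that collects data from consumer wearables and
connected scales: multi-phase screening with adaptive questionnaires,
covariate-adaptive randomization, rate-limit-aware device-data
synchronization, rule-based adherence alerting, and CONSORT/retention
reporting — plus a seeded synthetic-data simulator and a mock vendor
server so the entire pipeline runs with no network, no vendor accounts,
and no participants.

## Who this is for

Teams building or evaluating trial-management infrastructure for
mHealth/IoT studies (e.g. a remotely delivered weight-loss intervention
where participants self-monitor diet, activity, and weight through an
activity tracker and a smart scale). Every component is a plain Python
library with a thin `weartrial` CLI on top; state persists as JSON-lines
event logs and long-format CSV observation stores.

## What's inside

- **core** — an event-sourced participant registry. Participants move
  along a fixed funnel (`phase1_screen → phase2_screen → phase3_screen →
  baseline → randomized → completed`, with terminal `withdrawn` /
  `ineligible` states). Every mutation is an append-only `StudyEvent`;
  replaying the log reconstructs the registry exactly, which makes every
  report auditable.
- **questionnaire** — definitions with typed items, single-item branch
  rules (first match wins, skipped items recorded as *not presented*),
  declarative score and flag rules, and public/private submission tokens.
- **screening** — declarative eligibility criteria (including BMI derived
  from self-reported height/weight as kg/m², bounds inclusive: 27–43
  admits exactly 27.0 and 43.0; age ≥ 18; smartphone use), automatic
  phase advancement, and the coordinator's 5-day food-diary review.
- **randomization** — Pocock–Simon minimization. For each arriving
  participant with factor levels $x_f$, the candidate score for arm $a$ is

  $$G(a) = \sum_f w_f \cdot \mathrm{spread}_{a'}\big(n_{f,x_f,a'} + \mathbb{1}[a'=a]\big),$$

  with spread = range (max − min) or population variance over arms. A
  biased coin picks the minimizing arm with probability $p$ (default 0.8,
  ties broken by a fair draw from the seeded stream), otherwise a uniform
  draw among the rest. With $p = 1$ and one factor this degenerates to
  marginal balancing with $|n_A - n_B| \le 1$ in every level.
- **devicesync** — one API call per (endpoint, day), a half-open pull
  window covering the last 7 calendar days, and a *sliding* 3600-second
  quota of 100 calls per account per hour. Excess jobs are deferred with
  a next-eligible time and promoted FIFO; observations deduplicate by
  `(participant, metric, date, source)` with last-writer-wins conflicts.
- **monitoring** — four adherence rules scanned daily over the 7
  calendar dates ending at the scan date: no food entries, no weights,
  no tracker data (steps/heart rate/sleep jointly), and a recorded
  weight change strictly exceeding 5 lb within the window. Plus
  3-per-day tailored feedback message scheduling for the intervention
  arm and local delivered/opened/missed usage aggregation.
- **reporting** — CONSORT funnel aggregation from the event log (JSON
  and Graphviz DOT), withdrawal-adjusted retention
  (`rate = 100 · completers / (randomized − withdrawn before)`, half-up
  to 2 decimals), and whole-study snapshots.
- **synthdata** — seeded cohort and observation-stream generators
  (negative-binomial steps, trend-plus-noise weight, alternating
  adherent/missing runs with geometric lengths, optional upload delays)
  and a quota-enforcing mock vendor server.

## Worked example

```python
import json
from weartrial import (SimulationConfig, CohortParams, StreamParams,
                       run_study, retention)

cfg = SimulationConfig()
cfg.cohort = CohortParams(n=300)
cfg.stream = StreamParams(days=14)
run = run_study(cfg, seed=1)

flow = json.loads(run.reports["consort.json"])
for p in flow["phases"]:
    print(f"{p['phase']:>14}: entered {p['entered']:4d}  "
          f"eligible {p['eligible']:4d}  ineligible {p['ineligible']:4d}  "
          f"pending {p['pending']}")
print("randomized:", flow["randomized"], "arms:", flow["arms"])
```

prints the screening funnel for 300 synthetic registrants:

```
 phase1_screen: entered  300  eligible  231  ineligible   69  pending 0
 phase2_screen: entered  231  eligible  169  ineligible   62  pending 0
 phase3_screen: entered  169  eligible  108  ineligible   61  pending 0
      baseline: entered  108  eligible   97  ineligible    0  pending 11
randomized: 97 arms: {'sm_feedback': 50, 'sm_only': 47}
```

Each row conserves exactly (`entered = eligible + ineligible + pending`)
and each phase's eligible count is the next phase's entered count. The
97 randomized participants then stream 5769 observations through the
rate-limited scheduler over 14 days; the daily alert scan raises 17
adherence alerts (7 food gaps, 6 weighing gaps, 4 tracker gaps) under
the default missingness model. Retention arithmetic is exact:

```python
>>> r = retention(502, 9, 394)   # randomized, withdrawn before, completers
>>> f"{r.rate_percent}% ({r.completers}/{r.denominator})"
'79.92% (394/493)'
```

The same numbers come out of the CLI:

```bash
weartrial simulate --seed 1 --n 300 --days 14 --out run/
weartrial report retention --randomized 502 --withdrawn 9 --completers 394
```

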