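"""CONSORT funnel aggregation and withdrawal-adjusted retention.

Everything here is a pure function of the append-only event log (plus,
for snapshots, the observation store), so reports are replayable: the
same log always yields the same numbers.

Retention for an assessment uses the denominator
``randomized − withdrawn before that assessment`` — participants who
formally withdrew are no longer expected at follow-up — and reports the
completion percentage half-up-rounded to two decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

from pydantic import BaseModel

from .core import EventKind, Study, StudyEvent, StudyPhase, FUNNEL
from .monitoring import MonitoringConfig, scan_alerts

SCREEN_PHASES = (
    StudyPhase.PHASE1_SCREEN,
    StudyPhase.PHASE2_SCREEN,
    StudyPhase.PHASE3_SCREEN,
    StudyPhase.BASELINE,
)


@dataclass
class PhaseNode:
    phase: str
    entered: int = 0
    eligible: int = 0
    ineligible: int = 0
    pending: int = 0


@dataclass
class AssessmentNode:
    label: str
    due: int = 0
    completed: int = 0
    withdrawn_before: int = 0


@dataclass
class ConsortFlow:
    phases: list[PhaseNode] = field(default_factory=list)
    randomized: int = 0
    arms: dict[str, int] = field(default_factory=dict)
    assessments: list[AssessmentNode] = field(default_factory=list)

    def phase(self, name: str) -> PhaseNode:
        for node in self.phases:
            if node.phase == name:
                return node
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "phases": [vars(p) for p in self.phases],
            "randomized": self.randomized,
            "arms": dict(sorted(self.arms.items())),
            "assessments": [vars(a) for a in self.assessments],
        }

    def to_dot(self) -> str:
        """Graphviz DOT rendering of the funnel."""
        lines = ["digraph consort {", "  node [shape=box];"]
        prev = None
        for node in self.phases:
            nid = node.phase
            lines.append(
                f'  {nid} [label="{nid}\\nentered {node.entered}\\n'
                f'eligible {node.eligible} / ineligible {node.ineligible}"];'
            )
            if prev is not None:
                lines.append(f"  {prev} -> {nid};")
            prev = nid
        lines.append(f'  randomized [label="randomized {self.randomized}"];')
        if prev:
            lines.append(f"  {prev} -> randomized;")
        for arm, n in sorted(self.arms.items()):
            lines.append(f'  "arm_{arm}" [label="{arm}\\nn={n}"];')
            lines.append(f'  randomized -> "arm_{arm}";')
        for a in self.assessments:
            lines.append(
                f'  "{a.label}" [label="{a.label}\\ndue {a.due}\\n'
                f'completed {a.completed}"];'
            )
            lines.append(f'  randomized -> "{a.label}";')
        lines.append("}")
        return "\n".join(lines)


class ReportingError(Exception):
    pass


def consort_flow(
    event_log: Iterable[StudyEvent],
    assessment_labels: tuple[str, ...] = ("6mo", "12mo"),
) -> ConsortFlow:
    """Aggregate the event log into a CONSORT-style funnel.

    Counts are derived solely from events. Conservation holds by
    construction: entered(k) = eligible(k) + ineligible(k) + pending(k),
    where pending also covers participants who withdrew mid-screening,
    and entered(k+1) = eligible(k).
    """
    events = list(event_log)
    last_ts: dict[str, datetime] = {}
    for ev in events:
        prev = last_ts.get(ev.study_id)
        if prev is not None and ev.timestamp < prev:
            raise ReportingError(
                f"corrupted log: out-of-order events for {ev.study_id}"
            )
        last_ts[ev.study_id] = ev.timestamp

    nodes = {p.value: PhaseNode(phase=p.value) for p in SCREEN_PHASES}
    flow = ConsortFlow(phases=[nodes[p.value] for p in SCREEN_PHASES])

    withdrawn: set[str] = set()
    assessed: dict[str, set[str]] = {lab: set() for lab in assessment_labels}
    randomized_ids: list[str] = []
    for ev in events:
        if ev.kind is EventKind.REGISTERED:
            nodes[StudyPhase.PHASE1_SCREEN.value].entered += 1
        elif ev.kind is EventKind.ELIGIBLE:
            phase = ev.payload["phase"]
            if phase in nodes:
                nodes[phase].eligible += 1
                nxt = FUNNEL[FUNNEL.index(StudyPhase(phase)) + 1]
                if nxt.value in nodes:
                    nodes[nxt.value].entered += 1
        elif ev.kind is EventKind.INELIGIBLE:
            phase = ev.payload.get("phase")
            if phase in nodes:
                nodes[phase].ineligible += 1
        elif ev.kind is EventKind.RANDOMIZED:
            # leaving baseline counts as that phase's "eligible" outcome
            nodes[StudyPhase.BASELINE.value].eligible += 1
            flow.randomized += 1
            arm = ev.payload.get("arm", "")
            flow.arms[arm] = flow.arms.get(arm, 0) + 1
            randomized_ids.append(ev.study_id)
        elif ev.kind is EventKind.WITHDRAWN:
            withdrawn.add(ev.study_id)
        elif ev.kind is EventKind.ASSESSED:
            lab = ev.payload.get("label")
            if lab in assessed:
                assessed[lab].add(ev.study_id)

    for node in flow.phases:
        node.pending = node.entered - node.eligible - node.ineligible

    rand_set = set(randomized_ids)
    for lab in assessment_labels:
        completed = assessed[lab] & rand_set
        wd_before = {
            sid for sid in withdrawn & rand_set if sid not in assessed[lab]
        }
        flow.assessments.append(
            AssessmentNode(
                label=lab,
                due=flow.randomized - len(wd_before),
                completed=len(completed),
                withdrawn_before=len(wd_before),
            )
        )
    return flow


class RetentionReport(BaseModel):
    assessment: str
    randomized_n: int
    withdrawn_before: int
    completers: int
    denominator: int
    rate_percent: float


def retention(
    randomized_n: int,
    withdrawn_before: int,
    completers: int,
    assessment: str = "",
) -> RetentionReport:
    """Withdrawal-adjusted retention for one scheduled assessment.

    denominator = randomized − withdrawn before the assessment;
    rate = 100 · completers / denominator, half-up to 2 decimals.
    """
    denominator = randomized_n - withdrawn_before
    if not (0 <= completers <= denominator <= randomized_n):
        raise ReportingError(
            f"invalid retention counts: {completers}/{denominator}"
            f" of {randomized_n}"
        )
    if denominator == 0:  # nobody due (e.g. a study with no randomizations)
        rate = 0.0
    else:
        rate = float(
            (Decimal(100 * completers) / Decimal(denominator)).quantize(
                Decimal("0.01"), rounding=ROUND_HALF_UP
            )
        )
    return RetentionReport(
        assessment=assessment,
        randomized_n=randomized_n,
        withdrawn_before=withdrawn_before,
        completers=completers,
        denominator=denominator,
        rate_percent=rate,
    )


def retention_from_flow(flow: ConsortFlow) -> list[RetentionReport]:
    return [
        retention(flow.randomized, a.withdrawn_before, a.completed, a.label)
        for a in flow.assessments
    ]


def study_snapshot(
    study: Study,
    store,
    as_of: date,
    config: Optional[MonitoringConfig] = None,
    assessment_labels: tuple[str, ...] = ("6mo", "12mo"),
) -> dict:
    """One-page dashboard: funnel counts, open alerts, payments.

    A pure composition of :func:`consort_flow`, the alert scan, and the
    payment-event tally; serializing with sorted keys makes snapshots
    byte-comparable across runs.
    """
    flow = consort_flow(study.events, assessment_labels)
    open_alerts = []
    for p in sorted(study.participants.values(), key=lambda p: p.study_id):
        for alert in scan_alerts(store, p, as_of, config):
            open_alerts.append(
                {"study_id": alert.study_id, "rule": alert.rule.value}
            )
    paid = sum(
        float(ev.payload.get("amount", 0.0))
        for ev in study.events
        if ev.kind is EventKind.PAID
    )
    return {
        "as_of": as_of.isoformat(),
        "consort": flow.to_dict(),
        "open_alerts": open_alerts,
        "open_alert_count": len(open_alerts),
        "remuneration_total": paid,
        "retention": [
            r.model_dump() for r in retention_from_flow(flow)
        ],
    }


def snapshot_json(snapshot: dict) -> str:
    return json.dumps(snapshot, sort_keys=True, indent=2)
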