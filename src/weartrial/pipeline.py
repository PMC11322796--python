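"""End-to-end offline study simulation.

``run_study`` wires every module together: generate a cohort, push it
through the three-phase screening funnel, randomize the survivors by
minimization, link mock device accounts, serve synthetic observation
streams through the rate-limited sync scheduler, scan adherence alerts
daily, schedule feedback messages for the intervention arm, simulate
follow-up assessments and withdrawals, and render the CONSORT, retention,
alert, and snapshot reports.

Everything is driven by one integer seed through spawned
``numpy.random.SeedSequence`` children, so two runs with the same seed
produce byte-identical report text.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Optional

import numpy as np
import pandas as pd

from .core import Study, StudyPhase, Vendor
from .devicesync import (
    Endpoint,
    Metric,
    ObservationRecord,
    ObservationStore,
    SyncPlanner,
)
from .fixtures import (
    ARMS,
    FACTORS,
    default_criteria,
    phase1_questionnaire,
    phase2_questionnaire,
)
from .monitoring import (
    AlertScanner,
    MessageStatus,
    MonitoringConfig,
    schedule_feedback,
    usage_summary,
)
from .questionnaire import QuestionnaireRegistry
from .randomization import AllocationConfig, Minimizer
from .reporting import consort_flow, retention_from_flow, snapshot_json, study_snapshot
from .screening import (
    Outcome,
    ScreeningDecision,
    evaluate_eligibility,
    review_food_diary,
)
from .synthdata import (
    CohortParams,
    MockDeviceServer,
    StreamParams,
    generate_cohort,
    generate_streams,
)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated trial run."""

    cohort: CohortParams = field(default_factory=CohortParams)
    stream: StreamParams = field(default_factory=StreamParams)
    monitoring: MonitoringConfig = field(default_factory=MonitoringConfig)
    window_days: int = 7
    quota_per_hour: int = 100
    assignment_prob: float = 0.8
    start_date: date = date(2020, 1, 6)
    #: follow-up behavior, set to the evaluated trial's observed rates
    p_withdraw_before_6mo: float = 4 / 502
    p_withdraw_before_12mo: float = 5 / 498
    p_complete_6mo: float = 423 / 498
    p_complete_12mo: float = 394 / 493
    #: message outcome mix for the feedback arm
    p_msg_opened: float = 0.55
    p_msg_missed: float = 0.15
    monitor: bool = True


@dataclass
class StudyRun:
    study: Study
    store: ObservationStore
    planner: Optional[SyncPlanner]
    scanner: Optional[AlertScanner]
    reports: dict[str, str]


def run_study(config: Optional[SimulationConfig] = None, seed: int = 0) -> StudyRun:
    """Simulate a full trial offline; deterministic per seed."""
    cfg = config or SimulationConfig()
    root = np.random.SeedSequence(seed)
    (ss_cohort, ss_alloc, ss_streams, ss_diary, ss_followup,
     ss_msgs) = root.spawn(6)

    study = Study(id_prefix="SM")
    registry = QuestionnaireRegistry()
    q1, q2 = phase1_questionnaire(), phase2_questionnaire()
    registry.publish(q1)
    registry.publish(q2)
    criteria = default_criteria()

    cohort = generate_cohort(cfg.cohort, seed=int(ss_cohort.generate_state(1)[0] % 2**31))
    diary_rng = np.random.default_rng(ss_diary)

    minimizer = Minimizer(
        AllocationConfig(
            factors=FACTORS,
            arms=list(ARMS),
            assignment_prob=cfg.assignment_prob,
        ),
        seed=int(ss_alloc.generate_state(1)[0] % 2**31),
    )

    t0 = datetime(cfg.start_date.year, cfg.start_date.month, cfg.start_date.day)
    randomized: list[tuple[str, object]] = []  # (study_id, candidate)

    for i, cand in enumerate(cohort):
        ts = t0 + timedelta(minutes=i)
        p = study.register_participant({"email": cand.email}, ts)
        sid = p.study_id

        # phase 1: private link, submit, auto-screen
        token = registry.issue_link(q1.qid, study_id=sid, single_use=True)
        registry.submit(token, cand.phase1_answers, ts)
        study.record_submission(sid, q1.qid, ts)
        d1 = evaluate_eligibility(
            criteria, cand.phase1_answers, sid, StudyPhase.PHASE1_SCREEN, ts
        )
        if d1.outcome is not Outcome.ELIGIBLE:
            study.mark_ineligible(sid, ts, d1.failed_criteria or d1.missing_inputs)
            continue
        study.mark_eligible(sid, ts)

        # phase 2
        ts2 = ts + timedelta(days=2)
        token = registry.issue_link(q2.qid, study_id=sid, single_use=True)
        registry.submit(token, cand.phase2_answers, ts2)
        study.record_submission(sid, q2.qid, ts2)
        d2 = evaluate_eligibility(
            criteria, cand.phase2_answers, sid, StudyPhase.PHASE2_SCREEN, ts2
        )
        if d2.outcome is not Outcome.ELIGIBLE:
            study.mark_ineligible(sid, ts2, d2.failed_criteria)
            continue
        study.mark_eligible(sid, ts2)

        # phase 3: 5-day food diary, coordinator sign-off
        ts3 = ts2 + timedelta(days=7)
        diary_start = ts3.date()
        n_days = 5 if cand.phase3_pass else int(diary_rng.integers(0, 5))
        diary = [
            ObservationRecord(
                study_id=sid, metric=Metric.FOOD_ENTRY,
                timestamp=diary_start + timedelta(days=k), value=3,
            )
            for k in range(n_days)
        ]
        summary = review_food_diary(diary, diary_start, 5, min_days=5)
        d3 = ScreeningDecision(
            study_id=sid,
            phase=StudyPhase.PHASE3_SCREEN,
            outcome=Outcome.ELIGIBLE if summary.passed else Outcome.INELIGIBLE,
            failed_criteria=[] if summary.passed else ["food_diary_5_of_5"],
            decided_at=ts3 + timedelta(days=5),
            decided_by="coordinator",
        )
        ts3e = ts3 + timedelta(days=5)
        if d3.outcome is Outcome.ELIGIBLE:
            study.mark_eligible(sid, ts3e)
        else:
            study.mark_ineligible(sid, ts3e, d3.failed_criteria)
            continue

        # baseline assessment -> randomization
        if not cand.baseline_pass:
            continue  # never completed baseline: stays pending there
        tsr = ts3e + timedelta(days=14)
        levels = cand.factor_levels
        arm = minimizer.allocate(sid, levels)
        study.randomize(sid, arm, tsr, factor_levels=levels)
        study.link_device(sid, Vendor.WEARABLE_VENDOR, f"tok-w-{sid}",
                          tsr.date(), timestamp=tsr)
        study.link_device(sid, Vendor.SCALE_VENDOR, f"tok-s-{sid}",
                          tsr.date(), timestamp=tsr)
        randomized.append((sid, cand))

    # ------------------------------------------------------------------ #
    # monitoring period: serve streams via the mock vendor, sync daily,
    # scan alerts, schedule feedback messages

    store = ObservationStore()
    planner: Optional[SyncPlanner] = None
    scanner: Optional[AlertScanner] = None
    message_log: list = []
    app_open_log: list[tuple[str, datetime]] = []
    horizon_start = cfg.stream.start
    horizon_days = cfg.stream.days if cfg.monitor else 0

    if cfg.monitor and randomized:
        server = MockDeviceServer(quota_per_hour=cfg.quota_per_hour)
        stream_children = ss_streams.spawn(len(randomized))
        for (sid, cand), child in zip(randomized, stream_children):
            params = cfg.stream.model_copy(
                update={"weight_baseline_lb": cand.weight_lb}
            )
            server.load(
                sid,
                generate_streams(sid, params,
                                 seed=int(child.generate_state(1)[0] % 2**31)),
            )
        planner = SyncPlanner(
            window_days=cfg.window_days, limit_per_hour=cfg.quota_per_hour
        )
        scanner = AlertScanner(cfg.monitoring)
        msg_rng = np.random.default_rng(ss_msgs)
        accounts = [sid for sid, _ in randomized]
        linked = set(accounts)
        for k in range(1, horizon_days + 1):
            # sync runs nightly at 02:00 study time for the window ending
            # at the current simulated day
            now = datetime.combine(horizon_start + timedelta(days=k),
                                   datetime.min.time()) + timedelta(hours=2)
            planner.plan_sync(accounts, list(Endpoint), now, linked=linked)
            planner.promote_deferred(now)
            planner.run(server, store, now)
            scan_day = horizon_start + timedelta(days=k - 1)
            for sid, cand in randomized:
                participant = study.get(sid)
                scanner.scan(store, participant, scan_day)
                day_end = scan_day + timedelta(days=1)
                present = {
                    "diet": bool(store.dates_with_data(
                        sid, [Metric.FOOD_ENTRY], start=scan_day, end=day_end)),
                    "activity": bool(store.dates_with_data(
                        sid, [Metric.STEPS], start=scan_day, end=day_end)),
                    "weight": bool(store.dates_with_data(
                        sid, [Metric.WEIGHT], start=scan_day, end=day_end)),
                }
                for ev in schedule_feedback(participant, present, scan_day,
                                            cfg.monitoring):
                    u = msg_rng.random()
                    if u < cfg.p_msg_opened:
                        ev.status = MessageStatus.OPENED
                    elif u < cfg.p_msg_opened + cfg.p_msg_missed:
                        ev.status = MessageStatus.MISSED
                    message_log.append(ev)
                    if ev.status is MessageStatus.OPENED:
                        app_open_log.append((sid, ev.scheduled_at))

    # ------------------------------------------------------------------ #
    # follow-up assessments and withdrawals at the observed trial rates

    follow_rng = np.random.default_rng(ss_followup)
    base_after = t0 + timedelta(days=400)  # after every screening event
    for sid, _cand in randomized:
        t6 = base_after + timedelta(days=183)
        t12 = base_after + timedelta(days=365)
        if follow_rng.random() < cfg.p_withdraw_before_6mo:
            study.record_withdrawal(sid, (base_after + timedelta(days=90)).date(),
                                    "health", base_after + timedelta(days=90))
            continue
        if follow_rng.random() < cfg.p_complete_6mo:
            study.record_assessment(sid, "6mo", t6)
        if follow_rng.random() < cfg.p_withdraw_before_12mo:
            study.record_withdrawal(sid, (t6 + timedelta(days=60)).date(),
                                    "health", t6 + timedelta(days=60))
            continue
        if follow_rng.random() < cfg.p_complete_12mo:
            study.record_assessment(sid, "12mo", t12)
        study.record_payment(sid, 50.0, t12 + timedelta(days=1))

    # ------------------------------------------------------------------ #
    # reports

    flow = consort_flow(study.events)
    reports: dict[str, str] = {}
    reports["consort.json"] = json.dumps(flow.to_dict(), sort_keys=True, indent=2)
    reports["consort.dot"] = flow.to_dot()

    ret = retention_from_flow(flow)
    buf = io.StringIO()
    pd.DataFrame([r.model_dump() for r in ret]).to_csv(buf, index=False)
    reports["retention.csv"] = buf.getvalue()

    if scanner is not None:
        alert_rows = [
            {
                "study_id": a.study_id,
                "rule": a.rule.value,
                "window_start": a.window_start.isoformat(),
                "window_end": a.window_end.isoformat(),
                "details": json.dumps(a.details, sort_keys=True),
            }
            for a in scanner.raised
        ]
        buf = io.StringIO()
        pd.DataFrame(
            alert_rows,
            columns=["study_id", "rule", "window_start", "window_end", "details"],
        ).to_csv(buf, index=False)
        reports["alerts.csv"] = buf.getvalue()
        reports["usage.json"] = json.dumps(
            usage_summary(
                message_log, app_open_log,
                (horizon_start, horizon_start + timedelta(days=horizon_days)),
            ),
            sort_keys=True, indent=2,
        )

    as_of = horizon_start + timedelta(days=max(horizon_days - 1, 0))
    reports["snapshot.json"] = snapshot_json(
        study_snapshot(study, store, as_of, cfg.monitoring)
    )
    return StudyRun(
        study=study, store=store, planner=planner, scanner=scanner,
        reports=reports,
    )
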