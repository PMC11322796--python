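"""Adherence alert rules vs a brute-force oracle; feedback and usage."""

from datetime import date, datetime, timedelta

import numpy as np
import pytest

from weartrial.core import Participant, StudyPhase, Withdrawal
from weartrial.devicesync import Metric, ObservationRecord, ObservationStore
from weartrial.monitoring import (
    SM_CATEGORIES,
    AlertRule,
    AlertScanner,
    MessageEvent,
    MessageStatus,
    MonitoringConfig,
    scan_alerts,
    schedule_feedback,
    usage_summary,
)
from weartrial.units import lb_to_kg

D0 = date(2020, 3, 1)


def participant(arm="sm_feedback", phase=StudyPhase.RANDOMIZED, withdrawn=False):
    return Participant(
        study_id="SM0001",
        enrollment_date=date(2020, 1, 6),
        phase=phase,
        arm=arm,
        withdrawal=Withdrawal(date=date(2020, 2, 1)) if withdrawn else None,
    )


def fill_store(food_days=(), weight_lb_by_day=(), tracker_days=()):
    """Build a store from day offsets relative to D0."""
    store = ObservationStore()
    recs = []
    for k in food_days:
        recs.append(ObservationRecord(
            study_id="SM0001", metric=Metric.FOOD_ENTRY,
            timestamp=D0 + timedelta(days=k), value=3))
    for k, w_lb in weight_lb_by_day:
        recs.append(ObservationRecord(
            study_id="SM0001", metric=Metric.WEIGHT,
            timestamp=D0 + timedelta(days=k), value=lb_to_kg(w_lb)))
    for k in tracker_days:
        recs.append(ObservationRecord(
            study_id="SM0001", metric=Metric.STEPS,
            timestamp=D0 + timedelta(days=k), value=8000))
    store.ingest(recs)
    return store


def oracle_scan(store, sid, as_of, threshold_lb=5.0, span=7):
    """Independent sliding-window oracle, O(n²): enumerate the window's
    dates explicitly and re-derive each rule from raw record lists."""
    days = [as_of - timedelta(days=k) for k in range(span)]
    all_recs = store.records(study_id=sid)
    out = set()

    def has_any(metrics):
        return any(
            r.timestamp in days and r.metric in metrics for r in all_recs
        )

    if not has_any({Metric.FOOD_ENTRY}):
        out.add(AlertRule.FOOD_GAP_7D)
    if not has_any({Metric.WEIGHT}):
        out.add(AlertRule.WEIGHT_GAP_7D)
    if not has_any({Metric.STEPS, Metric.HEART_RATE, Metric.SLEEP_MINUTES}):
        out.add(AlertRule.TRACKER_GAP_7D)
    weights = [r for r in all_recs
               if r.metric is Metric.WEIGHT and r.timestamp in days]
    for a in weights:
        for b in weights:
            change = abs(a.value - b.value) / 0.45359237
            if change > threshold_lb + 1e-9:
                out.add(AlertRule.WEIGHT_CHANGE_5LB_7D)
    return out


class TestScanAlerts:
    def test_fully_adherent_stream_raises_nothing(self):
        store = fill_store(
            food_days=range(14),
            weight_lb_by_day=[(k, 180.0) for k in range(14)],
            tracker_days=range(14),
        )
        assert scan_alerts(store, participant(), D0 + timedelta(days=13)) == []

    def test_empty_store_fires_all_three_gap_rules(self):
        alerts = scan_alerts(ObservationStore(), participant(), D0)
        assert {a.rule for a in alerts} == {
            AlertRule.FOOD_GAP_7D, AlertRule.WEIGHT_GAP_7D,
            AlertRule.TRACKER_GAP_7D,
        }

    def test_weight_drop_of_5_5_lb_within_window_fires_with_details(self):
        store = fill_store(
            food_days=range(14),
            tracker_days=range(14),
            weight_lb_by_day=[(0, 180.0), (5, 174.5)] + [(k, 177.0) for k in range(6, 14)],
        )
        alerts = scan_alerts(store, participant(), D0 + timedelta(days=6))
        change = [a for a in alerts if a.rule is AlertRule.WEIGHT_CHANGE_5LB_7D]
        assert len(change) == 1
        assert change[0].details["change_lb"] == pytest.approx(5.5)
        assert change[0].details["direction"] == "loss"

    def test_change_of_exactly_5_lb_does_not_fire(self):
        store = fill_store(
            food_days=range(14), tracker_days=range(14),
            weight_lb_by_day=[(0, 180.0), (5, 175.0)],
        )
        alerts = scan_alerts(store, participant(), D0 + timedelta(days=6))
        assert all(a.rule is not AlertRule.WEIGHT_CHANGE_5LB_7D for a in alerts)

    def test_change_just_over_5_lb_fires(self):
        store = fill_store(
            food_days=range(14), tracker_days=range(14),
            weight_lb_by_day=[(0, 180.0), (5, 174.9)],
        )
        alerts = scan_alerts(store, participant(), D0 + timedelta(days=6))
        assert any(a.rule is AlertRule.WEIGHT_CHANGE_5LB_7D for a in alerts)

    def test_gap_windows_span_exactly_seven_dates(self):
        # food on day 0 then nothing: the gap window [1..7] has no food,
        # so day 7 fires; day 6's window still contains day 0
        store = fill_store(
            food_days=[0], tracker_days=range(20),
            weight_lb_by_day=[(k, 180.0) for k in range(20)],
        )
        day6 = scan_alerts(store, participant(), D0 + timedelta(days=6))
        day7 = scan_alerts(store, participant(), D0 + timedelta(days=7))
        assert all(a.rule is not AlertRule.FOOD_GAP_7D for a in day6)
        assert any(a.rule is AlertRule.FOOD_GAP_7D for a in day7)

    @pytest.mark.parametrize("phase, withdrawn", [
        (StudyPhase.PHASE2_SCREEN, False),
        (StudyPhase.WITHDRAWN, True),
    ])
    def test_non_randomized_or_withdrawn_participants_not_scanned(
        self, phase, withdrawn
    ):
        p = participant(phase=phase, withdrawn=withdrawn)
        assert scan_alerts(ObservationStore(), p, D0) == []

    def test_random_sparse_streams_match_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        p = participant()
        for _ in range(300):
            store = fill_store(
                food_days=[int(k) for k in
                           rng.choice(30, rng.integers(0, 12), replace=False)],
                tracker_days=[int(k) for k in
                              rng.choice(30, rng.integers(0, 12), replace=False)],
                weight_lb_by_day=[
                    (int(k), float(rng.uniform(170, 186)))
                    for k in rng.choice(30, rng.integers(0, 8), replace=False)
                ],
            )
            for day in range(30):
                as_of = D0 + timedelta(days=day)
                got = {a.rule for a in scan_alerts(store, p, as_of)}
                assert got == oracle_scan(store, "SM0001", as_of)

    def test_prefix_scan_consistent_with_full_stream(self):
        # no look-ahead: scanning at day d only sees records dated <= d,
        # so adding future records never changes an earlier day's alerts
        prefix = fill_store(food_days=[0, 1], tracker_days=[0, 1],
                            weight_lb_by_day=[(0, 180.0)])
        full = fill_store(food_days=[0, 1, 20], tracker_days=[0, 1, 20],
                          weight_lb_by_day=[(0, 180.0), (20, 170.0)])
        p = participant()
        for day in range(10):
            as_of = D0 + timedelta(days=day)
            assert (
                {a.rule for a in scan_alerts(prefix, p, as_of)}
                == {a.rule for a in scan_alerts(full, p, as_of)}
            )

    def test_cooldown_suppresses_daily_re_raises(self):
        store = ObservationStore()  # permanent triple gap
        scanner = AlertScanner(MonitoringConfig(cooldown_days=7))
        p = participant()
        raised_days = []
        for day in range(21):
            got = scanner.scan(store, p, D0 + timedelta(days=day))
            if got:
                raised_days.append(day)
        assert raised_days == [0, 7, 14]


class TestScheduleFeedback:
    def test_feedback_arm_gets_exactly_three_messages(self):
        events = schedule_feedback(
            participant("sm_feedback"), {"diet": True}, D0
        )
        assert len(events) == 3
        assert [e.slot for e in events] == [1, 2, 3]
        assert {e.category for e in events} <= set(SM_CATEGORIES)

    def test_sm_only_arm_gets_none(self):
        assert schedule_feedback(participant("sm_only"), {}, D0) == []

    def test_zero_messages_per_day_config(self):
        cfg = MonitoringConfig(messages_per_day=0)
        assert schedule_feedback(participant(), {}, D0, cfg) == []

    def test_withdrawn_participant_gets_none(self):
        p = participant(withdrawn=True)
        assert schedule_feedback(p, {}, D0) == []

    def test_template_hook_sees_category_data_presence(self):
        events = schedule_feedback(
            participant(), {"diet": True, "activity": False, "weight": True}, D0
        )
        refs = {e.category: e.template_ref for e in events}
        assert refs["diet"] == "diet_present"
        assert refs["activity"] == "activity_absent"


class TestUsageSummary:
    def _log(self, n_users=10, days=7, missed_every=5):
        log, opens = [], []
        k = 0
        for u in range(n_users):
            for d in range(days):
                for slot in range(1, 4):
                    status = (MessageStatus.MISSED if k % missed_every == 0
                              else MessageStatus.DELIVERED)
                    ev = MessageEvent(
                        study_id=f"U{u}",
                        scheduled_at=datetime(2020, 3, 1 + d, 8 + slot),
                        slot=slot, status=status,
                    )
                    log.append(ev)
                    k += 1
            opens.append((f"U{u}", datetime(2020, 3, 1, 9)))
        return log, opens

    def test_empty_logs_give_zeros(self):
        out = usage_summary([], [], (D0, D0 + timedelta(days=7)))
        assert out["totals"] == {"scheduled": 0, "delivered": 0, "opened": 0,
                                 "missed": 0}

    def test_totals_match_direct_tally_and_partition(self):
        log, opens = self._log()
        out = usage_summary(log, opens, (D0, D0 + timedelta(days=7)))
        assert out["totals"]["scheduled"] == 10 * 3 * 7
        assert out["totals"]["missed"] == sum(
            1 for e in log if e.status is MessageStatus.MISSED
        )
        for day in out["daily"].values():
            assert (day["delivered"] + day["opened"] + day["missed"]
                    == day["scheduled"])

    def test_user_opening_everything_counts_fully_opened(self):
        log = [
            MessageEvent(study_id="U1",
                         scheduled_at=datetime(2020, 3, 1, 8 + s), slot=s,
                         status=MessageStatus.DELIVERED).mark_opened()
            for s in range(1, 4)
        ]
        out = usage_summary(log, [], (D0, D0 + timedelta(days=1)))
        assert out["totals"]["opened"] == out["totals"]["scheduled"] == 3

    def test_status_transition_only_delivered_to_opened(self):
        ev = MessageEvent(study_id="U1", scheduled_at=datetime(2020, 3, 1, 9),
                          slot=1, status=MessageStatus.MISSED)
        with pytest.raises(ValueError):
            ev.mark_opened()
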