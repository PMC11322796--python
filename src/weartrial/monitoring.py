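"""Adherence alert scanning and feedback-message bookkeeping.

Four data-quality rules run against the observation store for each
randomized, non-withdrawn participant:

``food_gap_7d``
    no food-log entries on any of the 7 calendar dates ending at the
    scan date;
``weight_gap_7d``
    likewise for self-weighing;
``tracker_gap_7d``
    likewise for the activity tracker, where *tracker data* means any of
    steps, heart rate, or sleep (a worn tracker produces all three, so
    joint absence is the gap signal);
``weight_change_5lb_7d``
    two recorded weights within the same 7-calendar-date window ending
    at the scan date differ by strictly more than 5 lb (max − min over
    the window's records, either direction; the observed change and its
    sign are reported in the alert details).

A change of exactly 5.0 lb does not fire — the threshold is strict.
Scans are evaluated daily; :class:`AlertScanner` adds a per-rule
cool-down (default 7 days) so a long gap re-raises periodically rather
than every day.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from enum import Enum
from typing import Iterable, Optional

from pydantic import BaseModel, Field

from .core import Participant, StudyPhase
from .devicesync import Metric, ObservationStore
from .units import kg_to_lb

TRACKER_METRICS = (Metric.STEPS, Metric.HEART_RATE, Metric.SLEEP_MINUTES)


class AlertRule(str, Enum):
    FOOD_GAP_7D = "food_gap_7d"
    WEIGHT_GAP_7D = "weight_gap_7d"
    WEIGHT_CHANGE_5LB_7D = "weight_change_5lb_7d"
    TRACKER_GAP_7D = "tracker_gap_7d"


class Alert(BaseModel):
    study_id: str
    rule: AlertRule
    window_start: date
    window_end: date  # inclusive; length matches the rule's span
    raised_at: Optional[datetime] = None
    details: dict = Field(default_factory=dict)


@dataclass
class MonitoringConfig:
    gap_days: int = 7
    weight_change_lb: float = 5.0
    weight_change_days: int = 7
    cooldown_days: int = 7
    messages_per_day: int = 3
    feedback_arm: str = "sm_feedback"


def scan_alerts(
    store: ObservationStore,
    participant: Participant,
    as_of: date,
    config: Optional[MonitoringConfig] = None,
) -> list[Alert]:
    """Evaluate all four rules on the window ending at ``as_of``.

    Only randomized, non-withdrawn participants are scanned; everyone
    else yields an empty list. On an empty store all three gap rules
    fire. Deterministic and free of look-ahead: only records dated in
    the scan window are consulted.
    """
    cfg = config or MonitoringConfig()
    if participant.phase is not StudyPhase.RANDOMIZED:
        return []
    if participant.withdrawal is not None:
        return []
    sid = participant.study_id
    alerts: list[Alert] = []
    gap_start = as_of - timedelta(days=cfg.gap_days - 1)

    def gap_alert(rule: AlertRule, metrics: Iterable[Metric]) -> None:
        dates = store.dates_with_data(
            sid, metrics, start=gap_start, end=as_of + timedelta(days=1)
        )
        if not dates:
            alerts.append(
                Alert(study_id=sid, rule=rule,
                      window_start=gap_start, window_end=as_of)
            )

    gap_alert(AlertRule.FOOD_GAP_7D, [Metric.FOOD_ENTRY])
    gap_alert(AlertRule.WEIGHT_GAP_7D, [Metric.WEIGHT])
    gap_alert(AlertRule.TRACKER_GAP_7D, TRACKER_METRICS)

    chg_start = as_of - timedelta(days=cfg.weight_change_days - 1)
    weights = store.records(
        study_id=sid, metric=Metric.WEIGHT,
        start=chg_start, end=as_of + timedelta(days=1),
    )
    if len(weights) >= 2:
        lo = min(weights, key=lambda r: r.value)
        hi = max(weights, key=lambda r: r.value)
        change_lb = kg_to_lb(hi.value - lo.value)
        # strict threshold; the 1e-9 guard absorbs lb->kg->lb round-trip
        # float error so an exactly-5.0 lb change never fires
        if change_lb > cfg.weight_change_lb + 1e-9:
            direction = "loss" if lo.timestamp > hi.timestamp else "gain"
            alerts.append(
                Alert(
                    study_id=sid,
                    rule=AlertRule.WEIGHT_CHANGE_5LB_7D,
                    window_start=chg_start,
                    window_end=as_of,
                    details={
                        "change_lb": round(change_lb, 2),
                        "direction": direction,
                        "from_date": min(lo.timestamp, hi.timestamp).isoformat(),
                        "to_date": max(lo.timestamp, hi.timestamp).isoformat(),
                    },
                )
            )
    return alerts


class AlertScanner:
    """Daily scanning with a per-(participant, rule) cool-down.

    ``scan`` is :func:`scan_alerts` plus suppression of alerts raised
    again within ``cooldown_days`` of the previous raise, so a 3-week
    gap produces an alert roughly weekly, not 15 copies.
    """

    def __init__(self, config: Optional[MonitoringConfig] = None) -> None:
        self.config = config or MonitoringConfig()
        self._last_raised: dict[tuple[str, str], date] = {}
        self.raised: list[Alert] = []

    def scan(
        self, store: ObservationStore, participant: Participant, as_of: date
    ) -> list[Alert]:
        out = []
        for alert in scan_alerts(store, participant, as_of, self.config):
            key = (alert.study_id, alert.rule.value)
            last = self._last_raised.get(key)
            if last is not None and (as_of - last).days < self.config.cooldown_days:
                continue
            self._last_raised[key] = as_of
            alert.raised_at = datetime(as_of.year, as_of.month, as_of.day)
            self.raised.append(alert)
            out.append(alert)
        return out


# ---------------------------------------------------------------------- #
# feedback messages


class MessageStatus(str, Enum):
    DELIVERED = "delivered"
    OPENED = "opened"
    MISSED = "missed"


class MessageEvent(BaseModel):
    study_id: str
    scheduled_at: datetime
    slot: int
    status: MessageStatus = MessageStatus.DELIVERED
    template_ref: str = ""
    category: str = ""

    def mark_opened(self) -> "MessageEvent":
        if self.status is not MessageStatus.DELIVERED:
            raise ValueError("only delivered messages can be opened")
        self.status = MessageStatus.OPENED
        return self


#: Self-monitoring categories feedback responds to.
SM_CATEGORIES = ("diet", "activity", "weight")


def default_template(category: str, has_data: bool) -> str:
    """Pluggable template-selection hook: returns an opaque template label.

    Message *content* tailoring lives outside this package; the engine
    only records which category-level template a slot used.
    """
    return f"{category}_{'present' if has_data else 'absent'}"


def schedule_feedback(
    participant: Participant,
    sm_data_present: dict[str, bool],
    day: date,
    config: Optional[MonitoringConfig] = None,
    template_hook=default_template,
) -> list[MessageEvent]:
    """Schedule the day's tailored messages for a feedback-arm participant.

    Exactly ``messages_per_day`` (default 3) events, slots spread over the
    day, each tagged with the self-monitoring category that selected its
    template. Participants outside the feedback arm receive nothing.
    """
    cfg = config or MonitoringConfig()
    if participant.arm != cfg.feedback_arm:
        return []
    if participant.phase is not StudyPhase.RANDOMIZED or participant.withdrawal:
        return []
    events = []
    for slot in range(1, cfg.messages_per_day + 1):
        category = SM_CATEGORIES[(slot - 1) % len(SM_CATEGORIES)]
        has_data = bool(sm_data_present.get(category, False))
        events.append(
            MessageEvent(
                study_id=participant.study_id,
                scheduled_at=datetime(day.year, day.month, day.day,
                                      8 + (slot - 1) * 5),
                slot=slot,
                template_ref=template_hook(category, has_data),
                category=category,
            )
        )
    return events


def usage_summary(
    message_log: Iterable[MessageEvent],
    app_open_log: Iterable[tuple[str, datetime]],
    period: tuple[date, date],
) -> dict:
    """Local usage aggregation: daily active users and message outcomes.

    ``period`` is half-open ``[start, end)``. Per-day message counts
    partition as delivered + opened + missed = scheduled.
    """
    start, end = period
    by_day: dict[str, dict[str, int]] = {}
    totals = {"scheduled": 0, "delivered": 0, "opened": 0, "missed": 0}
    for ev in message_log:
        d = ev.scheduled_at.date()
        if not (start <= d < end):
            continue
        day = by_day.setdefault(
            d.isoformat(),
            {"scheduled": 0, "delivered": 0, "opened": 0, "missed": 0,
             "active_users": 0},
        )
        day["scheduled"] += 1
        day[ev.status.value] += 1
        totals["scheduled"] += 1
        totals[ev.status.value] += 1
    active: dict[str, set[str]] = {}
    for sid, ts in app_open_log:
        d = ts.date()
        if start <= d < end:
            active.setdefault(d.isoformat(), set()).add(sid)
    for iso, users in active.items():
        by_day.setdefault(
            iso,
            {"scheduled": 0, "delivered": 0, "opened": 0, "missed": 0,
             "active_users": 0},
        )["active_users"] = len(users)
    return {
        "period": [start.isoformat(), end.isoformat()],
        "daily": {k: by_day[k] for k in sorted(by_day)},
        "totals": totals,
        "daily_active_users_mean": (
            sum(len(u) for u in active.values()) / max(1, (end - start).days)
        ),
    }
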