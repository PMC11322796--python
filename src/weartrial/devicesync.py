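"""Rate-limit-aware synchronization of device observations.

Vendor web APIs grant a bounded number of calls per account per hour
(default 100) and the study pulls only a bounded look-back window
(default the last 7 calendar days), one API call per (endpoint, day).
The planner emits one :class:`SyncJob` per (account, endpoint, day in the
pull window); jobs beyond an account's remaining rolling-hour budget are
deferred with a next-eligible time and granted FIFO once the window
frees up. Re-planning the same day is idempotent.

The quota is a *sliding* 3600-second window over granted call
timestamps, the conservative reading of a per-hour limit: at no instant
may any trailing hour contain more than ``limit_per_hour`` grants.

Observations land in an :class:`ObservationStore` keyed by
``(study_id, metric, date, source)``; exact duplicates are skipped and
same-key conflicts resolve to the record with the latest ``retrieved_at``
(last writer wins).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from enum import Enum
from typing import Any, Iterable, Optional, Protocol
from zoneinfo import ZoneInfo

import pandas as pd
from pydantic import BaseModel, model_validator

HOUR = timedelta(seconds=3600)


class Metric(str, Enum):
    STEPS = "steps"
    HEART_RATE = "heart_rate"
    SLEEP_MINUTES = "sleep_minutes"
    FOOD_ENTRY = "food_entry"
    WEIGHT = "weight"


class Endpoint(str, Enum):
    ACTIVITY = "activity"
    FOOD = "food"
    SLEEP = "sleep"
    WEIGHT = "weight"


#: Metrics served by each vendor endpoint (activity covers steps + HR).
ENDPOINT_METRICS: dict[Endpoint, tuple[Metric, ...]] = {
    Endpoint.ACTIVITY: (Metric.STEPS, Metric.HEART_RATE),
    Endpoint.FOOD: (Metric.FOOD_ENTRY,),
    Endpoint.SLEEP: (Metric.SLEEP_MINUTES,),
    Endpoint.WEIGHT: (Metric.WEIGHT,),
}

METRIC_UNITS: dict[Metric, str] = {
    Metric.STEPS: "count",
    Metric.HEART_RATE: "bpm",
    Metric.SLEEP_MINUTES: "min",
    Metric.FOOD_ENTRY: "entry",
    Metric.WEIGHT: "kg",
}


class ObservationRecord(BaseModel):
    """One metric value from one device at one (daily) timestamp."""

    study_id: str
    metric: Metric
    timestamp: date
    value: float
    unit: str = ""
    source: str = "mock"
    retrieved_at: Optional[datetime] = None

    @model_validator(mode="after")
    def _value_in_range(self) -> "ObservationRecord":
        if self.metric in (Metric.STEPS, Metric.SLEEP_MINUTES, Metric.FOOD_ENTRY):
            if self.value < 0:
                raise ValueError(f"{self.metric.value} must be >= 0")
        if self.metric is Metric.WEIGHT and self.value <= 0:
            raise ValueError("weight must be > 0")
        if not self.unit:
            self.unit = METRIC_UNITS[self.metric]
        return self

    def key(self) -> tuple[str, str, str, str]:
        return (self.study_id, self.metric.value, self.timestamp.isoformat(),
                self.source)


def pull_window(
    now: datetime, window_days: int = 7, tz: str | ZoneInfo = "America/New_York"
) -> tuple[date, date]:
    """Half-open look-back range ``[today − window_days, today)``.

    ``today`` is the calendar date of ``now`` in the study timezone, so
    the window always spans exactly ``window_days`` calendar dates, DST
    transitions included.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    zone = ZoneInfo(tz) if isinstance(tz, str) else tz
    if now.tzinfo is None:
        today = now.date()
    else:
        today = now.astimezone(zone).date()
    return today - timedelta(days=window_days), today


def window_dates(start: date, end: date) -> list[date]:
    """All calendar dates in a half-open ``[start, end)`` range."""
    return [start + timedelta(days=k) for k in range((end - start).days)]


class QuotaExceededError(Exception):
    def __init__(self, retry_at: datetime) -> None:
        super().__init__(f"hourly API quota exhausted; retry at {retry_at}")
        self.retry_at = retry_at


@dataclass
class RateBudget:
    """Sliding-window hourly call budget for one vendor account."""

    account: str
    limit_per_hour: int = 100
    call_log: list[datetime] = field(default_factory=list)

    def _window_calls(self, now: datetime) -> list[datetime]:
        lo = now - HOUR
        return [t for t in self.call_log if lo < t <= now]

    def remaining(self, now: datetime) -> int:
        return self.limit_per_hour - len(self._window_calls(now))

    def next_eligible(self, now: datetime) -> datetime:
        """Earliest instant at which one more call could be granted."""
        if self.remaining(now) > 0:
            return now
        window = sorted(self._window_calls(now))
        # the oldest in-window call ages out one hour after it was made
        overflow = len(window) - self.limit_per_hour
        return window[overflow] + HOUR

    def grant(self, now: datetime) -> None:
        if self.remaining(now) <= 0:
            raise QuotaExceededError(self.next_eligible(now))
        self.call_log.append(now)


def acquire(budget: RateBudget, n_calls: int, now: datetime) -> tuple[int, int]:
    """Grant up to the remaining rolling-hour budget; defer the rest.

    Returns ``(granted, deferred)`` and logs one timestamp per grant.
    """
    if n_calls < 0:
        raise ValueError("n_calls must be >= 0")
    granted = max(0, min(n_calls, budget.remaining(now)))
    for _ in range(granted):
        budget.call_log.append(now)
    return granted, n_calls - granted


class JobStatus(str, Enum):
    PENDING = "pending"
    GRANTED = "granted"
    DEFERRED = "deferred"
    DONE = "done"
    FAILED = "failed"


@dataclass
class SyncJob:
    account: str
    endpoint: Endpoint
    day: date
    status: JobStatus = JobStatus.PENDING
    next_eligible_at: Optional[datetime] = None

    def key(self) -> tuple[str, str, str]:
        return (self.account, self.endpoint.value, self.day.isoformat())


class Connector(Protocol):
    """Vendor API surface the scheduler talks to.

    A live connector would wrap a vendor OAuth API; the shipped
    implementation is the mock device server in :mod:`weartrial.synthdata`.
    Push-style subscriptions are part of the protocol surface conceptually
    but are not implemented anywhere in this package.
    """

    def fetch(self, account: str, endpoint: Endpoint, day: date,
              now: datetime) -> list[ObservationRecord]:
        ...


class SyncPlanner:
    """Daily scheduler: plans, grants under budget, runs, and retries.

    One job per (account, endpoint, day in the pull window); planning the
    same day twice adds no duplicates. Deferred jobs sit in a FIFO queue
    and are promoted by :meth:`promote_deferred` as the clock advances,
    so no job starves.
    """

    def __init__(
        self,
        window_days: int = 7,
        limit_per_hour: int = 100,
        tz: str = "America/New_York",
    ) -> None:
        self.window_days = window_days
        self.limit_per_hour = limit_per_hour
        self.tz = tz
        self.budgets: dict[str, RateBudget] = {}
        self.jobs: dict[tuple[str, str, str], SyncJob] = {}
        self._deferred: list[SyncJob] = []
        self.warnings: list[str] = []

    def budget_for(self, account: str) -> RateBudget:
        if account not in self.budgets:
            self.budgets[account] = RateBudget(
                account=account, limit_per_hour=self.limit_per_hour
            )
        return self.budgets[account]

    def plan_sync(
        self,
        accounts: Iterable[str],
        endpoints: Iterable[Endpoint],
        now: datetime,
        linked: Optional[set[str]] = None,
    ) -> list[SyncJob]:
        """Plan one day's synchronization for the given accounts.

        Grants jobs against each account's rolling-hour budget at ``now``
        (one call per endpoint-day); excess jobs are deferred with the
        budget's next-eligible time. Accounts without an active device
        link are skipped with a warning.
        """
        start, end = pull_window(now, self.window_days, self.tz)
        days = window_dates(start, end)
        new_jobs: list[SyncJob] = []
        endpoints = list(endpoints)
        for account in accounts:
            if linked is not None and account not in linked:
                self.warnings.append(f"account {account} has no active link; skipped")
                continue
            budget = self.budget_for(account)
            for ep in endpoints:
                for day in days:
                    job = SyncJob(account=account, endpoint=Endpoint(ep), day=day)
                    if job.key() in self.jobs:
                        continue  # idempotent re-plan
                    if budget.remaining(now) > 0:
                        budget.grant(now)
                        job.status = JobStatus.GRANTED
                    else:
                        job.status = JobStatus.DEFERRED
                        job.next_eligible_at = budget.next_eligible(now)
                        self._deferred.append(job)
                    self.jobs[job.key()] = job
                    new_jobs.append(job)
        return new_jobs

    def promote_deferred(self, now: datetime) -> list[SyncJob]:
        """Grant deferred jobs (FIFO per arrival) whose budget has freed."""
        promoted: list[SyncJob] = []
        still: list[SyncJob] = []
        for job in self._deferred:
            budget = self.budget_for(job.account)
            if budget.remaining(now) > 0:
                budget.grant(now)
                job.status = JobStatus.GRANTED
                job.next_eligible_at = None
                promoted.append(job)
            else:
                job.next_eligible_at = budget.next_eligible(now)
                still.append(job)
        self._deferred = still
        return promoted

    def run(
        self, connector: Connector, store: "ObservationStore", now: datetime
    ) -> "IngestDelta":
        """Execute every granted job against the connector and ingest."""
        batch: list[ObservationRecord] = []
        for job in self.jobs.values():
            if job.status is not JobStatus.GRANTED:
                continue
            try:
                records = connector.fetch(job.account, job.endpoint, job.day, now)
            except QuotaExceededError as exc:
                job.status = JobStatus.DEFERRED
                job.next_eligible_at = exc.retry_at
                self._deferred.append(job)
                continue
            for rec in records:
                if rec.retrieved_at is None:
                    rec.retrieved_at = now
            batch.extend(records)
            job.status = JobStatus.DONE
        return store.ingest(batch)


@dataclass
class IngestDelta:
    inserted: int = 0
    duplicates_skipped: int = 0
    conflicts: int = 0
    rejected: int = 0


class ObservationStore:
    """Deduplicated long-format store of device observations."""

    def __init__(self) -> None:
        self._records: dict[tuple[str, str, str, str], ObservationRecord] = {}
        # per-participant view of the same records, for O(1) scan queries
        self._by_sid: dict[str, dict[tuple[str, str, str, str], ObservationRecord]] = {}

    def __len__(self) -> int:
        return len(self._records)

    def ingest(self, records: Iterable[Any]) -> IngestDelta:
        """Insert records idempotently.

        Exact duplicates (same key, same value) are skipped; same-key
        records with a different value are conflicts, resolved in favor
        of the latest ``retrieved_at``. Malformed records are rejected
        individually and the batch continues.
        """
        delta = IngestDelta()
        for raw in records:
            try:
                rec = (
                    raw
                    if isinstance(raw, ObservationRecord)
                    else ObservationRecord.model_validate(raw)
                )
            except Exception:
                delta.rejected += 1
                continue
            key = rec.key()
            existing = self._records.get(key)
            if existing is None:
                self._records[key] = rec
                self._by_sid.setdefault(rec.study_id, {})[key] = rec
                delta.inserted += 1
            elif existing.value == rec.value:
                delta.duplicates_skipped += 1
            else:
                delta.conflicts += 1
                old_t = existing.retrieved_at or datetime.min
                new_t = rec.retrieved_at or datetime.min
                if new_t >= old_t:
                    self._records[key] = rec
                    self._by_sid.setdefault(rec.study_id, {})[key] = rec
        return delta

    def records(
        self,
        study_id: Optional[str] = None,
        metric: Optional[Metric] = None,
        start: Optional[date] = None,
        end: Optional[date] = None,
    ) -> list[ObservationRecord]:
        pool = (
            self._by_sid.get(study_id, {}).values()
            if study_id is not None
            else self._records.values()
        )
        out = []
        for rec in pool:
            if metric is not None and rec.metric is not metric:
                continue
            if start is not None and rec.timestamp < start:
                continue
            if end is not None and rec.timestamp >= end:
                continue
            out.append(rec)
        out.sort(key=lambda r: r.key())
        return out

    def dates_with_data(
        self, study_id: str, metrics: Iterable[Metric],
        start: Optional[date] = None, end: Optional[date] = None,
    ) -> set[date]:
        metrics = set(metrics)
        return {
            r.timestamp
            for r in self._by_sid.get(study_id, {}).values()
            if r.metric in metrics
            and (start is None or r.timestamp >= start)
            and (end is None or r.timestamp < end)
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "study_id": r.study_id,
                "metric": r.metric.value,
                "timestamp": r.timestamp.isoformat(),
                "value": r.value,
                "unit": r.unit,
                "source": r.source,
                "retrieved_at": r.retrieved_at.isoformat() if r.retrieved_at else "",
            }
            for r in self.records()
        ]
        return pd.DataFrame(
            rows,
            columns=["study_id", "metric", "timestamp", "value", "unit",
                     "source", "retrieved_at"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ObservationStore":
        df = pd.read_csv(path, dtype=str).fillna("")
        store = cls()
        recs = []
        for row in df.itertuples(index=False):
            recs.append(
                ObservationRecord(
                    study_id=row.study_id,
                    metric=Metric(row.metric),
                    timestamp=date.fromisoformat(row.timestamp),
                    value=float(row.value),
                    unit=row.unit,
                    source=row.source,
                    retrieved_at=(
                        datetime.fromisoformat(row.retrieved_at)
                        if row.retrieved_at
                        else None
                    ),
                )
            )
        store.ingest(recs)
        return store
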