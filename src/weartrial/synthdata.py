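"""Seeded synthetic cohorts, observation streams, and a mock device server.

This module stands in for the recruitment stream and the wearable/IoT
vendor clouds so the entire pipeline — screen, randomize, sync, alert,
report — runs offline and is reproducible from a single seed.

Cohort defaults mirror the evaluated study's funnel: demographics are
drawn so that roughly 7 in 10 phase-1 candidates are auto-eligible
(adult, BMI inside the 27–43 window, smartphone user), and the later
phases pass at the ratios the trial observed (≈0.73 phase-2, ≈0.65
phase-3 diary, ≈0.85 baseline-to-randomization). Distributions straddle
every eligibility boundary so the screening logic is genuinely
exercised.

Observation streams emulate daily self-monitoring: overdispersed
(negative-binomial) step counts, resting heart rate, sleep minutes,
food-log entry counts, and a weight series that is baseline plus a
linear trend plus day-to-day noise. Adherence follows an alternating
renewal process — adherent runs and missing runs with geometric
lengths — which reproduces the multi-day gaps the alert rules target.
Records can carry an upload delay, emulating devices that sync late.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Any, Optional

import numpy as np
from pydantic import BaseModel, model_validator

from .devicesync import (
    ENDPOINT_METRICS,
    Endpoint,
    Metric,
    ObservationRecord,
    RateBudget,
)
from .fixtures import bmi_category
from .units import KG_PER_LB, M_PER_IN, lb_to_kg


class CohortParams(BaseModel):
    """Cohort size, demographic distributions, and per-phase pass rates."""

    n: int = 1741
    age_mean: float = 45.0
    age_sd: float = 14.0
    bmi_mean: float = 34.0
    bmi_sd: float = 6.0
    height_in_mean: float = 66.0
    height_in_sd: float = 4.0
    smartphone_rate: float = 0.95
    phase2_pass: float = 0.725
    phase3_pass: float = 0.653
    baseline_pass: float = 0.849
    seed: int = 0

    @model_validator(mode="after")
    def _valid(self) -> "CohortParams":
        for p in (self.smartphone_rate, self.phase2_pass, self.phase3_pass,
                  self.baseline_pass):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.n < 0:
            raise ValueError("n must be >= 0")
        return self


@dataclass
class Candidate:
    """One synthetic recruit: profile plus scripted screening behavior."""

    email: str
    age: int
    sex: str
    smartphone: str
    height_in: float
    weight_lb: float
    bmi: float
    phase1_answers: dict[str, Any]
    phase2_answers: dict[str, Any]
    phase3_pass: bool
    baseline_pass: bool

    @property
    def factor_levels(self) -> dict[str, str]:
        return {"sex": self.sex, "bmi_category": bmi_category(self.bmi)}


def generate_cohort(params: CohortParams, seed: Optional[int] = None) -> list[Candidate]:
    """Draw a reproducible cohort with phase-1/2 response sets.

    Phase-1 eligibility *emerges* from the drawn demographics (no coin
    flip); later phases are scripted by Bernoulli draws at the
    configured pass rates, realized through the generated answers and
    diary behavior.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    out: list[Candidate] = []
    for i in range(params.n):
        age = int(np.clip(round(rng.normal(params.age_mean, params.age_sd)), 14, 90))
        bmi = float(np.clip(rng.normal(params.bmi_mean, params.bmi_sd), 15.0, 60.0))
        height_in = float(
            np.clip(rng.normal(params.height_in_mean, params.height_in_sd), 56, 80)
        )
        height_m = height_in * M_PER_IN
        weight_lb = round(bmi * height_m * height_m / KG_PER_LB, 1)
        # recompute BMI from the rounded weight so answers and derived
        # quantity agree exactly
        bmi = (weight_lb * KG_PER_LB) / (height_m * height_m)
        smartphone = "yes" if rng.random() < params.smartphone_rate else "no"
        sex = "female" if rng.random() < 0.5 else "male"
        email = f"candidate{i + 1:05d}@example.org"
        phase1: dict[str, Any] = {"email": email, "smartphone": smartphone}
        if smartphone == "yes":
            phase1.update(
                age=age, height_in=height_in, weight_lb=weight_lb, sex=sex
            )
        pass2 = rng.random() < params.phase2_pass
        if pass2:
            phase2 = {
                "hx_cardiac": 0,
                "hx_diabetes": int(rng.random() < 0.2),
                "hx_pregnancy": 0,
            }
        else:
            which = rng.random()
            phase2 = {
                "hx_cardiac": int(which < 0.7),
                "hx_diabetes": int(rng.random() < 0.3),
                "hx_pregnancy": int(which >= 0.7),
            }
        out.append(
            Candidate(
                email=email,
                age=age,
                sex=sex,
                smartphone=smartphone,
                height_in=height_in,
                weight_lb=weight_lb,
                bmi=bmi,
                phase1_answers=phase1,
                phase2_answers=phase2,
                phase3_pass=bool(rng.random() < params.phase3_pass),
                baseline_pass=bool(rng.random() < params.baseline_pass),
            )
        )
    return out


class StreamParams(BaseModel):
    """Observation-stream model for one participant's monitoring horizon."""

    days: int = 28
    start: date = date(2020, 3, 1)
    steps_mean: float = 7500.0
    steps_dispersion: float = 10.0
    hr_mean: float = 70.0
    hr_sd: float = 6.0
    sleep_mean: float = 420.0
    sleep_sd: float = 50.0
    food_entries_mean: float = 3.0
    weight_baseline_lb: float = 200.0
    weight_trend_lb_per_week: float = -0.25
    weight_noise_lb: float = 0.8
    #: per-metric daily logging probability is implied by the renewal
    #: process: mean adherent-run and missing-run lengths in days
    adherent_run_mean: float = 20.0
    missing_run_mean: float = 3.0
    #: probability a record syncs late, and the mean extra days if so
    delay_prob: float = 0.1
    delay_mean_days: float = 2.0
    seed: int = 0

    @model_validator(mode="after")
    def _valid(self) -> "StreamParams":
        if self.days < 0:
            raise ValueError("days must be >= 0")
        if self.adherent_run_mean < 1 or self.missing_run_mean < 1:
            raise ValueError("mean run lengths must be >= 1 day")
        if not 0 <= self.delay_prob <= 1:
            raise ValueError("delay_prob must be in [0, 1]")
        return self


def _adherence_mask(rng: np.random.Generator, days: int,
                    adherent_mean: float, missing_mean: float) -> np.ndarray:
    """Alternating renewal process of adherent/missing runs.

    Run lengths are geometric with the given means; ``adherent_mean``
    of ``inf`` (or a degenerate missing mean of exactly 1 with
    adherent_mean >= days) yields full adherence.
    """
    mask = np.zeros(days, dtype=bool)
    i = 0
    adherent = True
    while i < days:
        mean = adherent_mean if adherent else missing_mean
        run = int(rng.geometric(min(1.0, 1.0 / mean)))
        mask[i : i + run] = adherent
        i += run
        adherent = not adherent
    return mask


@dataclass
class GeneratedRecord:
    """An observation plus the date it becomes visible at the vendor."""

    record: ObservationRecord
    available_on: date


def generate_streams(
    study_id: str, params: StreamParams, seed: Optional[int] = None
) -> list[GeneratedRecord]:
    """Simulate one participant's daily self-monitoring streams.

    Reproducible for a given seed; missing runs fall exactly where the
    adherence draws put them, and the weight series follows
    ``baseline + trend·t + noise`` (computed in lb, stored in kg).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    days = [params.start + timedelta(days=k) for k in range(params.days)]
    masks = {
        m: _adherence_mask(rng, params.days, params.adherent_run_mean,
                           params.missing_run_mean)
        for m in ("tracker", "food", "weight")
    }
    out: list[GeneratedRecord] = []

    def delay(d: date) -> date:
        if params.delay_prob > 0 and rng.random() < params.delay_prob:
            return d + timedelta(days=int(rng.geometric(1.0 / max(1.0, params.delay_mean_days))))
        return d

    p_nb = params.steps_dispersion / (params.steps_dispersion + params.steps_mean)
    for k, day in enumerate(days):
        if masks["tracker"][k]:
            steps = float(rng.negative_binomial(params.steps_dispersion, p_nb))
            hr = float(np.clip(rng.normal(params.hr_mean, params.hr_sd), 35, 180))
            sleep = float(np.clip(rng.normal(params.sleep_mean, params.sleep_sd), 0, 960))
            avail = delay(day)
            for metric, value in (
                (Metric.STEPS, steps),
                (Metric.HEART_RATE, hr),
                (Metric.SLEEP_MINUTES, sleep),
            ):
                out.append(GeneratedRecord(
                    ObservationRecord(
                        study_id=study_id, metric=metric, timestamp=day,
                        value=value, source="wearable_vendor",
                    ),
                    available_on=avail,
                ))
        if masks["food"][k]:
            entries = float(max(1, rng.poisson(params.food_entries_mean)))
            out.append(GeneratedRecord(
                ObservationRecord(
                    study_id=study_id, metric=Metric.FOOD_ENTRY, timestamp=day,
                    value=entries, source="wearable_vendor",
                ),
                available_on=delay(day),
            ))
        if masks["weight"][k]:
            w_lb = (
                params.weight_baseline_lb
                + params.weight_trend_lb_per_week * (k / 7.0)
                + (rng.normal(0.0, params.weight_noise_lb)
                   if params.weight_noise_lb > 0 else 0.0)
            )
            out.append(GeneratedRecord(
                ObservationRecord(
                    study_id=study_id, metric=Metric.WEIGHT, timestamp=day,
                    value=lb_to_kg(max(60.0, w_lb)), source="scale_vendor",
                ),
                available_on=delay(day),
            ))
    return out


class MockDeviceServer:
    """In-process stand-in for the wearable/IoT vendor clouds.

    Answers ``(account, endpoint, day)`` queries from preloaded
    generated streams, enforces the per-account rolling-hour API quota
    by refusing excess calls with :class:`QuotaExceededError`, and holds
    back records whose upload delay has not yet elapsed (emulating
    devices that sync late over flaky connections).
    """

    def __init__(self, quota_per_hour: int = 100) -> None:
        self.quota_per_hour = quota_per_hour
        self._streams: dict[str, list[GeneratedRecord]] = {}
        self.budgets: dict[str, RateBudget] = {}
        self.calls = 0

    def load(self, account: str, records: list[GeneratedRecord]) -> None:
        self._streams.setdefault(account, []).extend(records)
        self.budgets.setdefault(
            account, RateBudget(account=account, limit_per_hour=self.quota_per_hour)
        )

    def fetch(
        self, account: str, endpoint: Endpoint, day: date, now: datetime
    ) -> list[ObservationRecord]:
        if account not in self._streams:
            raise KeyError(f"unknown account {account}")
        budget = self.budgets[account]
        budget.grant(now)  # raises QuotaExceededError when exhausted
        self.calls += 1
        metrics = set(ENDPOINT_METRICS[Endpoint(endpoint)])
        today = now.date()
        return [
            g.record.model_copy()
            for g in self._streams[account]
            if g.record.metric in metrics
            and g.record.timestamp == day
            and g.available_on <= today
        ]


def mock_device_server(
    streams: dict[str, list[GeneratedRecord]], quota: int = 100
) -> MockDeviceServer:
    """Build a loaded mock vendor server (connector endpoint)."""
    server = MockDeviceServer(quota_per_hour=quota)
    for account, records in streams.items():
        server.load(account, records)
    return server
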