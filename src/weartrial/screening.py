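"""Three-phase screening funnel.

Phases 1 and 2 are auto-screened from questionnaire answers against
declarative eligibility criteria (age, BMI window, smartphone use, ...);
phase 3 supports the coordinator's food-diary review, and eligible
participants advance automatically along the funnel.

A criterion either reads an item's answer directly or a derived quantity
(currently BMI from self-reported height and weight, converted to
kg/m²). Bounds are inclusive on both ends: a BMI window of 27–43 admits
exactly 27.0 and exactly 43.0, mirroring the ≥18 age rule.
"""

from __future__ import annotations

from datetime import date, datetime, timedelta
from enum import Enum
from typing import Any, Iterable, Literal, Optional

from pydantic import BaseModel, Field

from .core import Participant, Study, StudyPhase
from .units import KG_PER_LB, M_PER_CM, M_PER_IN


class DerivedSource(BaseModel):
    """A quantity computed from answers rather than read from one item."""

    kind: Literal["bmi"]
    weight_item: str
    height_item: str
    weight_unit: Literal["kg", "lb"] = "lb"
    height_unit: Literal["m", "cm", "in"] = "in"


class Predicate(BaseModel):
    """Range (inclusive) or set membership over the source value."""

    min: Optional[float] = None
    max: Optional[float] = None
    allowed: Optional[list[Any]] = None
    equals: Optional[Any] = None

    def holds(self, value: Any) -> bool:
        if self.min is not None and not value >= self.min:
            return False
        if self.max is not None and not value <= self.max:
            return False
        if self.allowed is not None and value not in self.allowed:
            return False
        if self.equals is not None and value != self.equals:
            return False
        return True


class EligibilityCriterion(BaseModel):
    name: str
    phase: StudyPhase = StudyPhase.PHASE1_SCREEN
    item: Optional[str] = None
    derived: Optional[DerivedSource] = None
    predicate: Predicate


class Outcome(str, Enum):
    ELIGIBLE = "eligible"
    INELIGIBLE = "ineligible"
    NEEDS_MANUAL_REVIEW = "needs_manual_review"


class ScreeningDecision(BaseModel):
    study_id: str
    phase: StudyPhase
    outcome: Outcome
    failed_criteria: list[str] = Field(default_factory=list)
    missing_inputs: list[str] = Field(default_factory=list)
    decided_at: Optional[datetime] = None
    decided_by: str = "auto"


class ScreeningError(Exception):
    pass


def bmi(weight_kg: float, height_m: float) -> float:
    """Body-mass index in kg/m²."""
    return weight_kg / (height_m * height_m)


def criterion_value(
    criterion: EligibilityCriterion, answers: dict[str, Any]
) -> Any:
    """Resolve the criterion's source value from a response's answers.

    Returns ``None`` when a needed answer is absent, which routes the
    decision to manual review instead of silently failing the candidate.
    """
    if criterion.derived is not None:
        d = criterion.derived
        w = answers.get(d.weight_item)
        h = answers.get(d.height_item)
        if w is None or h is None:
            return None
        weight_kg = float(w) * (KG_PER_LB if d.weight_unit == "lb" else 1.0)
        height_m = float(h) * {
            "m": 1.0, "cm": M_PER_CM, "in": M_PER_IN
        }[d.height_unit]
        return bmi(weight_kg, height_m)
    return answers.get(criterion.item or "")


def evaluate_eligibility(
    criteria: Iterable[EligibilityCriterion],
    answers: dict[str, Any],
    study_id: str = "",
    phase: StudyPhase = StudyPhase.PHASE1_SCREEN,
    decided_at: Optional[datetime] = None,
    decided_by: str = "auto",
) -> ScreeningDecision:
    """Auto-screen one candidate: eligible iff every criterion passes.

    Every failing criterion is listed; a criterion whose inputs are
    unanswered sends the decision to ``needs_manual_review`` naming the
    criterion. Deterministic in its inputs.
    """
    failed: list[str] = []
    missing: list[str] = []
    for crit in criteria:
        if crit.phase != phase:
            continue
        value = criterion_value(crit, answers)
        if value is None:
            missing.append(crit.name)
        elif not crit.predicate.holds(value):
            failed.append(crit.name)
    if failed:
        outcome = Outcome.INELIGIBLE
    elif missing:
        outcome = Outcome.NEEDS_MANUAL_REVIEW
    else:
        outcome = Outcome.ELIGIBLE
    return ScreeningDecision(
        study_id=study_id,
        phase=phase,
        outcome=outcome,
        failed_criteria=failed,
        missing_inputs=missing,
        decided_at=decided_at,
        decided_by=decided_by,
    )


def advance_phase(
    study: Study, decision: ScreeningDecision, timestamp: datetime
) -> Participant:
    """Apply a screening decision: eligible moves to the next funnel
    phase, ineligible is terminal. Phase-3 decisions require coordinator
    sign-off (``decided_by`` other than ``auto``)."""
    p = study.get(decision.study_id)
    if decision.phase != p.phase:
        raise ScreeningError(
            f"decision for phase {decision.phase.value} does not match "
            f"participant phase {p.phase.value}"
        )
    if decision.phase is StudyPhase.PHASE3_SCREEN and decision.decided_by == "auto":
        raise ScreeningError("phase-3 outcome requires coordinator sign-off")
    if decision.outcome is Outcome.ELIGIBLE:
        return study.mark_eligible(decision.study_id, timestamp)
    if decision.outcome is Outcome.INELIGIBLE:
        return study.mark_ineligible(
            decision.study_id, timestamp, decision.failed_criteria
        )
    raise ScreeningError("needs_manual_review decisions cannot advance a phase")


class DiarySummary(BaseModel):
    study_id: str = ""
    window_start: date
    window_days: int
    days_logged: int
    total_entries: int
    entries_per_day: float
    passed: bool


def review_food_diary(
    observations: Iterable,
    window_start: date,
    window_length_days: int = 5,
    min_days: int = 5,
    min_entries_per_day: Optional[float] = None,
) -> DiarySummary:
    """Summarize a food-diary window for the coordinator's phase-3 review.

    ``days_logged`` counts distinct calendar dates inside the half-open
    window with at least one food entry; the default task is a 5-day diary
    with all 5 days logged. ``observations`` are food-entry records with a
    ``timestamp`` calendar date; a record's ``value`` (if present) is the
    number of entries logged that day, else each record counts as one.
    """
    if window_length_days < 1:
        raise ScreeningError("empty food-diary window")
    window = {window_start + timedelta(days=k) for k in range(window_length_days)}
    dates: set[date] = set()
    total = 0
    sid = ""
    for obs in observations:
        d = obs.timestamp if isinstance(obs.timestamp, date) else obs.timestamp.date()
        n = int(getattr(obs, "value", 1) or 0)
        if d in window and n >= 1:
            dates.add(d)
            total += n
            sid = getattr(obs, "study_id", sid)
    days_logged = len(dates)
    per_day = total / window_length_days
    passed = days_logged >= min_days and (
        min_entries_per_day is None or per_day >= min_entries_per_day
    )
    return DiarySummary(
        study_id=sid,
        window_start=window_start,
        window_days=window_length_days,
        days_logged=days_logged,
        total_entries=total,
        entries_per_day=per_day,
        passed=passed,
    )
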