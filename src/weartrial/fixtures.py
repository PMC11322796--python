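"""Fixture study assets: screening questionnaires, eligibility criteria,
and prognostic factors for a two-arm weight-loss trial.

The evaluated trial's actual instruments are not public, so these are
deliberately small stand-in definitions that exercise every engine
feature (branching, derived BMI, scoring, flags) rather than a
reconstruction of any real survey.
"""

from __future__ import annotations

from .core import StudyPhase
from .questionnaire import (
    AnswerType,
    BranchOp,
    BranchRule,
    FlagRule,
    FlagSource,
    Item,
    QuestionnaireDefinition,
    ScoreExpr,
    ScoreRule,
    Validation,
)
from .screening import DerivedSource, EligibilityCriterion, Predicate

#: Treatment arms: self-monitoring alone vs. SM plus tailored feedback.
ARMS = ("sm_only", "sm_feedback")
FEEDBACK_ARM = "sm_feedback"

#: Prognostic factors balanced by minimization in the fixture study.
FACTORS: dict[str, list[str]] = {
    "sex": ["female", "male"],
    "bmi_category": ["bmi_27_35", "bmi_35_43"],
}


def phase1_questionnaire() -> QuestionnaireDefinition:
    """Phase-1 web screener: demographics, anthropometrics, smartphone use.

    A "no" on smartphone use branches straight to END — the remaining
    items are not presented, and auto-screening fails the candidate on
    the smartphone criterion alone.
    """
    return QuestionnaireDefinition(
        qid="phase1_screen",
        phase=StudyPhase.PHASE1_SCREEN,
        items=[
            Item(item_id="email", prompt="Contact email",
                 answer_type=AnswerType.TEXT, required=True),
            Item(item_id="smartphone", prompt="Do you use a smartphone?",
                 answer_type=AnswerType.CHOICE, required=True,
                 options=["yes", "no"]),
            Item(item_id="age", prompt="Age in years",
                 answer_type=AnswerType.INTEGER, required=True,
                 validation=Validation(min=0, max=120)),
            Item(item_id="height_in", prompt="Height (inches)",
                 answer_type=AnswerType.DECIMAL, required=True,
                 validation=Validation(min=36, max=96)),
            Item(item_id="weight_lb", prompt="Weight (pounds)",
                 answer_type=AnswerType.DECIMAL, required=True,
                 validation=Validation(min=60, max=700)),
            Item(item_id="sex", prompt="Sex",
                 answer_type=AnswerType.CHOICE, required=True,
                 options=["female", "male"]),
        ],
        branch_rules=[
            BranchRule(source="smartphone", op=BranchOp.EQ, value="no",
                       target="END"),
        ],
    )


def phase2_questionnaire() -> QuestionnaireDefinition:
    """Phase-2 screener: brief health-history items with a summed risk
    score and a review flag."""
    risk_items = ["hx_cardiac", "hx_diabetes", "hx_pregnancy"]
    return QuestionnaireDefinition(
        qid="phase2_screen",
        phase=StudyPhase.PHASE2_SCREEN,
        items=[
            Item(item_id=i, prompt=f"History: {i.split('_', 1)[1]} (1=yes)",
                 answer_type=AnswerType.INTEGER, required=True,
                 validation=Validation(min=0, max=1))
            for i in risk_items
        ],
        scoring=[
            ScoreRule(name="risk_score",
                      expr=ScoreExpr(op="sum", items=risk_items)),
        ],
        flags=[
            FlagRule(label="medical_review",
                     source=FlagSource(score="risk_score"),
                     op=BranchOp.GT, value=0),
        ],
    )


def default_criteria() -> list[EligibilityCriterion]:
    """Preset auto-screening criteria: adult, BMI 27–43 (inclusive,
    derived from self-reported height/weight), smartphone user, and a
    clear phase-2 health history."""
    return [
        EligibilityCriterion(
            name="age_18_plus",
            phase=StudyPhase.PHASE1_SCREEN,
            item="age",
            predicate=Predicate(min=18),
        ),
        EligibilityCriterion(
            name="bmi_27_43",
            phase=StudyPhase.PHASE1_SCREEN,
            derived=DerivedSource(
                kind="bmi",
                weight_item="weight_lb",
                height_item="height_in",
                weight_unit="lb",
                height_unit="in",
            ),
            predicate=Predicate(min=27.0, max=43.0),
        ),
        EligibilityCriterion(
            name="smartphone_user",
            phase=StudyPhase.PHASE1_SCREEN,
            item="smartphone",
            predicate=Predicate(equals="yes"),
        ),
        EligibilityCriterion(
            name="no_exclusionary_history",
            phase=StudyPhase.PHASE2_SCREEN,
            item="hx_cardiac",
            predicate=Predicate(equals=0),
        ),
        EligibilityCriterion(
            name="not_pregnant",
            phase=StudyPhase.PHASE2_SCREEN,
            item="hx_pregnancy",
            predicate=Predicate(equals=0),
        ),
    ]


def bmi_category(bmi: float) -> str:
    return "bmi_27_35" if bmi < 35 else "bmi_35_43"
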