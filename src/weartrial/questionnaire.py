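"""Adaptive questionnaires: definition, validation, branching, scoring.

A questionnaire is an ordered list of items plus declarative branch rules,
score rules, and flag rules — the shape a drag-and-drop survey builder
produces. Branch predicates are single-item conditions; when an answered
item matches a rule, presentation jumps to the rule's target (first
matching rule in declaration order wins), and the skipped items are
recorded as *not presented*, which is distinct from *missing* in exports
and excluded from scoring.

The traversal graph (document-order edges plus branch edges) must be
acyclic; :func:`validate_definition` checks this along with duplicate ids,
dangling targets, and scoring references.
"""

from __future__ import annotations

import csv
import hashlib
import io
import re
from datetime import date, datetime
from enum import Enum
from typing import Any, Literal, Optional, Union

import networkx as nx
from pydantic import BaseModel, Field

from .core import StudyPhase

#: Branch / flow sentinel: the end of the questionnaire.
END = "END"

#: Export sentinel for items the branch logic skipped.
NOT_PRESENTED = "NOT_PRESENTED"


class AnswerType(str, Enum):
    INTEGER = "integer"
    DECIMAL = "decimal"
    CHOICE = "choice"
    MULTI_CHOICE = "multi_choice"
    TEXT = "text"
    DATE = "date"


class Validation(BaseModel):
    min: Optional[float] = None
    max: Optional[float] = None
    pattern: Optional[str] = None


class Item(BaseModel):
    item_id: str
    prompt: str = ""
    answer_type: AnswerType = AnswerType.TEXT
    required: bool = False
    options: Optional[list[str]] = None
    validation: Optional[Validation] = None


class BranchOp(str, Enum):
    EQ = "=="
    NE = "!="
    LT = "<"
    LE = "<="
    GT = ">"
    GE = ">="
    IN = "in"


def _compare(op: BranchOp, left: Any, right: Any) -> bool:
    if op is BranchOp.EQ:
        return left == right
    if op is BranchOp.NE:
        return left != right
    if op is BranchOp.IN:
        return left in right
    if left is None:
        return False
    if op is BranchOp.LT:
        return left < right
    if op is BranchOp.LE:
        return left <= right
    if op is BranchOp.GT:
        return left > right
    if op is BranchOp.GE:
        return left >= right
    raise ValueError(op)


class BranchRule(BaseModel):
    """Single-item predicate redirecting flow to ``target`` (or END)."""

    source: str
    op: BranchOp
    value: Any
    target: str = END


class ScoreExpr(BaseModel):
    """Small arithmetic AST over item answers.

    ``op`` is one of ``sum``/``count`` (over ``items``), the binary chain
    ops ``add``/``sub``/``mul``/``div`` (over ``args``), an ``item``
    reference, or a ``const``. Not-presented items contribute nothing to
    sum/count and read as 0 in arithmetic.
    """

    op: Literal["sum", "count", "add", "sub", "mul", "div", "item", "const"]
    items: Optional[list[str]] = None
    args: Optional[list["ScoreExpr"]] = None
    item: Optional[str] = None
    const: Optional[float] = None

    def referenced_items(self) -> set[str]:
        refs: set[str] = set(self.items or [])
        if self.item:
            refs.add(self.item)
        for a in self.args or []:
            refs |= a.referenced_items()
        return refs


class ScoreRule(BaseModel):
    name: str
    expr: ScoreExpr


class FlagSource(BaseModel):
    score: Optional[str] = None
    item: Optional[str] = None


class FlagRule(BaseModel):
    label: str
    source: FlagSource
    op: BranchOp
    value: Any


class QuestionnaireDefinition(BaseModel):
    qid: str
    phase: StudyPhase = StudyPhase.PHASE1_SCREEN
    items: list[Item] = Field(default_factory=list)
    branch_rules: list[BranchRule] = Field(default_factory=list)
    scoring: list[ScoreRule] = Field(default_factory=list)
    flags: list[FlagRule] = Field(default_factory=list)

    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def item(self, item_id: str) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)


class ResponseSet(BaseModel):
    qid: str
    study_id: Optional[str] = None
    token: Optional[str] = None
    answers: dict[str, Any] = Field(default_factory=dict)
    submitted_at: Optional[datetime] = None


class QuestionnaireError(Exception):
    pass


# ---------------------------------------------------------------------- #
# definition validation


def validate_definition(defn: QuestionnaireDefinition) -> list[str]:
    """Return all structural errors in a definition (empty list = valid)."""
    errors: list[str] = []
    if not defn.items:
        errors.append("no items")
        return errors
    ids = defn.item_ids()
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            errors.append(f"duplicate item id: {i}")
        seen.add(i)
    for it in defn.items:
        if it.answer_type in (AnswerType.CHOICE, AnswerType.MULTI_CHOICE):
            if not it.options:
                errors.append(f"choice item {it.item_id} has no options")
    idset = set(ids)
    for rule in defn.branch_rules:
        if rule.source not in idset:
            errors.append(f"branch source does not exist: {rule.source}")
        if rule.target != END and rule.target not in idset:
            errors.append(f"branch target does not exist: {rule.target}")
    # traversal graph: document-order edges + branch edges; must be a DAG
    if not any(e.startswith("branch") or e.startswith("duplicate") for e in errors):
        g = nx.DiGraph()
        g.add_nodes_from(ids + [END])
        for a, b in zip(ids, ids[1:] + [END]):
            g.add_edge(a, b)
        for rule in defn.branch_rules:
            g.add_edge(rule.source, rule.target)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            errors.append(
                "branch cycle: " + " -> ".join(a for a, _ in cycle)
            )
    for srule in defn.scoring:
        for ref in srule.expr.referenced_items():
            if ref not in idset:
                errors.append(
                    f"score {srule.name} references missing item: {ref}"
                )
    score_names = {s.name for s in defn.scoring}
    for frule in defn.flags:
        if frule.source.item and frule.source.item not in idset:
            errors.append(f"flag {frule.label} references missing item")
        if frule.source.score and frule.source.score not in score_names:
            errors.append(f"flag {frule.label} references missing score")
    return errors


# ---------------------------------------------------------------------- #
# branching


def _branch_target(defn: QuestionnaireDefinition, item_id: str, answer: Any) -> Optional[str]:
    for rule in defn.branch_rules:
        if rule.source == item_id and _compare(rule.op, answer, rule.value):
            return rule.target
    return None


def walk(defn: QuestionnaireDefinition, answers: dict[str, Any]) -> tuple[list[str], Union[Item, str]]:
    """Walk the questionnaire under ``answers``.

    Returns ``(presented_ids, frontier)`` where frontier is the next
    :class:`Item` to present, or :data:`END`. Items jumped over by a
    branch are not in ``presented_ids``.
    """
    ids = defn.item_ids()
    index = {i: k for k, i in enumerate(ids)}
    presented: list[str] = []
    k = 0
    steps = 0
    while k < len(ids):
        steps += 1
        if steps > len(ids):
            raise QuestionnaireError(
                f"branch cycle encountered while walking {defn.qid}"
            )
        it = defn.items[k]
        presented.append(it.item_id)
        if it.item_id not in answers:
            return presented, it
        target = _branch_target(defn, it.item_id, answers[it.item_id])
        if target is None:
            k += 1
        elif target == END:
            return presented, END
        else:
            k = index[target]
    return presented, END


def next_item(defn: QuestionnaireDefinition, partial_answers: dict[str, Any]) -> Union[Item, str]:
    """Next item to present given the answers so far, or :data:`END`.

    Pure function of ``(defn, partial_answers)``: document order unless a
    matching branch rule redirects.
    """
    _, frontier = walk(defn, partial_answers)
    return frontier


def presented_items(defn: QuestionnaireDefinition, answers: dict[str, Any]) -> list[str]:
    """Item ids actually shown under the branch logic (the walk's trace);
    includes an unanswered frontier item, excludes everything skipped."""
    presented, _ = walk(defn, answers)
    return presented


# ---------------------------------------------------------------------- #
# answer validation


def _check_type(item: Item, value: Any) -> Optional[str]:
    t = item.answer_type
    if t is AnswerType.INTEGER:
        if isinstance(value, bool) or not isinstance(value, int):
            return f"item {item.item_id}: expected integer, got {value!r}"
    elif t is AnswerType.DECIMAL:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            return f"item {item.item_id}: expected decimal, got {value!r}"
    elif t is AnswerType.CHOICE:
        if value not in (item.options or []):
            return f"item {item.item_id}: {value!r} not among options"
    elif t is AnswerType.MULTI_CHOICE:
        if not isinstance(value, (list, tuple)) or any(
            v not in (item.options or []) for v in value
        ):
            return f"item {item.item_id}: invalid multi-choice {value!r}"
    elif t is AnswerType.TEXT:
        if not isinstance(value, str):
            return f"item {item.item_id}: expected text, got {value!r}"
    elif t is AnswerType.DATE:
        if isinstance(value, (date, datetime)):
            return None
        try:
            date.fromisoformat(str(value))
        except ValueError:
            return f"item {item.item_id}: invalid date {value!r}"
    return None


def _check_validation(item: Item, value: Any) -> Optional[str]:
    v = item.validation
    if v is None:
        return None
    if v.min is not None and isinstance(value, (int, float)) and value < v.min:
        return f"item {item.item_id}: {value} below minimum {v.min}"
    if v.max is not None and isinstance(value, (int, float)) and value > v.max:
        return f"item {item.item_id}: {value} above maximum {v.max}"
    if v.pattern is not None and isinstance(value, str):
        if re.fullmatch(v.pattern, value) is None:
            return f"item {item.item_id}: {value!r} does not match pattern"
    return None


def validate_answers(defn: QuestionnaireDefinition, answers: dict[str, Any]) -> list[str]:
    """Validate a (complete) response: presented required items answered,
    types and range/pattern constraints respected, no unknown items."""
    errors: list[str] = []
    idset = set(defn.item_ids())
    for item_id in answers:
        if item_id not in idset:
            errors.append(f"answer for unknown item: {item_id}")
    presented, frontier = walk(defn, answers)
    if isinstance(frontier, Item):
        if frontier.required:
            errors.append(f"required item not answered: {frontier.item_id}")
    for item_id in presented:
        if item_id not in answers:
            continue
        item = defn.item(item_id)
        err = _check_type(item, answers[item_id]) or _check_validation(
            item, answers[item_id]
        )
        if err:
            errors.append(err)
    return errors


# ---------------------------------------------------------------------- #
# scoring


def _numeric(defn: QuestionnaireDefinition, item_id: str, value: Any) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise QuestionnaireError(
            f"item {item_id}: non-numeric answer {value!r} in score expression"
        )
    return float(value)


def _eval_expr(
    expr: ScoreExpr,
    defn: QuestionnaireDefinition,
    answers: dict[str, Any],
    presented: set[str],
) -> float:
    if expr.op == "const":
        return float(expr.const or 0.0)
    if expr.op == "item":
        iid = expr.item or ""
        if iid in presented and iid in answers:
            return _numeric(defn, iid, answers[iid])
        return 0.0
    if expr.op == "sum":
        return sum(
            _numeric(defn, i, answers[i])
            for i in (expr.items or [])
            if i in presented and i in answers
        )
    if expr.op == "count":
        return float(
            sum(1 for i in (expr.items or []) if i in presented and i in answers)
        )
    vals = [_eval_expr(a, defn, answers, presented) for a in (expr.args or [])]
    if not vals:
        return 0.0
    acc = vals[0]
    for v in vals[1:]:
        if expr.op == "add":
            acc += v
        elif expr.op == "sub":
            acc -= v
        elif expr.op == "mul":
            acc *= v
        elif expr.op == "div":
            if v == 0:
                raise QuestionnaireError("division by zero in score expression")
            acc /= v
    return acc


def score_and_flag(
    defn: QuestionnaireDefinition, answers: dict[str, Any]
) -> tuple[dict[str, float], list[str]]:
    """Compute named scores over presented items, then evaluate flags.

    Scores see only items actually presented under the branch logic;
    flags are evaluated after all scores, against scores or raw answers.
    """
    errors = validate_answers(defn, answers)
    if errors:
        raise QuestionnaireError("; ".join(errors))
    presented = set(presented_items(defn, answers))
    scores = {
        rule.name: _eval_expr(rule.expr, defn, answers, presented)
        for rule in defn.scoring
    }
    flags: list[str] = []
    for frule in defn.flags:
        if frule.source.score is not None:
            left: Any = scores.get(frule.source.score)
        else:
            iid = frule.source.item or ""
            left = answers.get(iid) if iid in presented else None
        if left is not None and _compare(frule.op, left, frule.value):
            flags.append(frule.label)
    return scores, flags


# ---------------------------------------------------------------------- #
# link issuance and response collection


class QuestionnaireRegistry:
    """Published definitions, issued links, and collected responses.

    Tokens are opaque, deterministic digests of (qid, sequence, salt):
    reproducible for a given issuance order yet meaningless outside the
    registry. A private token resolves to exactly one participant; a
    public token binds to none. Single-use tokens refuse a second
    submission.
    """

    def __init__(self, salt: str = "weartrial") -> None:
        self.salt = salt
        self.definitions: dict[str, QuestionnaireDefinition] = {}
        self._tokens: dict[str, dict[str, Any]] = {}
        self.responses: list[ResponseSet] = []
        self._seq = 0

    def publish(self, defn: QuestionnaireDefinition) -> None:
        errors = validate_definition(defn)
        if errors:
            raise QuestionnaireError(
                f"definition {defn.qid} invalid: " + "; ".join(errors)
            )
        self.definitions[defn.qid] = defn

    def issue_link(
        self,
        qid: str,
        study_id: Optional[str] = None,
        single_use: bool = False,
    ) -> str:
        if qid not in self.definitions:
            raise QuestionnaireError(f"questionnaire {qid} not published")
        self._seq += 1
        token = hashlib.sha256(
            f"{self.salt}:{qid}:{self._seq}".encode()
        ).hexdigest()[:20]
        self._tokens[token] = {
            "qid": qid,
            "study_id": study_id,
            "single_use": single_use,
            "used": 0,
        }
        return token

    def submit(
        self, token: str, answers: dict[str, Any], submitted_at: datetime
    ) -> ResponseSet:
        meta = self._tokens.get(token)
        if meta is None:
            raise QuestionnaireError("unknown questionnaire token")
        if meta["single_use"] and meta["used"]:
            raise QuestionnaireError("token already used")
        defn = self.definitions[meta["qid"]]
        errors = validate_answers(defn, answers)
        if errors:
            raise QuestionnaireError("; ".join(errors))
        meta["used"] += 1
        rs = ResponseSet(
            qid=meta["qid"],
            study_id=meta["study_id"],
            token=token,
            answers=dict(answers),
            submitted_at=submitted_at,
        )
        self.responses.append(rs)
        return rs

    def responses_for(self, qid: str) -> list[ResponseSet]:
        return [r for r in self.responses if r.qid == qid]

    def export_csv(self, qid: str) -> str:
        """One row per response, one column per item; skipped items carry
        the :data:`NOT_PRESENTED` sentinel, unanswered presented items are
        empty."""
        defn = self.definitions[qid]
        ids = defn.item_ids()
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["qid", "study_id", "submitted_at"] + ids)
        for rs in self.responses_for(qid):
            presented = set(presented_items(defn, rs.answers))
            row = [rs.qid, rs.study_id or "", rs.submitted_at.isoformat() if rs.submitted_at else ""]
            for i in ids:
                if i in rs.answers:
                    row.append(rs.answers[i])
                elif i in presented:
                    row.append("")
                else:
                    row.append(NOT_PRESENTED)
            writer.writerow(row)
        return buf.getvalue()
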