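"""Definition validation, branching vs a graph-walk oracle, scoring,
links, and serialization round trips."""

import json
from datetime import datetime

import pytest
from hypothesis import given, settings, strategies as st

from weartrial.questionnaire import (
    END,
    NOT_PRESENTED,
    AnswerType,
    BranchOp,
    BranchRule,
    FlagRule,
    FlagSource,
    Item,
    QuestionnaireDefinition,
    QuestionnaireError,
    QuestionnaireRegistry,
    ScoreExpr,
    ScoreRule,
    next_item,
    presented_items,
    score_and_flag,
    validate_definition,
)


def _int_items(n):
    return [
        Item(item_id=f"q{k}", answer_type=AnswerType.INTEGER) for k in range(n)
    ]


def linear_def(n=4, **kw):
    return QuestionnaireDefinition(qid="lin", items=_int_items(n), **kw)


# ---------------------------------------------------------------------- #
# validate_definition


class TestValidateDefinition:
    def test_empty_definition_reports_no_items(self):
        assert validate_definition(QuestionnaireDefinition(qid="e")) == ["no items"]

    @pytest.mark.parametrize(
        "mutation, fragment",
        [
            (dict(items=_int_items(2) + [Item(item_id="q0")]), "duplicate item id"),
            (dict(items=_int_items(2),
                  branch_rules=[BranchRule(source="q0", op=BranchOp.EQ,
                                           value=1, target="nowhere")]),
             "branch target"),
            (dict(items=_int_items(2),
                  branch_rules=[BranchRule(source="ghost", op=BranchOp.EQ,
                                           value=1)]),
             "branch source"),
            (dict(items=_int_items(2),
                  scoring=[ScoreRule(name="s",
                                     expr=ScoreExpr(op="sum", items=["zz"]))]),
             "missing item"),
            (dict(items=_int_items(2),
                  flags=[FlagRule(label="f", source=FlagSource(score="nope"),
                                  op=BranchOp.GT, value=1)]),
             "missing score"),
        ],
    )
    def test_structural_errors_detected(self, mutation, fragment):
        defn = QuestionnaireDefinition(qid="bad", **mutation)
        assert any(fragment in e for e in validate_definition(defn))

    def test_backward_branch_cycle_detected(self):
        defn = linear_def(
            3,
            branch_rules=[BranchRule(source="q2", op=BranchOp.EQ, value=1,
                                     target="q0")],
        )
        assert any("cycle" in e for e in validate_definition(defn))

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_forward_branching_definitions_are_always_valid(self, data):
        # generator constrained to forward branches (a DAG by construction);
        # the validator must accept every one
        n = data.draw(st.integers(2, 8))
        items = _int_items(n)
        rules = []
        for _ in range(data.draw(st.integers(0, 5))):
            src = data.draw(st.integers(0, n - 2))
            tgt = data.draw(st.integers(src + 1, n - 1) | st.just(END))
            rules.append(
                BranchRule(source=f"q{src}", op=BranchOp.GE,
                           value=data.draw(st.integers(0, 5)),
                           target=tgt if tgt == END else f"q{tgt}")
            )
        defn = QuestionnaireDefinition(qid="gen", items=items, branch_rules=rules)
        assert validate_definition(defn) == []


# ---------------------------------------------------------------------- #
# next_item / branching


def oracle_walk(defn, answers):
    """Independent traversal oracle: explicit adjacency over item ids."""
    ids = [it.item_id for it in defn.items]
    pos = {i: k for k, i in enumerate(ids)}
    seq, cur = [], 0
    while cur < len(ids):
        iid = ids[cur]
        seq.append(iid)
        if iid not in answers:
            return seq, iid
        nxt = None
        for r in defn.branch_rules:
            if r.source != iid:
                continue
            a = answers[iid]
            ok = {
                BranchOp.EQ: lambda: a == r.value,
                BranchOp.NE: lambda: a != r.value,
                BranchOp.LT: lambda: a < r.value,
                BranchOp.LE: lambda: a <= r.value,
                BranchOp.GT: lambda: a > r.value,
                BranchOp.GE: lambda: a >= r.value,
                BranchOp.IN: lambda: a in r.value,
            }[r.op]()
            if ok:
                nxt = r.target
                break
        if nxt is None:
            cur += 1
        elif nxt == END:
            return seq, END
        else:
            cur = pos[nxt]
    return seq, END


class TestNextItem:
    def test_document_order_without_branches(self):
        defn = linear_def(3)
        assert next_item(defn, {}).item_id == "q0"
        assert next_item(defn, {"q0": 1}).item_id == "q1"
        assert next_item(defn, {"q0": 1, "q1": 2, "q2": 3}) == END

    def test_branch_to_end_skips_downstream_items(self):
        defn = linear_def(
            4,
            branch_rules=[BranchRule(source="q0", op=BranchOp.EQ, value=9,
                                     target=END)],
        )
        assert next_item(defn, {"q0": 9}) == END
        assert presented_items(defn, {"q0": 9}) == ["q0"]

    def test_first_matching_rule_wins(self):
        defn = linear_def(
            4,
            branch_rules=[
                BranchRule(source="q0", op=BranchOp.GE, value=1, target="q3"),
                BranchRule(source="q0", op=BranchOp.GE, value=1, target="q2"),
            ],
        )
        assert next_item(defn, {"q0": 5}).item_id == "q3"

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_random_paths_match_graph_walk_oracle(self, data):
        n = data.draw(st.integers(2, 7))
        items = _int_items(n)
        rules = []
        for _ in range(data.draw(st.integers(0, 4))):
            src = data.draw(st.integers(0, n - 2))
            tgt = data.draw(st.sampled_from(
                [f"q{j}" for j in range(src + 1, n)] + [END]))
            rules.append(BranchRule(
                source=f"q{src}",
                op=data.draw(st.sampled_from(list(BranchOp)[:6])),
                value=data.draw(st.integers(0, 3)),
                target=tgt,
            ))
        defn = QuestionnaireDefinition(qid="g", items=items, branch_rules=rules)
        answers = {
            f"q{k}": data.draw(st.integers(0, 3))
            for k in range(n) if data.draw(st.booleans())
        }
        expect_seq, expect_front = oracle_walk(defn, answers)
        got = next_item(defn, answers)
        got_front = got if got == END else got.item_id
        assert got_front == expect_front
        assert presented_items(defn, answers) == expect_seq


# ---------------------------------------------------------------------- #
# scoring and flags


class TestScoring:
    def test_all_zero_sum_is_zero(self):
        defn = linear_def(
            3,
            scoring=[ScoreRule(name="total",
                               expr=ScoreExpr(op="sum",
                                              items=["q0", "q1", "q2"]))],
        )
        scores, flags = score_and_flag(defn, {"q0": 0, "q1": 0, "q2": 0})
        assert scores == {"total": 0}
        assert flags == []

    def test_flag_triggers_after_scores(self):
        defn = linear_def(
            2,
            scoring=[ScoreRule(name="total",
                               expr=ScoreExpr(op="sum", items=["q0", "q1"]))],
            flags=[FlagRule(label="high", source=FlagSource(score="total"),
                            op=BranchOp.GT, value=10)],
        )
        _, flags = score_and_flag(defn, {"q0": 6, "q1": 5})
        assert flags == ["high"]
        _, flags = score_and_flag(defn, {"q0": 5, "q1": 5})
        assert flags == []

    def test_not_presented_items_are_excluded_from_scores(self):
        defn = linear_def(
            3,
            branch_rules=[BranchRule(source="q0", op=BranchOp.EQ, value=1,
                                     target="q2")],
            scoring=[ScoreRule(name="total",
                               expr=ScoreExpr(op="sum",
                                              items=["q0", "q1", "q2"]))],
        )
        scores, _ = score_and_flag(defn, {"q0": 1, "q2": 4})
        assert scores["total"] == 5  # q1 skipped by the branch

    def test_type_mismatch_names_the_item(self):
        defn = QuestionnaireDefinition(
            qid="t",
            items=[Item(item_id="q0", answer_type=AnswerType.INTEGER)],
            scoring=[ScoreRule(name="s", expr=ScoreExpr(op="sum", items=["q0"]))],
        )
        with pytest.raises(QuestionnaireError, match="q0"):
            score_and_flag(defn, {"q0": "oops"})

    @given(st.lists(st.integers(0, 9), min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_arithmetic_matches_direct_recomputation(self, vals):
        defn = linear_def(
            3,
            scoring=[
                ScoreRule(name="combo", expr=ScoreExpr(
                    op="add",
                    args=[
                        ScoreExpr(op="mul", args=[
                            ScoreExpr(op="item", item="q0"),
                            ScoreExpr(op="const", const=2.0)]),
                        ScoreExpr(op="sum", items=["q1", "q2"]),
                    ],
                )),
            ],
        )
        answers = {f"q{k}": v for k, v in enumerate(vals)}
        scores, _ = score_and_flag(defn, answers)
        assert scores["combo"] == vals[0] * 2.0 + vals[1] + vals[2]

    def test_scoring_invariant_to_answer_storage_order(self):
        defn = linear_def(
            3,
            scoring=[ScoreRule(name="t",
                               expr=ScoreExpr(op="sum",
                                              items=["q0", "q1", "q2"]))],
        )
        a = {"q0": 1, "q1": 2, "q2": 3}
        b = {"q2": 3, "q0": 1, "q1": 2}
        assert score_and_flag(defn, a) == score_and_flag(defn, b)


# ---------------------------------------------------------------------- #
# links, submission, export, round trip


class TestLinksAndCollection:
    def test_public_token_yields_unbound_response(self):
        reg = QuestionnaireRegistry()
        reg.publish(linear_def(1))
        token = reg.issue_link("lin")
        rs = reg.submit(token, {"q0": 1}, datetime(2020, 1, 1))
        assert rs.study_id is None
        assert rs.submitted_at is not None

    def test_private_token_binds_to_its_participant(self):
        reg = QuestionnaireRegistry()
        reg.publish(linear_def(1))
        token = reg.issue_link("lin", study_id="P007")
        rs = reg.submit(token, {"q0": 2}, datetime(2020, 1, 1))
        assert rs.study_id == "P007"

    def test_single_use_token_refuses_second_submission(self):
        reg = QuestionnaireRegistry()
        reg.publish(linear_def(1))
        token = reg.issue_link("lin", study_id="P001", single_use=True)
        reg.submit(token, {"q0": 1}, datetime(2020, 1, 1))
        with pytest.raises(QuestionnaireError):
            reg.submit(token, {"q0": 1}, datetime(2020, 1, 2))

    def test_all_submissions_are_retrievable(self):
        # the trial collected 4131 questionnaire answer sets in total
        reg = QuestionnaireRegistry()
        reg.publish(linear_def(1))
        for i in range(4131):
            reg.submit(reg.issue_link("lin"), {"q0": i % 7},
                       datetime(2020, 1, 1))
        assert len(reg.responses_for("lin")) == 4131

    def test_definition_json_round_trip_is_identity(self, q1):
        blob = q1.model_dump_json()
        back = QuestionnaireDefinition.model_validate_json(blob)
        assert back == q1
        assert json.loads(blob)["qid"] == q1.qid

    def test_export_distinguishes_not_presented_from_missing(self):
        defn = linear_def(
            3,
            branch_rules=[BranchRule(source="q0", op=BranchOp.EQ, value=1,
                                     target=END)],
        )
        reg = QuestionnaireRegistry()
        reg.publish(defn)
        reg.submit(reg.issue_link("lin"), {"q0": 1}, datetime(2020, 1, 1))
        csv_text = reg.export_csv("lin")
        row = csv_text.strip().splitlines()[1]
        assert row.endswith(f"1,{NOT_PRESENTED},{NOT_PRESENTED}")
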