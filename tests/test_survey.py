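"""Questionnaire composition, sociometric expansion, roster edits, and
pseudonymization."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sociosurvey.instruments import ResponseOption, ScoringRule
from sociosurvey.responses import ResponseSet, RespondentResponse
from sociosurvey.survey import (
    DEFAULT_TIE_SCALE,
    KNOWN_TO_BEST_FRIEND_SCALE,
    Person,
    Question,
    QuestionGroup,
    Roster,
    RosterEdit,
    SchemaError,
    SociometricTemplate,
    TieScale,
    anonymize,
    apply_roster_edit,
    compose_questionnaire,
    evaluate_group_score,
    expand_sociometric,
    generated_item_id,
)

from conftest import make_roster


def _question(qid: str, values=(0, 1)) -> Question:
    return Question(
        id=qid, text=qid,
        options=tuple(ResponseOption(code=str(v), label=str(v), value=v) for v in values),
    )


class TestComposition:
    def test_instrument_plus_question(self, audit):
        q = compose_questionnaire([audit, _question("extra")], metadata={"id": "q"})
        assert len(q.static_item_ids()) == 11

    def test_empty_questionnaire_is_valid(self, caplog):
        q = compose_questionnaire([], metadata={"id": "empty"})
        assert q.blocks == ()

    def test_id_collision_rejected(self):
        with pytest.raises(SchemaError, match="collision"):
            compose_questionnaire([_question("q1"), _question("q1")])

    def test_template_without_roster_rejected(self, friend_template):
        with pytest.raises(SchemaError, match="unknown roster"):
            compose_questionnaire([friend_template], rosters={})


class TestTieScales:
    def test_default_scale_levels(self):
        assert [l[1] for l in DEFAULT_TIE_SCALE.levels] == ["acquaintance", "partner", "friend"]
        assert DEFAULT_TIE_SCALE.weights == (1.0, 2.0, 3.0)

    def test_alternative_scale_spans_known_to_best_friend(self):
        labels = [l[1] for l in KNOWN_TO_BEST_FRIEND_SCALE.levels]
        assert labels[0].startswith("I know") and "best friend" in labels[-1]

    def test_non_increasing_weights_rejected(self):
        with pytest.raises(SchemaError, match="strictly increasing"):
            TieScale(levels=(("1", "a", 2.0), ("2", "b", 1.0)))

    def test_options_include_absent_level(self):
        opts = DEFAULT_TIE_SCALE.options()
        assert opts[0].value == 0.0 and len(opts) == 4


class TestExpansion:
    def test_one_mode_excludes_ego(self, friend_template):
        roster = make_roster(5)
        items = expand_sociometric(friend_template, roster, roster.members[0])
        assert len(items) == 4
        assert generated_item_id("friend", "p1") not in [i.id for i in items]

    def test_two_mode_keeps_all_entities(self):
        venues = Roster(id="venues", members=tuple(
            Person(id=f"v{i}", display_name=f"Venue {i}") for i in range(3)
        ))
        template = SociometricTemplate(
            id="drink", prompt="How often do you drink at {alter}?",
            relation_label="venue", mode="two_mode", roster_ref="venues",
        )
        ego = Person(id="p1", display_name="Someone")
        assert len(expand_sociometric(template, venues, ego)) == 3

    def test_ids_enumerate_roster_minus_ego(self, friend_template):
        roster = make_roster(25)
        ego = roster.members[3]
        items = expand_sociometric(friend_template, roster, ego)
        expected = {generated_item_id("friend", p.id) for p in roster.members if p.id != ego.id}
        assert {i.id for i in items} == expected and len(items) == 24

    def test_empty_roster_gives_empty_list(self, friend_template):
        empty = Roster(id="class", members=())
        ego = Person(id="x", display_name="X")
        assert expand_sociometric(friend_template, empty, ego) == []

    def test_expansion_idempotent(self, friend_template):
        roster = make_roster(8)
        ego = roster.members[0]
        a = expand_sociometric(friend_template, roster, ego)
        b = expand_sociometric(friend_template, roster, ego)
        assert a == b

    @settings(deadline=None, max_examples=20)
    @given(n=st.integers(min_value=1, max_value=40))
    def test_generated_item_counts(self, n):
        template = SociometricTemplate(
            id="friend", prompt="{alter}?", relation_label="friendship",
            mode="one_mode", roster_ref="class",
        )
        roster = make_roster(n)
        ego = roster.members[0]
        assert len(expand_sociometric(template, roster, ego)) == n - 1
        two_mode = SociometricTemplate(
            id="t2", prompt="{alter}?", relation_label="x", mode="two_mode", roster_ref="class",
        )
        assert len(expand_sociometric(two_mode, roster, ego)) == n


class TestRosterEdits:
    def test_add_grows_every_ego_block(self, questionnaire10, roster10):
        newcomer = Person(id="p11", display_name="Person 11")
        before = len(expand_sociometric(questionnaire10.template("friend"), roster10,
                                        roster10.members[0]))
        updated, report = apply_roster_edit(
            questionnaire10, RosterEdit(kind="add", roster_id="class", person=newcomer)
        )
        after = len(expand_sociometric(updated.template("friend"), updated.roster("class"),
                                       roster10.members[0]))
        assert (before, after) == (9, 10)
        assert report.created == (generated_item_id("friend", "p11"),)
        assert report.deleted == () and report.orphaned == ()

    def test_rename_relabels_without_changing_ids(self, questionnaire10, roster10):
        updated, report = apply_roster_edit(
            questionnaire10,
            RosterEdit(kind="rename", roster_id="class", person=roster10.members[2],
                       new_name="Renamed"),
        )
        assert report.created == () and report.deleted == ()
        assert report.renamed == (generated_item_id("friend", "p3"),)
        items = expand_sociometric(updated.template("friend"), updated.roster("class"),
                                   roster10.members[0])
        renamed = [i for i in items if i.id == generated_item_id("friend", "p3")]
        assert "Renamed" in renamed[0].text

    def test_remove_flags_orphaned_answers(self, questionnaire10, roster10):
        victim = "p5"
        # three stored answers name the removed alter
        rs = ResponseSet(
            questionnaire_id="study", wave="wave1",
            responses=tuple(
                RespondentResponse(person_id=p, wave="wave1",
                                   answers={generated_item_id("friend", victim): "3"})
                for p in ("p1", "p2", "p3")
            ),
        )
        _, report = apply_roster_edit(
            questionnaire10,
            RosterEdit(kind="remove", roster_id="class", person=roster10.member(victim)),
            response_set=rs,
        )
        assert len(report.orphaned) == 3
        assert all(item == generated_item_id("friend", victim) for _, item in report.orphaned)

    def test_remove_unknown_person_rejected(self, questionnaire10):
        ghost = Person(id="nobody", display_name="Nobody")
        with pytest.raises(SchemaError, match="not in roster"):
            apply_roster_edit(questionnaire10,
                              RosterEdit(kind="remove", roster_id="class", person=ghost))

    def test_add_then_remove_restores_item_set(self, questionnaire10, roster10):
        ego = roster10.members[0]
        template = questionnaire10.template("friend")
        original = [i.id for i in expand_sociometric(template, roster10, ego)]
        extra = Person(id="p99", display_name="Extra")
        step1, _ = apply_roster_edit(questionnaire10,
                                     RosterEdit(kind="add", roster_id="class", person=extra))
        step2, _ = apply_roster_edit(step1,
                                     RosterEdit(kind="remove", roster_id="class", person=extra))
        restored = [i.id for i in expand_sociometric(step2.template("friend"),
                                                     step2.roster("class"), ego)]
        assert restored == original


class TestAnonymization:
    def test_deterministic_for_fixed_salt(self):
        a, _ = anonymize(["Alice Garcia"], salt="s3cret")
        b, _ = anonymize(["Alice Garcia"], salt="s3cret")
        assert a == b

    def test_different_salts_differ(self):
        a, _ = anonymize(["Alice Garcia"], salt="salt-one")
        b, _ = anonymize(["Alice Garcia"], salt="salt-two")
        assert a != b

    def test_distinct_at_study_scale(self):
        names = [f"Student {i:03d}" for i in range(214)]
        pseudonyms, mapping = anonymize(names, salt="study-salt")
        assert len(set(pseudonyms)) == 214
        assert set(mapping) == set(names)

    def test_empty_salt_rejected(self):
        with pytest.raises(SchemaError, match="salt"):
            anonymize(["x"], salt="")


class TestGroupScores:
    def test_sum_rule(self):
        group = QuestionGroup(
            id="g", questions=(_question("q1", (1, 2, 3)), _question("q2", (1, 2, 3)),
                               _question("q3", (1, 2, 3))),
        )
        assert evaluate_group_score(group, {"q1": "1", "q2": "2", "q3": "3"}) == 6

    def test_mean_rule(self):
        group = QuestionGroup(
            id="g", questions=(_question("q1", (2, 4)), _question("q2", (2, 4))),
            scoring=ScoringRule("mean(q1, q2)"),
        )
        assert evaluate_group_score(group, {"q1": "2", "q2": "4"}) == 3

    def test_formula_with_multiplier(self):
        group = QuestionGroup(
            id="g", questions=(_question("q1", (1, 2)), _question("q2", (1, 2))),
            scoring=ScoringRule("sum(q1, q2) * 2"),
        )
        # independent evaluation: (1 + 2) * 2
        assert evaluate_group_score(group, {"q1": "1", "q2": "2"}) == (1 + 2) * 2

    def test_scoring_must_reference_member_questions(self):
        with pytest.raises(SchemaError, match="unknown question"):
            QuestionGroup(id="g", questions=(_question("q1"),),
                          scoring=ScoringRule("q1 + q7"))
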