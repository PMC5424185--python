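"""Questionnaire composition: custom questions, scored groups, rosters, and
roster-expanded sociometric questions.

A sociometric question (name generator) asks the respondent (the *ego*) to
rate their relationship with each listed other (the *alters*).  Instead of
authoring one question per alter by hand, a :class:`SociometricTemplate`
holds the prompt and the tie-strength scale, and is expanded against a
:class:`Roster`; editing the roster regenerates the expanded questions and
reports exactly what changed, flagging stored answers that now reference a
removed alter instead of dropping them.
"""

from __future__ import annotations

import hashlib
import hmac
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

from . import _expr
from .instruments import Instrument, Item, ResponseOption, ScoringRule

__all__ = [
    "ChangeReport",
    "Person",
    "Question",
    "QuestionGroup",
    "Questionnaire",
    "Roster",
    "RosterEdit",
    "SchemaError",
    "SociometricTemplate",
    "TieScale",
    "DEFAULT_TIE_SCALE",
    "KNOWN_TO_BEST_FRIEND_SCALE",
    "anonymize",
    "apply_roster_edit",
    "compose_questionnaire",
    "evaluate_group_score",
    "expand_sociometric",
    "generated_item_id",
    "parse_generated_item_id",
]

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Invalid questionnaire/roster structure or reference."""


@dataclass(frozen=True)
class Person:
    id: str
    display_name: str
    attributes: Mapping[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class Roster:
    id: str
    members: tuple[Person, ...]

    def __post_init__(self):
        ids = [p.id for p in self.members]
        if len(set(ids)) != len(ids):
            raise SchemaError(f"roster {self.id!r} has duplicate person ids")

    def member(self, person_id: str) -> Person:
        for p in self.members:
            if p.id == person_id:
                return p
        raise SchemaError(f"person {person_id!r} not in roster {self.id!r}")

    def has(self, person_id: str) -> bool:
        return any(p.id == person_id for p in self.members)


@dataclass(frozen=True)
class Question:
    id: str
    text: str
    options: tuple[ResponseOption, ...]
    anonymize: bool = False

    def __post_init__(self):
        if len(self.options) < 2:
            raise SchemaError(f"question {self.id!r} needs at least 2 options")
        codes = [o.code for o in self.options]
        if len(set(codes)) != len(codes):
            raise SchemaError(f"question {self.id!r} has duplicate option codes")

    def value_of(self, code: str) -> float:
        for o in self.options:
            if o.code == code:
                return o.value
        raise SchemaError(f"unknown option code {code!r} for question {self.id!r}")


@dataclass(frozen=True)
class QuestionGroup:
    id: str
    questions: tuple[Question, ...]
    scoring: ScoringRule = field(default_factory=ScoringRule)

    def __post_init__(self):
        qids = [q.id for q in self.questions]
        if len(set(qids)) != len(qids):
            raise SchemaError(f"question group {self.id!r} has duplicate question ids")
        bound = self.scoring.bound(tuple(qids))
        for ref in _expr.referenced_ids(bound):
            if ref not in qids:
                raise SchemaError(
                    f"group {self.id!r} scoring references unknown question {ref!r}"
                )

    @property
    def question_ids(self) -> tuple[str, ...]:
        return tuple(q.id for q in self.questions)


@dataclass(frozen=True)
class TieScale:
    """Ordered tie-strength levels, weakest to strongest.

    A generated sociometric item always offers an additional implicit
    "no relation" option (weight 0); an unanswered or zero-weight response
    records no tie.
    """

    levels: tuple[tuple[str, str, float], ...]  # (code, label, weight)
    absent_code: str = "0"
    absent_label: str = "no relation"

    def __post_init__(self):
        if len(self.levels) < 2:
            raise SchemaError("a tie scale needs at least 2 levels")
        weights = [w for _, _, w in self.levels]
        if any(b <= a for a, b in zip(weights, weights[1:])):
            raise SchemaError("tie scale weights must be strictly increasing")
        if weights[0] <= 0:
            raise SchemaError("tie scale weights must be positive (0 is the absent level)")
        codes = [c for c, _, _ in self.levels] + [self.absent_code]
        if len(set(codes)) != len(codes):
            raise SchemaError("tie scale codes must be unique (including the absent code)")

    @property
    def weights(self) -> tuple[float, ...]:
        return tuple(w for _, _, w in self.levels)

    @property
    def max_weight(self) -> float:
        return self.levels[-1][2]

    def weight_of(self, code: str) -> float:
        if code == self.absent_code:
            return 0.0
        for c, _, w in self.levels:
            if c == code:
                return w
        raise SchemaError(f"unknown tie scale code {code!r}")

    def options(self) -> tuple[ResponseOption, ...]:
        absent = ResponseOption(code=self.absent_code, label=self.absent_label, value=0.0)
        return (absent,) + tuple(
            ResponseOption(code=c, label=l, value=w) for c, l, w in self.levels
        )


DEFAULT_TIE_SCALE = TieScale(
    levels=(("1", "acquaintance", 1.0), ("2", "partner", 2.0), ("3", "friend", 3.0))
)

KNOWN_TO_BEST_FRIEND_SCALE = TieScale(
    levels=(
        ("1", "I know him/her", 1.0),
        ("2", "we talk sometimes", 2.0),
        ("3", "we are friends", 3.0),
        ("4", "we are close friends", 4.0),
        ("5", "he/she is my best friend", 5.0),
    )
)


@dataclass(frozen=True)
class SociometricTemplate:
    id: str
    prompt: str  # wording with an {alter} placeholder
    relation_label: str
    mode: Literal["one_mode", "two_mode"]
    roster_ref: str
    scale: TieScale = DEFAULT_TIE_SCALE
    directed: bool = True

    def __post_init__(self):
        if self.mode not in ("one_mode", "two_mode"):
            raise SchemaError(f"template {self.id!r}: mode must be one_mode or two_mode")
        if "{alter}" not in self.prompt:
            raise SchemaError(f"template {self.id!r}: prompt must contain an {{alter}} placeholder")


Block = Instrument | QuestionGroup | Question | SociometricTemplate


@dataclass(frozen=True)
class Questionnaire:
    id: str
    type: str
    description: str
    blocks: tuple[Block, ...]
    rosters: Mapping[str, Roster] = field(default_factory=dict)
    wave_assignments: tuple[tuple[str, str], ...] = ()  # (roster id, wave label)

    @property
    def instruments(self) -> tuple[Instrument, ...]:
        return tuple(b for b in self.blocks if isinstance(b, Instrument))

    @property
    def groups(self) -> tuple[QuestionGroup, ...]:
        return tuple(b for b in self.blocks if isinstance(b, QuestionGroup))

    @property
    def questions(self) -> tuple[Question, ...]:
        return tuple(b for b in self.blocks if isinstance(b, Question))

    @property
    def templates(self) -> tuple[SociometricTemplate, ...]:
        return tuple(b for b in self.blocks if isinstance(b, SociometricTemplate))

    def template(self, template_id: str) -> SociometricTemplate:
        for t in self.templates:
            if t.id == template_id:
                return t
        raise SchemaError(f"questionnaire {self.id!r} has no template {template_id!r}")

    def roster(self, roster_id: str) -> Roster:
        try:
            return self.rosters[roster_id]
        except KeyError:
            raise SchemaError(f"questionnaire {self.id!r} has no roster {roster_id!r}") from None

    def static_item_ids(self) -> list[str]:
        """Item ids excluding roster-generated ones."""
        ids: list[str] = []
        for b in self.blocks:
            if isinstance(b, Instrument):
                ids.extend(b.item_ids)
            elif isinstance(b, QuestionGroup):
                ids.extend(b.question_ids)
            elif isinstance(b, Question):
                ids.append(b.id)
        return ids

    def generated_item_ids(self) -> list[str]:
        """All ids a sociometric template can generate across its roster."""
        ids: list[str] = []
        for t in self.templates:
            roster = self.roster(t.roster_ref)
            ids.extend(generated_item_id(t.id, p.id) for p in roster.members)
        return ids

    def all_item_ids(self) -> set[str]:
        return set(self.static_item_ids()) | set(self.generated_item_ids())

    def items_for(self, ego: Person) -> list[Item | Question]:
        """The full, ordered answerable item list for one respondent."""
        out: list[Item | Question] = []
        for b in self.blocks:
            if isinstance(b, Instrument):
                out.extend(b.items)
            elif isinstance(b, QuestionGroup):
                out.extend(b.questions)
            elif isinstance(b, Question):
                out.append(b)
            else:
                out.extend(expand_sociometric(b, self.roster(b.roster_ref), ego))
        return out


# ---------------------------------------------------------------------------
# Operations


def compose_questionnaire(
    blocks: Sequence[Block],
    metadata: Mapping[str, str] | None = None,
    rosters: Mapping[str, Roster] | None = None,
    wave_assignments: Sequence[tuple[str, str]] = (),
) -> Questionnaire:
    """Assemble a questionnaire from instrument references, question groups,
    single questions, and sociometric templates, in the given order.

    Instrument blocks are referenced, not copied, so one validated test can
    be reused across questionnaires.
    """
    metadata = dict(metadata or {})
    rosters = dict(rosters or {})
    if not blocks:
        logger.warning("composing an empty questionnaire %r", metadata.get("id", ""))
    q = Questionnaire(
        id=metadata.get("id", "questionnaire"),
        type=metadata.get("type", ""),
        description=metadata.get("description", ""),
        blocks=tuple(blocks),
        rosters=rosters,
        wave_assignments=tuple(wave_assignments),
    )
    for t in q.templates:
        if t.roster_ref not in rosters:
            raise SchemaError(f"template {t.id!r} references unknown roster {t.roster_ref!r}")
    static = q.static_item_ids()
    dupes = sorted({i for i in static if static.count(i) > 1})
    if dupes:
        raise SchemaError(f"item id collision across blocks: {dupes}")
    overlap = set(static) & set(q.generated_item_ids())
    if overlap:
        raise SchemaError(f"item id collision with generated sociometric ids: {sorted(overlap)}")
    return q


def generated_item_id(template_id: str, alter_id: str) -> str:
    return f"{template_id}::{alter_id}"


def parse_generated_item_id(item_id: str) -> tuple[str, str] | None:
    """(template id, alter id) for a roster-generated item id, else None."""
    if "::" not in item_id:
        return None
    template_id, alter_id = item_id.split("::", 1)
    return template_id, alter_id


def expand_sociometric(
    template: SociometricTemplate, roster: Roster, ego: Person
) -> list[Question]:
    """One generated question per alter, with the template's tie scale.

    One-mode templates exclude the ego (no self-tie); two-mode templates
    keep every entity regardless of the ego.  Generated ids encode
    ``(template id, alter id)`` so responses can be traced back.
    """
    if template.mode == "one_mode" and not roster.has(ego.id):
        logger.warning(
            "ego %r is not in one-mode roster %r for template %r",
            ego.id, roster.id, template.id,
        )
    items: list[Question] = []
    for alter in roster.members:
        if template.mode == "one_mode" and alter.id == ego.id:
            continue
        items.append(
            Question(
                id=generated_item_id(template.id, alter.id),
                text=template.prompt.format(alter=alter.display_name),
                options=template.scale.options(),
            )
        )
    return items


@dataclass(frozen=True)
class RosterEdit:
    kind: Literal["add", "remove", "rename"]
    roster_id: str
    person: Person  # for rename: the existing person (matched by id)
    new_name: str | None = None


@dataclass(frozen=True)
class ChangeReport:
    created: tuple[str, ...]
    deleted: tuple[str, ...]
    renamed: tuple[str, ...]
    orphaned: tuple[tuple[str, str], ...]  # (person_id of respondent, orphaned item id)

    def to_dict(self) -> dict:
        return {
            "created": list(self.created),
            "deleted": list(self.deleted),
            "renamed": list(self.renamed),
            "orphaned": [list(o) for o in self.orphaned],
        }


def apply_roster_edit(
    questionnaire: Questionnaire,
    edit: RosterEdit,
    response_set=None,
) -> tuple[Questionnaire, ChangeReport]:
    """Propagate a roster edit to every sociometric question generated from it.

    Returns the updated questionnaire and a change report listing created,
    deleted, and re-labeled generated item ids.  If ``response_set`` is
    given, stored answers that reference a removed alter are flagged as
    orphaned — never silently dropped.
    """
    roster = questionnaire.roster(edit.roster_id)
    affected = [t for t in questionnaire.templates if t.roster_ref == edit.roster_id]
    if edit.kind == "add":
        if roster.has(edit.person.id):
            raise SchemaError(f"person {edit.person.id!r} already in roster {roster.id!r}")
        new_roster = Roster(id=roster.id, members=roster.members + (edit.person,))
        created = tuple(generated_item_id(t.id, edit.person.id) for t in affected)
        deleted: tuple[str, ...] = ()
        renamed: tuple[str, ...] = ()
    elif edit.kind == "remove":
        if not roster.has(edit.person.id):
            raise SchemaError(f"person {edit.person.id!r} not in roster {roster.id!r}")
        new_roster = Roster(
            id=roster.id, members=tuple(p for p in roster.members if p.id != edit.person.id)
        )
        created = ()
        deleted = tuple(generated_item_id(t.id, edit.person.id) for t in affected)
        renamed = ()
    elif edit.kind == "rename":
        if not roster.has(edit.person.id):
            raise SchemaError(f"person {edit.person.id!r} not in roster {roster.id!r}")
        if edit.new_name is None:
            raise SchemaError("rename edit requires new_name")
        new_members = tuple(
            replace(p, display_name=edit.new_name) if p.id == edit.person.id else p
            for p in roster.members
        )
        new_roster = Roster(id=roster.id, members=new_members)
        created = ()
        deleted = ()
        renamed = tuple(generated_item_id(t.id, edit.person.id) for t in affected)
    else:
        raise SchemaError(f"unknown edit kind {edit.kind!r}")

    orphaned: list[tuple[str, str]] = []
    if response_set is not None and deleted:
        deleted_set = set(deleted)
        for resp in response_set.responses:
            for item_id in resp.answers:
                if item_id in deleted_set:
                    orphaned.append((resp.person_id, item_id))
    new_rosters = dict(questionnaire.rosters)
    new_rosters[roster.id] = new_roster
    updated = replace(questionnaire, rosters=new_rosters)
    return updated, ChangeReport(
        created=created, deleted=deleted, renamed=renamed, orphaned=tuple(sorted(orphaned))
    )


def anonymize(values: Iterable[str], salt: str) -> tuple[list[str], dict[str, str]]:
    """Pseudonymize protected field values with a keyed hash.

    Deterministic for a fixed salt, so re-runs produce stable pseudonyms
    without persisting any state beyond the salt.  Returns the pseudonym
    list (order-preserving) and the value -> pseudonym mapping, which must
    be stored separately from data outputs.
    """
    if not salt:
        raise SchemaError("anonymization salt must be non-empty")
    mapping: dict[str, str] = {}
    out: list[str] = []
    for v in values:
        token = hmac.new(salt.encode("utf-8"), v.encode("utf-8"), hashlib.sha256).hexdigest()[:12]
        pseudonym = f"anon-{token}"
        mapping[v] = pseudonym
        out.append(pseudonym)
    return out, mapping


def evaluate_group_score(group: QuestionGroup, answers: Mapping[str, str]) -> float:
    """Total score of a question group under its formula."""
    values: dict[str, float] = {}
    for q in group.questions:
        if q.id not in answers:
            raise SchemaError(f"missing answer for question {q.id!r} of group {group.id!r}")
        values[q.id] = q.value_of(answers[q.id])
    unknown = set(answers) - set(group.question_ids)
    if unknown:
        raise SchemaError(f"answers reference questions not in group {group.id!r}: {sorted(unknown)}")
    bound = group.scoring.bound(group.question_ids)
    total = _expr.evaluate(bound, values)
    return int(total) if float(total).is_integer() else total
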