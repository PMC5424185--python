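"""Ingest, validate, and score filled questionnaires.

Responses arrive as CSV tables: one row per respondent, a ``person_id``
column, an optional ``wave`` column, and one column per item id.  Columns
are matched by item id rather than position, so per-class files whose
sociometric column sets differ (each class rates its own roster) load
against the same questionnaire and merge into one response set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .instruments import InstrumentScore, MissingPolicy, score_instrument
from .survey import (
    Questionnaire,
    SchemaError,
    evaluate_group_score,
    parse_generated_item_id,
)

__all__ = [
    "ResponseError",
    "ResponseSet",
    "RespondentResponse",
    "ScoredRecord",
    "ValidationIssue",
    "merge_response_sets",
    "read_responses",
    "score_all",
    "scored_records_to_frame",
    "validate_responses",
]

logger = logging.getLogger(__name__)

DEFAULT_WAVE = "wave1"


class ResponseError(ValueError):
    pass


@dataclass(frozen=True)
class RespondentResponse:
    person_id: str
    wave: str
    answers: Mapping[str, str]  # item id -> recorded option code


@dataclass(frozen=True)
class ResponseSet:
    questionnaire_id: str
    wave: str
    responses: tuple[RespondentResponse, ...]
    ignored_columns: tuple[str, ...] = ()

    def __post_init__(self):
        keys = [(r.person_id, r.wave) for r in self.responses]
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        if dupes:
            raise ResponseError(f"duplicate (person, wave) rows: {dupes}")

    def for_person(self, person_id: str, wave: str | None = None) -> RespondentResponse:
        for r in self.responses:
            if r.person_id == person_id and (wave is None or r.wave == wave):
                return r
        raise ResponseError(f"no response for person {person_id!r}")


@dataclass(frozen=True)
class ScoredRecord:
    person_id: str
    wave: str
    instrument_scores: tuple[InstrumentScore, ...]
    group_totals: Mapping[str, float] = field(default_factory=dict)

    def score_for(self, instrument_id: str) -> InstrumentScore | None:
        for s in self.instrument_scores:
            if s.instrument_id == instrument_id:
                return s
        return None


@dataclass(frozen=True)
class ValidationIssue:
    kind: str  # unknown_code | orphan_alter | unknown_person | duplicate
    person_id: str
    item_id: str | None
    detail: str


def _clean(value: object) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() == "nan":
        return None
    # CSV round trips integer codes through floats ("2.0"); normalize back
    if s.endswith(".0") and s[:-2].isdigit():
        s = s[:-2]
    return s


def read_responses(
    tables: str | Path | pd.DataFrame | Sequence[str | Path | pd.DataFrame],
    questionnaire: Questionnaire,
    wave: str | None = None,
) -> ResponseSet:
    """Load one or more response tables into a single :class:`ResponseSet`.

    Unknown columns (not any static or roster-generated item id) are
    reported on ``ignored_columns``, not fatal.  A missing ``wave`` column
    defaults every row to ``wave1``; duplicate (person, wave) rows are an
    error, not last-wins.
    """
    if isinstance(tables, (str, Path, pd.DataFrame)):
        tables = [tables]
    known = questionnaire.all_item_ids()
    responses: list[RespondentResponse] = []
    ignored: list[str] = []
    waves_seen: set[str] = set()
    for table in tables:
        df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table, dtype=str)
        if "person_id" not in df.columns:
            raise ResponseError("response table is missing the person_id column")
        item_cols = [c for c in df.columns if c not in ("person_id", "wave")]
        unknown_cols = [c for c in item_cols if c not in known]
        if unknown_cols:
            logger.warning("ignoring %d unknown columns: %s", len(unknown_cols), unknown_cols)
            ignored.extend(unknown_cols)
        item_cols = [c for c in item_cols if c in known]
        if df.empty:
            logger.warning("response table has no data rows")
        for _, row in df.iterrows():
            person_id = _clean(row["person_id"])
            if person_id is None:
                raise ResponseError("row with empty person_id")
            row_wave = _clean(row["wave"]) if "wave" in df.columns else None
            row_wave = row_wave or wave or DEFAULT_WAVE
            waves_seen.add(row_wave)
            answers = {}
            for c in item_cols:
                v = _clean(row[c])
                if v is not None:
                    answers[c] = v
            responses.append(RespondentResponse(person_id=person_id, wave=row_wave, answers=answers))
    set_wave = wave or (waves_seen.pop() if len(waves_seen) == 1 else "multi")
    return ResponseSet(
        questionnaire_id=questionnaire.id,
        wave=set_wave,
        responses=tuple(responses),
        ignored_columns=tuple(dict.fromkeys(ignored)),
    )


def merge_response_sets(sets: Iterable[ResponseSet]) -> ResponseSet:
    sets = list(sets)
    if not sets:
        raise ResponseError("nothing to merge")
    qids = {s.questionnaire_id for s in sets}
    if len(qids) > 1:
        raise ResponseError(f"cannot merge response sets from different questionnaires: {sorted(qids)}")
    waves = {s.wave for s in sets}
    return ResponseSet(
        questionnaire_id=sets[0].questionnaire_id,
        wave=waves.pop() if len(waves) == 1 else "multi",
        responses=tuple(r for s in sets for r in s.responses),
        ignored_columns=tuple(dict.fromkeys(c for s in sets for c in s.ignored_columns)),
    )


def validate_responses(rs: ResponseSet, questionnaire: Questionnaire) -> list[ValidationIssue]:
    """Enumerate data problems; an empty list means the set is clean."""
    issues: list[ValidationIssue] = []
    static_lookup: dict[str, object] = {}
    for inst in questionnaire.instruments:
        for it in inst.items:
            static_lookup[it.id] = it
    for grp in questionnaire.groups:
        for q in grp.questions:
            static_lookup[q.id] = q
    for q in questionnaire.questions:
        static_lookup[q.id] = q
    study_persons = {p.id for r in questionnaire.rosters.values() for p in r.members}
    for resp in rs.responses:
        if study_persons and resp.person_id not in study_persons:
            issues.append(
                ValidationIssue("unknown_person", resp.person_id, None,
                                f"person {resp.person_id!r} is not on any study roster")
            )
        for item_id, code in resp.answers.items():
            gen = parse_generated_item_id(item_id)
            if gen is not None:
                template_id, alter_id = gen
                try:
                    template = questionnaire.template(template_id)
                except SchemaError:
                    issues.append(ValidationIssue("unknown_code", resp.person_id, item_id,
                                                  f"unknown template {template_id!r}"))
                    continue
                roster = questionnaire.roster(template.roster_ref)
                if not roster.has(alter_id):
                    issues.append(
                        ValidationIssue("orphan_alter", resp.person_id, item_id,
                                        f"answer names alter {alter_id!r} no longer on roster {roster.id!r}")
                    )
                    continue
                try:
                    template.scale.weight_of(code)
                except SchemaError:
                    issues.append(ValidationIssue("unknown_code", resp.person_id, item_id,
                                                  f"code {code!r} is not on the tie scale"))
            else:
                item = static_lookup.get(item_id)
                if item is None:
                    continue  # already reported as ignored column at load time
                try:
                    item.value_of(code)
                except Exception:
                    issues.append(ValidationIssue("unknown_code", resp.person_id, item_id,
                                                  f"code {code!r} is not a valid option of {item_id!r}"))
    return issues


def score_all(
    rs: ResponseSet,
    questionnaire: Questionnaire,
    missing_policy: MissingPolicy = "strict",
) -> list[ScoredRecord]:
    """Score every respondent on every instrument and question group.

    Deterministic and row-order independent: records are returned sorted by
    (person, wave).  This replaces the manual per-respondent calculation
    workflow that standardized instruments otherwise require.
    """
    records: list[ScoredRecord] = []
    for resp in sorted(rs.responses, key=lambda r: (r.person_id, r.wave)):
        inst_scores = []
        for inst in questionnaire.instruments:
            sub_answers = {i: resp.answers[i] for i in inst.item_ids if i in resp.answers}
            inst_scores.append(score_instrument(inst, sub_answers, missing_policy))
        group_totals = {}
        for grp in questionnaire.groups:
            sub_answers = {i: resp.answers[i] for i in grp.question_ids if i in resp.answers}
            if missing_policy == "strict" or len(sub_answers) == len(grp.question_ids):
                group_totals[grp.id] = evaluate_group_score(grp, sub_answers)
        records.append(
            ScoredRecord(
                person_id=resp.person_id,
                wave=resp.wave,
                instrument_scores=tuple(inst_scores),
                group_totals=group_totals,
            )
        )
    return records


def scored_records_to_frame(records: Sequence[ScoredRecord]) -> pd.DataFrame:
    """Flatten scored records to a table (one column per total and band)."""
    rows = []
    for rec in records:
        row: dict[str, object] = {"person_id": rec.person_id, "wave": rec.wave}
        for s in rec.instrument_scores:
            row[f"{s.instrument_id}_total"] = s.total
            if s.band_label is not None:
                row[f"{s.instrument_id}_band"] = s.band_label
            for name, v in s.subscale_totals.items():
                row[f"{s.instrument_id}_{name}"] = v
        for gid, v in rec.group_totals.items():
            row[f"{gid}_total"] = v
        rows.append(row)
    return pd.DataFrame(rows)
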