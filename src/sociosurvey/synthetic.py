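"""Synthetic cohorts, friendship networks, and instrument responses.

Generates study data at the scale of a typical multi-school sociometric
deployment — by default 214 students in 9 classrooms across 3 secondary
schools — with planted statistical structure so the whole pipeline can be
exercised and parameter recovery can be tested without any real data:

* **homophily** — friendship nominations are biased toward the same class,
  the same sex, and similar planted consumption levels through log-odds
  boosts in an ego-wise nomination model;
* **popularity–consumption coupling** — after the network is drawn, each
  student's consumption level is tilted by their standardized in-degree, so
  popular students drink more when the coupling is positive;
* **screening totals** — AUDIT item answers are sampled so per-person
  totals follow a level-conditional normal distribution truncated to 0–40.

A single integer seed drives one splittable generator stream per stage
(cohort, friendship, responses), so each stage is independently
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .instruments import Instrument, load_bundled_instrument
from .networks import TieRecord
from .responses import DEFAULT_WAVE, ResponseSet, RespondentResponse
from .survey import (
    DEFAULT_TIE_SCALE,
    Person,
    Questionnaire,
    Roster,
    SociometricTemplate,
    compose_questionnaire,
    generated_item_id,
)

__all__ = [
    "Cohort",
    "CohortSpec",
    "SyntheticResponses",
    "build_study_questionnaire",
    "generate_cohort",
    "generate_friendship",
    "generate_responses",
    "simulate_study",
]

#: Consumption levels planted per student (none/low/moderate/high) and the
#: AUDIT total distribution conditional on each level.
LEVEL_PROBS = (0.40, 0.35, 0.17, 0.08)
LEVEL_MEANS = (1.0, 5.0, 12.0, 22.0)
LEVEL_SDS = (1.5, 2.5, 3.0, 4.0)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for the generator.

    ``students_per_class`` may be a single size or one size per class; the
    default distributes 214 students over 9 classes (seven of 24, two of
    23), the deployment scale the defaults emulate.
    """

    n_schools: int = 3
    classes_per_school: int = 3
    students_per_class: int | Sequence[int] = (24, 24, 24, 24, 24, 24, 24, 23, 23)
    sex_ratio: float = 0.5  # probability of "F"
    seed: int = 0
    same_class_boost: float = 2.0
    same_sex_boost: float = 0.5
    consumption_similarity_boost: float = 1.0
    mean_out_degree: float = 5.0
    level_probs: tuple[float, ...] = LEVEL_PROBS
    level_means: tuple[float, ...] = LEVEL_MEANS
    level_sds: tuple[float, ...] = LEVEL_SDS
    popularity_coupling: float = 1.0
    tie_level_probs: tuple[float, ...] = (0.2, 0.3, 0.5)

    def __post_init__(self):
        if self.n_schools <= 0 or self.classes_per_school <= 0:
            raise ValueError("school and class counts must be positive")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")
        for b in (self.same_class_boost, self.same_sex_boost, self.consumption_similarity_boost):
            if b < 0:
                raise ValueError("homophily boosts must be >= 0")
        if self.mean_out_degree < 0:
            raise ValueError("mean_out_degree must be >= 0")
        if not math.isclose(sum(self.level_probs), 1.0, abs_tol=1e-9):
            raise ValueError("level_probs must sum to 1")
        if not math.isclose(sum(self.tie_level_probs), 1.0, abs_tol=1e-9):
            raise ValueError("tie_level_probs must sum to 1")
        sizes = self.class_sizes()
        if any(s <= 0 for s in sizes):
            raise ValueError("class sizes must be positive")

    def n_classes(self) -> int:
        return self.n_schools * self.classes_per_school

    def class_sizes(self) -> tuple[int, ...]:
        if isinstance(self.students_per_class, int):
            return (self.students_per_class,) * self.n_classes()
        sizes = tuple(int(s) for s in self.students_per_class)
        if len(sizes) != self.n_classes():
            raise ValueError(
                f"students_per_class lists {len(sizes)} classes, spec defines {self.n_classes()}"
            )
        return sizes

    def n_students(self) -> int:
        return sum(self.class_sizes())

    def stage_rng(self, stage: int, seed: int | None = None) -> np.random.Generator:
        base = self.seed if seed is None else seed
        return np.random.default_rng(np.random.SeedSequence(entropy=base, spawn_key=(stage,)))


@dataclass(frozen=True)
class Cohort:
    persons: tuple[Person, ...]
    study_roster: Roster
    class_rosters: Mapping[str, Roster]
    consumption_base: Mapping[str, int]  # planted level per person, before coupling

    def person_index(self) -> dict[str, int]:
        return {p.id: i for i, p in enumerate(self.persons)}


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> Cohort:
    """Deterministic cohort: persons with sex/class/school attributes and a
    planted baseline consumption level, grouped into class rosters."""
    rng = spec.stage_rng(0, seed)
    persons: list[Person] = []
    class_rosters: dict[str, Roster] = {}
    consumption: dict[str, int] = {}
    counter = 0
    class_idx = 0
    sizes = spec.class_sizes()
    for school_i in range(spec.n_schools):
        school = f"school{school_i + 1}"
        for _ in range(spec.classes_per_school):
            class_id = f"class{class_idx + 1}"
            members = []
            for _ in range(sizes[class_idx]):
                counter += 1
                pid = f"s{counter:03d}"
                sex = "F" if rng.random() < spec.sex_ratio else "M"
                level = int(rng.choice(len(spec.level_probs), p=spec.level_probs))
                person = Person(
                    id=pid,
                    display_name=f"Student {counter:03d}",
                    attributes={"sex": sex, "class": class_id, "school": school},
                )
                persons.append(person)
                members.append(person)
                consumption[pid] = level
            class_rosters[class_id] = Roster(id=class_id, members=tuple(members))
            class_idx += 1
    study_roster = Roster(id="study", members=tuple(persons))
    return Cohort(
        persons=tuple(persons),
        study_roster=study_roster,
        class_rosters=class_rosters,
        consumption_base=consumption,
    )


def generate_friendship(
    cohort: Cohort,
    spec: CohortSpec,
    seed: int | None = None,
    relation_label: str = "friendship",
    wave: str = DEFAULT_WAVE,
) -> list[TieRecord]:
    """Ego-wise nomination model.

    Each ego draws an out-degree (Poisson around the spec mean) and samples
    that many distinct alters with selection log-odds
    ``same_class·β₁ + same_sex·β₂ + consumption_similarity·β₃``; the tie
    level is then drawn from the tie scale's level distribution.  No
    self-ties; deterministic per seed.
    """
    rng = spec.stage_rng(1, seed)
    persons = cohort.persons
    n = len(persons)
    classes = np.array([p.attributes["class"] for p in persons])
    sexes = np.array([p.attributes["sex"] for p in persons])
    levels = np.array([cohort.consumption_base[p.id] for p in persons], dtype=float)
    max_level = max(len(spec.level_probs) - 1, 1)
    weights = DEFAULT_TIE_SCALE.weights
    ties: list[TieRecord] = []
    for i, ego in enumerate(persons):
        k = int(rng.poisson(spec.mean_out_degree))
        k = min(k, n - 1)
        if k == 0:
            continue
        logits = (
            spec.same_class_boost * (classes == classes[i])
            + spec.same_sex_boost * (sexes == sexes[i])
            + spec.consumption_similarity_boost * (1.0 - np.abs(levels - levels[i]) / max_level)
        )
        logits[i] = -np.inf
        stable = logits - logits.max()
        probs = np.exp(stable)
        probs /= probs.sum()
        alters = rng.choice(n, size=k, replace=False, p=probs)
        tie_levels = rng.choice(len(weights), size=k, p=spec.tie_level_probs)
        for j, lvl in zip(alters, tie_levels):
            ties.append(
                TieRecord(
                    ego_id=ego.id,
                    alter_id=persons[j].id,
                    relation_label=relation_label,
                    weight=float(weights[lvl]),
                    wave=wave,
                )
            )
    return ties


@dataclass(frozen=True)
class SyntheticResponses:
    """Generated answers plus the planted ground truth behind them."""

    response_set: ResponseSet
    consumption_levels: Mapping[str, int]  # final levels, after popularity coupling
    audit_totals: Mapping[str, int]


def _decompose_total(
    instrument: Instrument, total: int, rng: np.random.Generator
) -> dict[str, str]:
    """Random item answers whose option values sum exactly to ``total``."""
    items = list(instrument.items)
    # achievable[i] = set of sums reachable with items[i:], so every partial
    # choice stays completable even for items with gapped option values
    achievable: list[set[float]] = [set() for _ in range(len(items) + 1)]
    achievable[-1] = {0.0}
    for i in range(len(items) - 1, -1, -1):
        achievable[i] = {v + s for v in items[i].values for s in achievable[i + 1]}
    answers: dict[str, str] = {}
    remaining = float(total)
    for i, item in enumerate(items):
        feasible = [o for o in item.options if remaining - o.value in achievable[i + 1]]
        chosen = feasible[rng.integers(len(feasible))]
        answers[item.id] = chosen.code
        remaining -= chosen.value
    assert remaining == 0
    return answers


def generate_responses(
    cohort: Cohort,
    ties: Sequence[TieRecord],
    instruments: Sequence[Instrument],
    spec: CohortSpec,
    seed: int | None = None,
    template_id: str = "friend",
    wave: str = DEFAULT_WAVE,
) -> SyntheticResponses:
    """Filled questionnaires consistent with the planted structure.

    AUDIT totals follow the level-conditional normal distributions truncated
    to the instrument's 0–40 range; the popularity–consumption coupling
    tilts each student's level by their standardized in-degree before totals
    are drawn.  Instruments other than AUDIT are answered uniformly.
    Sociometric answers reproduce the given ties exactly.
    """
    rng = spec.stage_rng(2, seed)
    in_degree = {p.id: 0 for p in cohort.persons}
    for t in ties:
        in_degree[t.alter_id] += 1
    deg = np.array([in_degree[p.id] for p in cohort.persons], dtype=float)
    z = (deg - deg.mean()) / deg.std() if deg.std() > 0 else np.zeros_like(deg)
    n_levels = len(spec.level_probs)
    grid = np.arange(n_levels, dtype=float)
    means = np.asarray(spec.level_means, dtype=float)
    sds = np.asarray(spec.level_sds, dtype=float)

    def mean_at(latent: float) -> float:
        # linear interpolation between level means, extrapolated with the end
        # slopes so the coupling keeps acting beyond the top planted level
        if latent <= grid[0]:
            slope = (means[1] - means[0]) / (grid[1] - grid[0])
            return float(means[0] + slope * (latent - grid[0]))
        if latent >= grid[-1]:
            slope = (means[-1] - means[-2]) / (grid[-1] - grid[-2])
            return float(means[-1] + slope * (latent - grid[-1]))
        return float(np.interp(latent, grid, means))

    final_levels: dict[str, int] = {}
    latents: dict[str, float] = {}
    for i, p in enumerate(cohort.persons):
        latent = cohort.consumption_base[p.id] + spec.popularity_coupling * z[i]
        latents[p.id] = latent
        final_levels[p.id] = int(np.clip(round(latent), 0, n_levels - 1))

    weight_to_code = {w: c for c, _, w in DEFAULT_TIE_SCALE.levels}
    ties_by_ego: dict[str, list[TieRecord]] = {}
    for t in ties:
        ties_by_ego.setdefault(t.ego_id, []).append(t)

    audit = next((inst for inst in instruments if inst.id == "audit"), None)
    audit_totals: dict[str, int] = {}
    responses: list[RespondentResponse] = []
    for p in cohort.persons:
        answers: dict[str, str] = {}
        for inst in instruments:
            if inst is audit:
                lvl = final_levels[p.id]
                total = rng.normal(mean_at(latents[p.id]), sds[lvl])
                total = int(np.clip(round(total), 0, 40))
                audit_totals[p.id] = total
                answers.update(_decompose_total(audit, total, rng))
            else:
                for item in inst.items:
                    answers[item.id] = item.options[rng.integers(len(item.options))].code
        for t in ties_by_ego.get(p.id, ()):
            answers[generated_item_id(template_id, t.alter_id)] = weight_to_code[t.weight]
        responses.append(RespondentResponse(person_id=p.id, wave=wave, answers=answers))
    rs = ResponseSet(questionnaire_id="study", wave=wave, responses=tuple(responses))
    return SyntheticResponses(
        response_set=rs, consumption_levels=final_levels, audit_totals=audit_totals
    )


def build_study_questionnaire(
    cohort: Cohort,
    instruments: Sequence[Instrument],
    template_id: str = "friend",
) -> Questionnaire:
    """The default study questionnaire: instruments plus one friendship
    name-generator over the whole study roster."""
    template = SociometricTemplate(
        id=template_id,
        prompt="How is your relationship with {alter}?",
        relation_label="friendship",
        mode="one_mode",
        roster_ref="study",
        scale=DEFAULT_TIE_SCALE,
    )
    rosters = {"study": cohort.study_roster}
    rosters.update(cohort.class_rosters)
    return compose_questionnaire(
        blocks=list(instruments) + [template],
        metadata={"id": "study", "type": "school survey",
                  "description": "Alcohol-use screening with a friendship name generator."},
        rosters=rosters,
    )


@dataclass(frozen=True)
class StudyBundle:
    spec: CohortSpec
    cohort: Cohort
    ties: list[TieRecord]
    questionnaire: Questionnaire
    synthetic: SyntheticResponses


def simulate_study(
    spec: CohortSpec | None = None,
    seed: int | None = None,
    instruments: Sequence[Instrument] | None = None,
) -> StudyBundle:
    """Generate a full study in one call (cohort → ties → responses)."""
    spec = spec or CohortSpec()
    if instruments is None:
        instruments = [load_bundled_instrument("audit")]
    cohort = generate_cohort(spec, seed)
    ties = generate_friendship(cohort, spec, seed)
    questionnaire = build_study_questionnaire(cohort, instruments)
    synthetic = generate_responses(cohort, ties, instruments, spec, seed)
    return StudyBundle(
        spec=spec, cohort=cohort, ties=ties, questionnaire=questionnaire, synthetic=synthetic
    )


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    rows = [
        {"id": p.id, "display_name": p.display_name, "sex": p.attributes["sex"],
         "class": p.attributes["class"], "school": p.attributes["school"]}
        for p in cohort.persons
    ]
    return pd.DataFrame(rows)


def responses_to_class_frames(
    bundle: StudyBundle, template_id: str = "friend"
) -> dict[str, pd.DataFrame]:
    """One response table per classroom, with only the columns that class
    actually answered — reproducing the per-class column differences that
    merged spreadsheets exhibit in real deployments."""
    by_class: dict[str, list[RespondentResponse]] = {}
    person_class = {p.id: p.attributes["class"] for p in bundle.cohort.persons}
    for resp in bundle.synthetic.response_set.responses:
        by_class.setdefault(person_class[resp.person_id], []).append(resp)
    frames = {}
    for class_id in sorted(by_class):
        rows = []
        for resp in by_class[class_id]:
            row: dict[str, object] = {"person_id": resp.person_id, "wave": resp.wave}
            row.update(resp.answers)
            rows.append(row)
        df = pd.DataFrame(rows)
        static = [c for c in df.columns if "::" not in c]
        socio = sorted(c for c in df.columns if "::" in c)
        frames[class_id] = df[static + socio]
    return frames
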