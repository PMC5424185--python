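"""Validated questionnaire instruments: items, scoring rules, and risk bands.

An :class:`Instrument` is a standardized test such as AUDIT (the Alcohol Use
Disorders Identification Test): a fixed, ordered set of multiple-choice items
whose option values feed a scoring rule, plus an optional table of score
bands mapping the quantitative total onto qualitative risk categories with a
recommended intervention (e.g. AUDIT Zone I "Alcohol education" for totals
0–7).  Definitions are JSON documents; the dialect is described by the
JSON-Schema file shipped under ``data/instrument.schema.json``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping

from . import _expr
from ._expr import ExpressionError

__all__ = [
    "Instrument",
    "InstrumentError",
    "InstrumentScore",
    "Item",
    "ResponseOption",
    "ScoreBand",
    "ScoringRule",
    "Subscale",
    "attainable_range",
    "bundled_instrument_ids",
    "load_bundled_instrument",
    "load_instrument",
    "map_to_band",
    "score_instrument",
    "serialize_instrument",
]

MissingPolicy = Literal["strict", "prorate", "omit"]


class InstrumentError(ValueError):
    """Malformed instrument definition or invalid scoring request."""


@dataclass(frozen=True)
class ResponseOption:
    code: str
    label: str
    value: float

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise InstrumentError(f"option {self.code!r} has a non-finite value")


@dataclass(frozen=True)
class Item:
    id: str
    text: str
    options: tuple[ResponseOption, ...]

    def __post_init__(self):
        if len(self.options) < 2:
            raise InstrumentError(f"item {self.id!r} needs at least 2 response options")
        codes = [o.code for o in self.options]
        if len(set(codes)) != len(codes):
            raise InstrumentError(f"item {self.id!r} has duplicate option codes")

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(o.value for o in self.options)

    def value_of(self, code: str) -> float:
        for o in self.options:
            if o.code == code:
                return o.value
        raise InstrumentError(f"unknown option code {code!r} for item {self.id!r}")


@dataclass(frozen=True)
class ScoringRule:
    """Arithmetic expression over item values; ``sum(*)`` means all items."""

    expression: str = "sum(*)"

    def bound(self, item_ids: tuple[str, ...]) -> str:
        return _expr.expand_wildcard(self.expression, item_ids)


@dataclass(frozen=True)
class ScoreBand:
    label: str
    action: str
    lo: float
    hi: float

    def __post_init__(self):
        if self.lo > self.hi:
            raise InstrumentError(f"band {self.label!r} has lo > hi")

    def contains(self, total: float) -> bool:
        return self.lo <= total <= self.hi


@dataclass(frozen=True)
class Subscale:
    name: str
    item_ids: tuple[str, ...]
    scoring: ScoringRule = field(default_factory=ScoringRule)

    def __post_init__(self):
        if not self.item_ids:
            raise InstrumentError(f"subscale {self.name!r} has no items")


@dataclass(frozen=True)
class Instrument:
    id: str
    name: str
    citation: str
    items: tuple[Item, ...]
    scoring: ScoringRule = field(default_factory=ScoringRule)
    bands: tuple[ScoreBand, ...] = ()
    subscales: tuple[Subscale, ...] = ()
    provisional: bool = False

    def __post_init__(self):
        _validate_instrument(self)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(i.id for i in self.items)

    def item(self, item_id: str) -> Item:
        for it in self.items:
            if it.id == item_id:
                return it
        raise InstrumentError(f"instrument {self.id!r} has no item {item_id!r}")

    @property
    def integer_valued(self) -> bool:
        return all(float(v).is_integer() for it in self.items for v in it.values)


@dataclass(frozen=True)
class InstrumentScore:
    instrument_id: str
    total: float
    band_label: str | None = None
    band_action: str | None = None
    subscale_totals: Mapping[str, float] = field(default_factory=dict)


def _validate_instrument(inst: Instrument) -> None:
    if not inst.citation.strip():
        raise InstrumentError(f"instrument {inst.id!r}: citation is required")
    if not inst.items:
        raise InstrumentError(f"instrument {inst.id!r} has no items")
    ids = [i.id for i in inst.items]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise InstrumentError(f"instrument {inst.id!r}: duplicate item ids {sorted(dupes)}")
    bound = inst.scoring.bound(inst.item_ids)
    for ref in _expr.referenced_ids(bound):
        if ref not in ids:
            raise InstrumentError(f"instrument {inst.id!r}: scoring references unknown item {ref!r}")
    for sub in inst.subscales:
        for sid in sub.item_ids:
            if sid not in ids:
                raise InstrumentError(
                    f"instrument {inst.id!r}: subscale {sub.name!r} references unknown item {sid!r}"
                )
    if inst.bands:
        _validate_bands(inst)


def _validate_bands(inst: Instrument) -> None:
    lo, hi = attainable_range(inst)
    bands = inst.bands
    ordered = sorted(bands, key=lambda b: b.lo)
    if list(ordered) != list(bands):
        raise InstrumentError(f"instrument {inst.id!r}: bands are not sorted by lower bound")
    if bands[0].lo != lo:
        raise InstrumentError(
            f"instrument {inst.id!r}: first band starts at {bands[0].lo}, attainable minimum is {lo}"
        )
    if bands[-1].hi != hi:
        raise InstrumentError(
            f"instrument {inst.id!r}: last band ends at {bands[-1].hi}, attainable maximum is {hi}"
        )
    for prev, nxt in zip(bands, bands[1:]):
        if nxt.lo <= prev.hi:
            raise InstrumentError(
                f"instrument {inst.id!r}: bands {prev.label!r} and {nxt.label!r} overlap"
            )
        if nxt.lo != prev.hi + 1:
            raise InstrumentError(f"instrument {inst.id!r}: band gap at {prev.hi + 1}")


# ---------------------------------------------------------------------------
# Loading and serialization


def load_instrument(document: Mapping | str | Path) -> Instrument:
    """Build a validated :class:`Instrument` from a JSON document or mapping."""
    if isinstance(document, (str, Path)):
        with open(document, encoding="utf-8") as fh:
            document = json.load(fh)
    if not isinstance(document, Mapping):
        raise InstrumentError("instrument definition must be a JSON object")
    for key in ("id", "name", "citation", "items"):
        if key not in document:
            raise InstrumentError(f"instrument definition is missing required key {key!r}")
    items = tuple(
        Item(
            id=str(it["id"]),
            text=str(it.get("text", "")),
            options=tuple(
                ResponseOption(code=str(o["code"]), label=str(o.get("label", "")), value=float(o["value"]))
                for o in it["options"]
            ),
        )
        for it in document["items"]
    )
    scoring = ScoringRule(str(document.get("scoring", {}).get("expression", "sum(*)"))
                          if isinstance(document.get("scoring"), Mapping)
                          else str(document.get("scoring") or "sum(*)"))
    bands = tuple(
        ScoreBand(label=str(b["label"]), action=str(b.get("action", "")), lo=float(b["lo"]), hi=float(b["hi"]))
        for b in document.get("bands", ())
    )
    subscales = tuple(
        Subscale(
            name=str(s["name"]),
            item_ids=tuple(str(i) for i in s["item_ids"]),
            scoring=ScoringRule(str(s.get("scoring", "sum(*)"))),
        )
        for s in document.get("subscales", ())
    )
    return Instrument(
        id=str(document["id"]),
        name=str(document["name"]),
        citation=str(document["citation"]),
        items=items,
        scoring=scoring,
        bands=bands,
        subscales=subscales,
        provisional=bool(document.get("provisional", False)),
    )


def serialize_instrument(inst: Instrument) -> dict:
    """Inverse of :func:`load_instrument` (round-trips exactly)."""
    return {
        "id": inst.id,
        "name": inst.name,
        "citation": inst.citation,
        "items": [
            {
                "id": it.id,
                "text": it.text,
                "options": [{"code": o.code, "label": o.label, "value": o.value} for o in it.options],
            }
            for it in inst.items
        ],
        "scoring": {"expression": inst.scoring.expression},
        "bands": [{"label": b.label, "action": b.action, "lo": b.lo, "hi": b.hi} for b in inst.bands],
        "subscales": [
            {"name": s.name, "item_ids": list(s.item_ids), "scoring": s.scoring.expression}
            for s in inst.subscales
        ],
        "provisional": inst.provisional,
    }


def bundled_instrument_ids() -> list[str]:
    root = resources.files("sociosurvey").joinpath("data/instruments")
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".json"))


def load_bundled_instrument(instrument_id: str) -> Instrument:
    """Load one of the definitions shipped with the package (e.g. ``audit``)."""
    path = resources.files("sociosurvey").joinpath(f"data/instruments/{instrument_id}.json")
    try:
        text = path.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise InstrumentError(
            f"no bundled instrument {instrument_id!r}; available: {bundled_instrument_ids()}"
        ) from None
    return load_instrument(json.loads(text))


# ---------------------------------------------------------------------------
# Scoring


def attainable_range(instrument: Instrument) -> tuple[float, float]:
    """Min/max total over all combinations of option values.

    Sum-type rules reduce to per-item minima/maxima; general expressions fall
    back to exact interval evaluation or exhaustive search (see ``_expr``).
    """
    bound = instrument.scoring.bound(instrument.item_ids)
    option_values = {it.id: it.values for it in instrument.items}
    try:
        return _expr.value_range(bound, option_values)
    except ExpressionError as exc:
        raise InstrumentError(str(exc)) from exc


def map_to_band(instrument: Instrument, total: float) -> tuple[str, str]:
    """Qualitative band (label, intervention text) for a quantitative total."""
    if not instrument.bands:
        raise InstrumentError(f"instrument {instrument.id!r} has no score bands")
    lo, hi = attainable_range(instrument)
    if not lo <= total <= hi:
        raise InstrumentError(
            f"total {total} outside attainable range [{lo}, {hi}] of instrument {instrument.id!r}"
        )
    for band in instrument.bands:
        if band.contains(total):
            return band.label, band.action
    raise InstrumentError(f"no band contains total {total} (instrument {instrument.id!r})")


def _round_half_up(x: float) -> float:
    return math.floor(x + 0.5)


def _resolve_values(
    instrument_items: tuple[Item, ...],
    answers: Mapping[str, str],
    missing_policy: MissingPolicy,
    owner: str,
) -> dict[str, float]:
    known = {it.id for it in instrument_items}
    for item_id in answers:
        if item_id not in known:
            raise InstrumentError(f"unknown item id {item_id!r} for {owner}")
    values: dict[str, float] = {}
    missing: list[Item] = []
    for it in instrument_items:
        if it.id in answers:
            values[it.id] = it.value_of(answers[it.id])
        else:
            missing.append(it)
    if missing:
        if missing_policy == "strict":
            raise InstrumentError(
                f"missing answers for items {[m.id for m in missing]} of {owner} under strict policy"
            )
        if missing_policy == "omit":
            for it in missing:
                values[it.id] = min(it.values)
        elif missing_policy == "prorate":
            if not values:
                raise InstrumentError(f"cannot prorate {owner}: no items answered")
            imputed = sum(values.values()) / len(values)
            for it in missing:
                values[it.id] = imputed
        else:
            raise InstrumentError(f"unknown missing policy {missing_policy!r}")
    return values


def score_instrument(
    instrument: Instrument,
    answers: Mapping[str, str],
    missing_policy: MissingPolicy = "strict",
) -> InstrumentScore:
    """Total score, band label, and subscale totals for one respondent.

    ``answers`` maps item ids to the recorded option codes.  Under
    ``prorate`` missing items are imputed with the mean value of the answered
    ones; under ``omit`` they contribute the item minimum; under ``strict``
    (default) any missing item is an error.  Prorated totals are rounded
    half-up to integer resolution before band mapping when the instrument is
    integer valued.
    """
    values = _resolve_values(instrument.items, answers, missing_policy, f"instrument {instrument.id!r}")
    bound = instrument.scoring.bound(instrument.item_ids)
    total = _expr.evaluate(bound, values)
    band_total = total
    if instrument.integer_valued and not float(total).is_integer():
        band_total = _round_half_up(total)
    if instrument.integer_valued and float(total).is_integer():
        total = int(total)
        band_total = total
    band_label = band_action = None
    if instrument.bands:
        band_label, band_action = map_to_band(instrument, band_total)
    subscale_totals = {}
    for sub in instrument.subscales:
        sub_bound = sub.scoring.bound(sub.item_ids)
        sub_total = _expr.evaluate(sub_bound, {i: values[i] for i in sub.item_ids})
        subscale_totals[sub.name] = int(sub_total) if float(sub_total).is_integer() else sub_total
    return InstrumentScore(
        instrument_id=instrument.id,
        total=total,
        band_label=band_label,
        band_action=band_action,
        subscale_totals=subscale_totals,
    )
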