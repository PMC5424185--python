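"""Align and compare repeated administrations (waves) of one questionnaire.

Descriptive only: joiners/leavers, tie turnover, and risk-band transitions.
No smoothing and no influence-vs-selection inference — the module reports
what changed between two time points, not why.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .instruments import Instrument
from .networks import DegenerateNetworkError, NetworkError, OneModeNetwork
from .responses import ResponseSet, ScoredRecord

__all__ = [
    "NetworkDiff",
    "WaveAlignment",
    "WaveSeries",
    "align_waves",
    "diff_networks",
    "zone_transition_matrix",
]


@dataclass(frozen=True)
class WaveEntry:
    wave: str
    response_set: ResponseSet
    scored_records: tuple[ScoredRecord, ...] = ()
    networks: tuple[OneModeNetwork, ...] = ()


@dataclass(frozen=True)
class WaveSeries:
    questionnaire_id: str
    entries: tuple[WaveEntry, ...]

    def __post_init__(self):
        labels = [e.wave for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("wave labels must be unique")
        for e in self.entries:
            if e.response_set.questionnaire_id != self.questionnaire_id:
                raise ValueError(
                    f"wave {e.wave!r} belongs to questionnaire "
                    f"{e.response_set.questionnaire_id!r}, not {self.questionnaire_id!r}"
                )


@dataclass(frozen=True)
class WaveAlignment:
    persons: tuple[str, ...]  # union of person ids, sorted
    presence: pd.DataFrame  # index: person id; one boolean column per wave
    joiners: Mapping[str, tuple[str, ...]]  # wave -> persons absent in the previous wave
    leavers: Mapping[str, tuple[str, ...]]  # wave -> persons present previously, absent now


def align_waves(series: WaveSeries) -> WaveAlignment:
    """Union person index with per-wave presence flags and joiner/leaver sets."""
    if len(series.entries) < 2:
        raise ValueError("wave alignment needs at least 2 waves")
    per_wave = {
        e.wave: {r.person_id for r in e.response_set.responses} for e in series.entries
    }
    persons = tuple(sorted(set().union(*per_wave.values())))
    presence = pd.DataFrame(
        {wave: [p in ids for p in persons] for wave, ids in per_wave.items()},
        index=list(persons),
    )
    joiners: dict[str, tuple[str, ...]] = {}
    leavers: dict[str, tuple[str, ...]] = {}
    waves = [e.wave for e in series.entries]
    for prev, cur in zip(waves, waves[1:]):
        joiners[cur] = tuple(sorted(per_wave[cur] - per_wave[prev]))
        leavers[cur] = tuple(sorted(per_wave[prev] - per_wave[cur]))
    return WaveAlignment(persons=persons, presence=presence, joiners=joiners, leavers=leavers)


@dataclass(frozen=True)
class NetworkDiff:
    gained: tuple[tuple[str, str], ...]
    lost: tuple[tuple[str, str], ...]
    jaccard: float
    degree_deltas: Mapping[str, int]  # per common node: degree(b) - degree(a)

    def to_dict(self) -> dict:
        return {
            "gained": [list(e) for e in self.gained],
            "lost": [list(e) for e in self.lost],
            "jaccard": self.jaccard,
            "degree_deltas": dict(self.degree_deltas),
        }


def diff_networks(net_a: OneModeNetwork, net_b: OneModeNetwork) -> NetworkDiff:
    """Tie turnover between two waves of the same relation.

    Ties gained/lost and Jaccard stability |A∩B|/|A∪B| are computed over
    the common node set; two identical networks give Jaccard 1.0 with no
    turnover, and an edge set fully replaced gives 0.0.
    """
    if net_a.relation_label != net_b.relation_label:
        raise NetworkError(
            f"cannot diff networks of different relations "
            f"({net_a.relation_label!r} vs {net_b.relation_label!r})"
        )
    common = set(net_a.graph.nodes) & set(net_b.graph.nodes)
    if not common:
        raise DegenerateNetworkError("node sets are disjoint; tie stability is undefined")
    edges_a = {(u, v) for u, v in net_a.graph.edges if u in common and v in common}
    edges_b = {(u, v) for u, v in net_b.graph.edges if u in common and v in common}
    union = edges_a | edges_b
    jaccard = len(edges_a & edges_b) / len(union) if union else 1.0
    deg_a = dict(net_a.graph.degree(common))
    deg_b = dict(net_b.graph.degree(common))
    return NetworkDiff(
        gained=tuple(sorted(edges_b - edges_a)),
        lost=tuple(sorted(edges_a - edges_b)),
        jaccard=jaccard,
        degree_deltas={v: deg_b[v] - deg_a[v] for v in sorted(common)},
    )


def zone_transition_matrix(
    scores_a: Sequence[ScoredRecord],
    scores_b: Sequence[ScoredRecord],
    instrument: Instrument,
) -> pd.DataFrame:
    """Band × band counts of persons moving between risk zones across waves.

    Cell (i, j) counts persons in band i at the first wave and band j at the
    second.  Only persons scored in both waves enter the matrix; attrition
    is visible through :func:`align_waves`, not mixed into the counts.
    """
    if not instrument.bands:
        raise ValueError(f"instrument {instrument.id!r} has no bands")
    labels = [b.label for b in instrument.bands]

    def band_by_person(records: Sequence[ScoredRecord]) -> dict[str, str]:
        out = {}
        for rec in records:
            s = rec.score_for(instrument.id)
            if s is not None and s.band_label is not None:
                out[rec.person_id] = s.band_label
        return out

    bands_a = band_by_person(scores_a)
    bands_b = band_by_person(scores_b)
    if not bands_a or not bands_b:
        raise ValueError(f"instrument {instrument.id!r} is not scored in both waves")
    matrix = pd.DataFrame(0, index=labels, columns=labels)
    for person, band_a in bands_a.items():
        band_b = bands_b.get(person)
        if band_b is not None:
            matrix.loc[band_a, band_b] += 1
    return matrix
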