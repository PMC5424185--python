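"""Deterministic natural-language reports for individuals and groups.

Rendering is template-based: an editable phrase catalog with named slots
(``data/templates/phrases_en.json``) is filled from computed values, so the
same inputs always produce byte-identical text.  Prose is written for
health professionals with no network-analysis background: standings are
phrased by within-group quartiles ("among the highest in the group"), and
technical index names never appear in rendered text.  Every numeric claim
in the prose is mirrored in the section's structured payload.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from string import Template
from typing import Literal, Mapping, Sequence

import pandas as pd

from .instruments import Instrument, attainable_range
from .networks import OneModeNetwork
from .responses import ScoredRecord
from .sna import CentralityTable, GroupSummary, Partition, influencers_for, mediators_for

__all__ = ["ReportDocument", "ReportSection", "group_report", "individual_report"]


def _load_catalog(language: str = "en") -> dict[str, str]:
    path = resources.files("sociosurvey").joinpath(f"data/templates/phrases_{language}.json")
    catalog = json.loads(path.read_text(encoding="utf-8"))
    return {k: v for k, v in catalog.items() if not k.startswith("_")}


@dataclass(frozen=True)
class ReportSection:
    title: str
    text: str
    payload: Mapping[str, object]


@dataclass(frozen=True)
class ReportDocument:
    subject: str
    sections: tuple[ReportSection, ...]
    format: Literal["plain", "markdown", "html"] = "markdown"

    def render(self) -> str:
        if self.format == "plain":
            return "\n\n".join(f"{s.title}\n{s.text}" for s in self.sections) + "\n"
        if self.format == "markdown":
            parts = [f"# Report: {self.subject}"]
            parts += [f"## {s.title}\n\n{s.text}" for s in self.sections]
            return "\n\n".join(parts) + "\n"
        body = "\n".join(
            f"<section><h2>{s.title}</h2><p>{s.text}</p></section>" for s in self.sections
        )
        return f"<html><body><h1>Report: {self.subject}</h1>\n{body}\n</body></html>\n"

    def payloads(self) -> dict[str, Mapping[str, object]]:
        return {s.title: s.payload for s in self.sections}


def _fill(catalog: Mapping[str, str], key: str, **slots: object) -> str:
    return Template(catalog[key]).substitute({k: str(v) for k, v in slots.items()})


def _standing(catalog: Mapping[str, str], values: pd.Series, value: float) -> str:
    """Quartile standing phrase for a value within its network distribution."""
    q25, q50, q75 = values.quantile([0.25, 0.5, 0.75])
    if value >= q75:
        return catalog["quartile_top"]
    if value >= q50:
        return catalog["quartile_high"]
    if value >= q25:
        return catalog["quartile_mid"]
    return catalog["quartile_low"]


def _fmt(x: float, places: int = 2) -> str:
    return f"{x:.{places}f}"


def individual_report(
    person: str,
    scores: Sequence[ScoredRecord],
    network: OneModeNetwork,
    centralities: CentralityTable,
    partition: Partition,
    k: int = 3,
    instrument: Instrument | None = None,
    fmt: Literal["plain", "markdown", "html"] = "markdown",
    language: str = "en",
) -> ReportDocument:
    """Personal report: who the person is, their screening risk band with the
    recommended intervention, their place in the friendship network, their
    social standing, and the people best placed to reach or influence them."""
    catalog = _load_catalog(language)
    g = network.graph
    if person not in g:
        raise KeyError(f"person {person!r} not in network")
    record = next((r for r in scores if r.person_id == person), None)
    if record is None:
        raise KeyError(f"person {person!r} has no scored record")
    attrs = g.nodes[person]
    name = attrs.get("display_name", person)
    sections: list[ReportSection] = []

    # personal data
    if all(a in attrs for a in ("sex", "class", "school")):
        text = _fill(catalog, "personal_data", name=name, sex=attrs["sex"],
                     **{"class": attrs["class"]}, school=attrs["school"])
    else:
        text = _fill(catalog, "personal_data_minimal", name=name)
    sections.append(ReportSection("Personal data", text, {
        "person_id": person,
        "display_name": name,
        "attributes": {k_: v for k_, v in attrs.items()
                       if k_ in ("sex", "class", "school", "age")},
    }))

    # risk band
    score = record.score_for(instrument.id) if instrument is not None else (
        record.instrument_scores[0] if record.instrument_scores else None
    )
    if score is not None and score.band_label is not None and instrument is not None:
        _, max_total = attainable_range(instrument)
        text = _fill(catalog, "risk_band", name=name, band=score.band_label,
                     total=score.total, max=int(max_total), action=score.band_action)
        payload = {"total": score.total, "band": score.band_label,
                   "action": score.band_action, "max_total": max_total}
    else:
        text = _fill(catalog, "risk_missing", name=name)
        payload = {"total": None, "band": None}
    sections.append(ReportSection("Alcohol-use risk", text, payload))

    # friendship-network narrative
    named_by = g.in_degree(person) if network.directed else g.degree(person)
    names_out = g.out_degree(person) if network.directed else g.degree(person)
    if named_by == 0 and names_out == 0:
        text = _fill(catalog, "friendship_isolate", name=name, relation=network.relation_label)
    else:
        text = _fill(catalog, "friendship_named", name=name, relation=network.relation_label,
                     named_by=named_by, names_out=names_out)
    community = partition.labels[person]
    community_size = sum(1 for c in partition.labels.values() if c == community)
    if community_size > 1:
        text += " " + _fill(catalog, "friendship_community", name=name,
                            community_size=community_size)
    sections.append(ReportSection("Friendship network", text, {
        "named_by": named_by, "names_out": names_out,
        "community": community, "community_size": community_size,
    }))

    # consumption narrative
    if score is not None and score.band_label is not None:
        band_attr = f"{score.instrument_id}_band"
        peers = sum(
            1 for v, a in g.nodes(data=True)
            if v != person and a.get(band_attr) == score.band_label
        )
        text = _fill(catalog, "consumption_band_context", name=name, band=score.band_label,
                     band_peers=peers, n_total=g.number_of_nodes())
        payload = {"band": score.band_label, "band_peers": peers,
                   "n_total": g.number_of_nodes()}
    else:
        text = _fill(catalog, "consumption_no_band", name=name)
        payload = {"band": None}
    sections.append(ReportSection("Alcohol consumption habits", text, payload))

    # social measures with quartile standings
    table = centralities.table.set_index("node")
    row = table.loc[person]
    measures = {}
    lines = []
    for column, phrase_key in (("popularity", "measure_popularity"),
                               ("influence", "measure_influence"),
                               ("mediation", "measure_mediation")):
        standing = _standing(catalog, table[column], float(row[column]))
        lines.append(_fill(catalog, phrase_key, name=name, standing=standing))
        measures[column] = float(row[column])
    measures["popularity_raw"] = int(row["popularity_raw"])
    sections.append(ReportSection("Social measures", " ".join(lines), measures))

    # mediators and influencers
    display = {v: g.nodes[v].get("display_name", v) for v in g.nodes}
    mediators = mediators_for(network, person, k)
    if mediators:
        text = _fill(catalog, "mediators_intro", name=name,
                     names=", ".join(display[v] for v in mediators))
    else:
        text = _fill(catalog, "mediators_none", name=name)
    sections.append(ReportSection("Mediators", text, {"mediators": mediators}))
    influencers = influencers_for(network, person, k)
    if influencers:
        text = _fill(catalog, "influencers_intro", name=name,
                     names=", ".join(display[v] for v in influencers))
    else:
        text = _fill(catalog, "influencers_none", name=name)
    sections.append(ReportSection("Influencers", text, {"influencers": influencers}))

    return ReportDocument(subject=person, sections=tuple(sections), format=fmt)


def group_report(
    network: OneModeNetwork,
    summary: GroupSummary,
    partition: Partition,
    score_columns: Mapping[str, pd.Series] | None = None,
    fmt: Literal["plain", "markdown", "html"] = "markdown",
    language: str = "en",
) -> ReportDocument:
    """Group-level report: cohesion, reciprocation, friendship groups,
    drinking-score homophily, and pairwise correlations between instrument
    totals when several are available."""
    catalog = _load_catalog(language)
    sections: list[ReportSection] = []

    text = _fill(catalog, "group_overview", n_nodes=summary.n_nodes, n_edges=summary.n_edges,
                 density_pct=_fmt(100 * summary.density, 1))
    if summary.reciprocity is not None:
        text += " " + _fill(catalog, "group_reciprocity",
                            reciprocity_pct=_fmt(100 * summary.reciprocity, 1))
    sections.append(ReportSection("Group overview", text, {
        "n_nodes": summary.n_nodes, "n_edges": summary.n_edges,
        "density": summary.density, "reciprocity": summary.reciprocity,
        "mean_in_degree": summary.mean_in_degree,
    }))

    sizes = partition.community_sizes()
    text = _fill(catalog, "group_communities", n_communities=partition.n_communities,
                 sizes=", ".join(str(s) for s in sizes))
    sections.append(ReportSection("Friendship groups", text, {
        "n_communities": partition.n_communities, "sizes": sizes,
    }))

    a = summary.score_assortativity
    if a is None:
        text = catalog["group_assortativity_none"]
    elif a >= 0:
        text = _fill(catalog, "group_assortativity_pos", assortativity=_fmt(a))
    else:
        text = _fill(catalog, "group_assortativity_neg", assortativity=_fmt(a))
    sections.append(ReportSection("Consumption and relationships", text,
                                  {"score_assortativity": a}))

    if score_columns and len(score_columns) >= 2:
        names = sorted(score_columns)
        lines, corr_payload = [], {}
        for i, na in enumerate(names):
            for nb in names[i + 1:]:
                paired = pd.concat([score_columns[na], score_columns[nb]], axis=1).dropna()
                if len(paired) < 2 or paired.iloc[:, 0].std() == 0 or paired.iloc[:, 1].std() == 0:
                    continue
                r = float(paired.iloc[:, 0].corr(paired.iloc[:, 1]))
                lines.append(_fill(catalog, "group_correlation", a=na, b=nb, r=_fmt(r)))
                corr_payload[f"{na}~{nb}"] = r
        if lines:
            sections.append(ReportSection("Score correlations", " ".join(lines), corr_payload))

    subject = f"group:{network.relation_label}:{network.wave}"
    return ReportDocument(subject=subject, sections=tuple(sections), format=fmt)
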