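"""Build one-mode and two-mode social networks from sociometric responses.

Edge direction convention: ego → alter (the namer points to the named), so
"popularity" is in-degree.  One-mode networks are directed weighted graphs
over a single roster (square adjacency matrix); two-mode networks are
bipartite person→entity incidence structures (rectangular matrix), e.g.
students × the venues where they drink.  Isolates are retained throughout —
a student naming no one is a finding, not missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import networkx as nx
import pandas as pd

from .responses import ResponseSet
from .survey import Roster, SchemaError, SociometricTemplate, parse_generated_item_id

__all__ = [
    "DegenerateNetworkError",
    "NetworkError",
    "OneModeNetwork",
    "TieRecord",
    "TwoModeNetwork",
    "adjacency_matrix",
    "build_one_mode",
    "build_two_mode",
    "extract_ties",
    "filter_by_level",
    "from_adjacency_matrix",
    "from_incidence_matrix",
    "incidence_matrix",
    "project_persons",
    "reciprocity",
    "symmetrize",
]


class NetworkError(ValueError):
    pass


class DegenerateNetworkError(NetworkError):
    """A quantity is undefined on this network (e.g. no edges)."""


@dataclass(frozen=True)
class TieRecord:
    ego_id: str
    alter_id: str
    relation_label: str
    weight: float
    wave: str = "wave1"


@dataclass
class OneModeNetwork:
    """Directed weighted person-to-person network with node attributes."""

    graph: nx.DiGraph | nx.Graph
    relation_label: str
    wave: str = "wave1"

    @property
    def directed(self) -> bool:
        return self.graph.is_directed()

    @property
    def node_ids(self) -> list[str]:
        return list(self.graph.nodes)

    def copy(self) -> "OneModeNetwork":
        return OneModeNetwork(self.graph.copy(), self.relation_label, self.wave)


@dataclass
class TwoModeNetwork:
    """Bipartite person→entity incidence network."""

    graph: nx.Graph
    person_ids: tuple[str, ...]
    entity_ids: tuple[str, ...]
    relation_label: str
    wave: str = "wave1"


def extract_ties(
    rs: ResponseSet,
    template: SociometricTemplate,
    questionnaire=None,
) -> list[TieRecord]:
    """One tie per answered generated item whose level is above "no relation".

    The tie weight is the chosen scale level's weight; a zero-weight
    (absent-level) or unanswered item records no tie.
    """
    if questionnaire is not None and template.id not in {t.id for t in questionnaire.templates}:
        raise SchemaError(f"template {template.id!r} is not part of questionnaire {questionnaire.id!r}")
    ties: list[TieRecord] = []
    for resp in rs.responses:
        for item_id, code in resp.answers.items():
            gen = parse_generated_item_id(item_id)
            if gen is None or gen[0] != template.id:
                continue
            weight = template.scale.weight_of(code)
            if weight <= 0:
                continue
            ties.append(
                TieRecord(
                    ego_id=resp.person_id,
                    alter_id=gen[1],
                    relation_label=template.relation_label,
                    weight=weight,
                    wave=resp.wave,
                )
            )
    return ties


def build_one_mode(
    ties: Sequence[TieRecord],
    roster: Roster,
    attributes: Mapping[str, Mapping[str, object]] | None = None,
    relation_label: str = "friendship",
    wave: str = "wave1",
) -> OneModeNetwork:
    """Directed network over the full roster; isolates preserved.

    ``attributes`` maps person id to a per-node attribute dict (sex, class,
    instrument totals, band labels, ...), attached to the nodes so exports
    and reports can use them.
    """
    g = nx.DiGraph()
    for p in roster.members:
        attrs = dict(p.attributes)
        attrs["display_name"] = p.display_name
        if attributes and p.id in attributes:
            attrs.update(attributes[p.id])
        g.add_node(p.id, **attrs)
    for t in ties:
        if t.ego_id not in g or t.alter_id not in g:
            raise NetworkError(f"tie {t.ego_id!r}->{t.alter_id!r} references a person not on the roster")
        if t.ego_id == t.alter_id:
            raise NetworkError(f"self-tie for person {t.ego_id!r} in a one-mode relation")
        if g.has_edge(t.ego_id, t.alter_id):
            raise NetworkError(f"duplicate tie {t.ego_id!r}->{t.alter_id!r}")
        g.add_edge(t.ego_id, t.alter_id, weight=float(t.weight))
    return OneModeNetwork(graph=g, relation_label=relation_label, wave=wave)


def filter_by_level(net: OneModeNetwork, min_weight: float) -> OneModeNetwork:
    """Keep ties at or above a relationship level; all nodes stay."""
    out = net.copy()
    drop = [(u, v) for u, v, w in out.graph.edges(data="weight") if w < min_weight]
    out.graph.remove_edges_from(drop)
    return out


def symmetrize(
    net: OneModeNetwork,
    rule: Literal["mutual", "any"] = "mutual",
    weight_rule: Literal["min", "max"] = "min",
) -> OneModeNetwork:
    """Directed → undirected.

    ``mutual``: an undirected edge only where both directions were named
    (friendship claims confirmed by both sides); ``any``: where either was.
    The undirected weight is the min or max of the available directions.
    """
    if not net.directed:
        return net.copy()
    g = net.graph
    u = nx.Graph()
    u.add_nodes_from(g.nodes(data=True))
    agg = min if weight_rule == "min" else max
    for a, b, w in g.edges(data="weight", default=1.0):
        if u.has_edge(a, b):
            continue
        back = g.has_edge(b, a)
        if rule == "mutual":
            if back:
                u.add_edge(a, b, weight=agg(w, g[b][a].get("weight", 1.0)))
        elif rule == "any":
            weights = [w] + ([g[b][a].get("weight", 1.0)] if back else [])
            u.add_edge(a, b, weight=agg(weights))
        else:
            raise NetworkError(f"unknown symmetrization rule {rule!r}")
    return OneModeNetwork(graph=u, relation_label=net.relation_label, wave=net.wave)


def reciprocity(net: OneModeNetwork) -> float:
    """Fraction of directed ties returned by the named party."""
    g = net.graph
    if not net.directed:
        raise NetworkError("reciprocity is defined on directed networks")
    m = g.number_of_edges()
    if m == 0:
        raise DegenerateNetworkError("reciprocity is undefined on an edgeless network")
    mutual = sum(1 for a, b in g.edges if g.has_edge(b, a))
    return mutual / m


def build_two_mode(
    ties: Sequence[TieRecord],
    person_roster: Roster,
    entity_roster: Roster,
    relation_label: str = "affiliation",
    wave: str = "wave1",
) -> TwoModeNetwork:
    g = nx.Graph()
    for p in person_roster.members:
        g.add_node(p.id, bipartite=0, display_name=p.display_name, **dict(p.attributes))
    for e in entity_roster.members:
        if g.has_node(e.id):
            raise NetworkError(f"id {e.id!r} appears in both the person and entity rosters")
        g.add_node(e.id, bipartite=1, display_name=e.display_name, **dict(e.attributes))
    persons = {p.id for p in person_roster.members}
    entities = {e.id for e in entity_roster.members}
    for t in ties:
        if t.ego_id not in persons or t.alter_id not in entities:
            raise NetworkError(
                f"incidence tie {t.ego_id!r}->{t.alter_id!r} must run person -> entity"
            )
        g.add_edge(t.ego_id, t.alter_id, weight=float(t.weight))
    return TwoModeNetwork(
        graph=g,
        person_ids=tuple(p.id for p in person_roster.members),
        entity_ids=tuple(e.id for e in entity_roster.members),
        relation_label=relation_label,
        wave=wave,
    )


def project_persons(net: TwoModeNetwork) -> OneModeNetwork:
    """Co-affiliation projection: persons linked by shared entities, with
    co-membership count weights.  Convenience, undirected."""
    g = nx.Graph()
    for pid in net.person_ids:
        g.add_node(pid, **net.graph.nodes[pid])
    for i, a in enumerate(net.person_ids):
        for b in net.person_ids[i + 1:]:
            shared = set(net.graph[a]) & set(net.graph[b])
            if shared:
                g.add_edge(a, b, weight=float(len(shared)))
    return OneModeNetwork(graph=g, relation_label=f"co-{net.relation_label}", wave=net.wave)


# ---------------------------------------------------------------------------
# Matrix interchange


def adjacency_matrix(net: OneModeNetwork) -> pd.DataFrame:
    """Square weighted adjacency matrix with person-id headers."""
    ids = net.node_ids
    return pd.DataFrame(
        nx.to_numpy_array(net.graph, nodelist=ids, weight="weight"), index=ids, columns=ids
    )


def from_adjacency_matrix(
    matrix: pd.DataFrame, relation_label: str = "friendship", wave: str = "wave1", directed: bool = True
) -> OneModeNetwork:
    if list(matrix.index) != list(matrix.columns):
        raise NetworkError("adjacency matrix must be square with matching id headers")
    g: nx.DiGraph | nx.Graph = nx.DiGraph() if directed else nx.Graph()
    g.add_nodes_from(str(i) for i in matrix.index)
    for a in matrix.index:
        for b in matrix.columns:
            w = float(matrix.loc[a, b])
            if a != b and w != 0:
                g.add_edge(str(a), str(b), weight=w)
    return OneModeNetwork(graph=g, relation_label=relation_label, wave=wave)


def incidence_matrix(net: TwoModeNetwork) -> pd.DataFrame:
    """Rectangular person × entity incidence matrix."""
    data = [
        [net.graph[p][e]["weight"] if net.graph.has_edge(p, e) else 0.0 for e in net.entity_ids]
        for p in net.person_ids
    ]
    return pd.DataFrame(data, index=list(net.person_ids), columns=list(net.entity_ids))


def from_incidence_matrix(
    matrix: pd.DataFrame, relation_label: str = "affiliation", wave: str = "wave1"
) -> TwoModeNetwork:
    g = nx.Graph()
    persons = tuple(str(i) for i in matrix.index)
    entities = tuple(str(c) for c in matrix.columns)
    for p in persons:
        g.add_node(p, bipartite=0)
    for e in entities:
        g.add_node(e, bipartite=1)
    for p in matrix.index:
        for e in matrix.columns:
            w = float(matrix.loc[p, e])
            if w != 0:
                g.add_edge(str(p), str(e), weight=w)
    return TwoModeNetwork(
        graph=g, person_ids=persons, entity_ids=entities, relation_label=relation_label, wave=wave
    )
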