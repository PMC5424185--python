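from __future__ import annotations

import networkx as nx
import pytest

from sociosurvey.instruments import load_bundled_instrument
from sociosurvey.networks import OneModeNetwork
from sociosurvey.survey import (
    DEFAULT_TIE_SCALE,
    Person,
    Roster,
    SociometricTemplate,
    compose_questionnaire,
)


@pytest.fixture(scope="session")
def audit():
    return load_bundled_instrument("audit")


@pytest.fixture(scope="session")
def kidscreen():
    return load_bundled_instrument("kidscreen27")


def make_roster(n: int, roster_id: str = "class") -> Roster:
    members = tuple(
        Person(id=f"p{i}", display_name=f"Person {i}", attributes={"sex": "F" if i % 2 else "M"})
        for i in range(1, n + 1)
    )
    return Roster(id=roster_id, members=members)


@pytest.fixture
def roster10():
    return make_roster(10)


@pytest.fixture
def friend_template():
    return SociometricTemplate(
        id="friend",
        prompt="How is your relationship with {alter}?",
        relation_label="friendship",
        mode="one_mode",
        roster_ref="class",
        scale=DEFAULT_TIE_SCALE,
    )


@pytest.fixture
def questionnaire10(audit, roster10, friend_template):
    return compose_questionnaire(
        blocks=[audit, friend_template],
        metadata={"id": "study", "type": "test", "description": ""},
        rosters={"class": roster10},
    )


def net_from_edges(edges, nodes=None, directed=True, relation="friendship") -> OneModeNetwork:
    g = nx.DiGraph() if directed else nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for e in edges:
        if len(e) == 3:
            g.add_edge(e[0], e[1], weight=float(e[2]))
        else:
            g.add_edge(e[0], e[1], weight=1.0)
    return OneModeNetwork(graph=g, relation_label=relation)


@pytest.fixture
def two_clique_bridge():
    """Two 4-cliques joined by one bridge edge; modularity optimum is the
    two-clique split."""
    g = nx.Graph()
    for block in (["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]):
        for i, u in enumerate(block):
            for v in block[i + 1:]:
                g.add_edge(u, v, weight=1.0)
    g.add_edge("a1", "b1", weight=1.0)
    return OneModeNetwork(graph=g, relation_label="friendship")
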