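"""Graph interchange: GEXF (Gephi-native) and GraphML export.

GEXF 1.2 is the primary export because Gephi consumes it directly (and
browser renderers in the SigmaJS family read it too); GraphML is the
portability fallback.  Node attributes (sex, class, school, instrument
totals, band labels, community, centralities) are declared with proper
types — numbers as numeric attributes, labels as strings — and direction
is preserved.

Visual conventions the study's displays use, for consumers that want to
reproduce them: node size ∝ the alcohol-screening total (bigger circles
mean higher consumption risk) and node color keyed to sex (light grey for
girls, dark grey for boys).  These are documented here, not baked into the
files: layout and styling belong to the consuming tool.
"""

from __future__ import annotations

import re
from pathlib import Path

import networkx as nx

from .networks import NetworkError, OneModeNetwork, TwoModeNetwork

__all__ = ["export_gexf", "export_graphml", "import_gexf", "import_graphml"]

# fixed timestamp so identical networks export byte-identically across runs
_GEXF_DATE = 'lastmodifieddate="1970-01-01"'


def _prepare(net: OneModeNetwork | TwoModeNetwork) -> nx.Graph | nx.DiGraph:
    g = net.graph.copy()
    reserved = {"id", "label", "pid"}
    for _, attrs in g.nodes(data=True):
        collisions = reserved & set(attrs)
        if collisions:
            raise NetworkError(f"node attribute names collide with reserved keys: {sorted(collisions)}")
        for k, v in list(attrs.items()):
            if v is None:
                del attrs[k]
    g.graph["relation"] = net.relation_label
    g.graph["wave"] = net.wave
    return g


def export_gexf(net: OneModeNetwork | TwoModeNetwork, path: str | Path) -> Path:
    """Write GEXF 1.2 with a declared attribute schema; returns the path."""
    g = _prepare(net)
    lines = list(nx.generate_gexf(g, version="1.2draft"))
    text = "\n".join(
        re.sub(r'lastmodifieddate="[^"]*"', _GEXF_DATE, line) for line in lines
    )
    path = Path(path)
    path.write_text(text + "\n", encoding="utf-8")
    return path


def export_graphml(net: OneModeNetwork | TwoModeNetwork, path: str | Path) -> Path:
    """Write GraphML with key declarations for every node attribute."""
    g = _prepare(net)
    path = Path(path)
    text = "\n".join(nx.generate_graphml(g, named_key_ids=True))
    path.write_text(text + "\n", encoding="utf-8")
    return path


def import_gexf(path: str | Path, relation_label: str = "", wave: str = "wave1") -> OneModeNetwork:
    g = nx.read_gexf(path)
    return OneModeNetwork(
        graph=g,
        relation_label=relation_label or g.graph.get("relation", ""),
        wave=g.graph.get("wave", wave),
    )


def import_graphml(path: str | Path, relation_label: str = "", wave: str = "wave1") -> OneModeNetwork:
    g = nx.read_graphml(path)
    return OneModeNetwork(
        graph=g,
        relation_label=relation_label or g.graph.get("relation", ""),
        wave=g.graph.get("wave", wave),
    )
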