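"""Individual and group social metrics: popularity, mediation, influence,
communities, and homophily summaries.

Terminology used in the rest of the package and in rendered reports maps to
standard network indices as follows:

* **popularity** — in-degree: how many peers name the individual (raw and
  normalized by n−1).
* **mediation** — shortest-path betweenness (Brandes accumulation):
  how often the individual sits on geodesics between others.
* **influence** — a damped random-surfer score computed on *reversed*
  name-edges, damping 0.85: a person named by many (especially by
  well-connected namers) scores high.  Scores are normalized to sum to 1.
* **communities** — two-phase Louvain modularity maximization at
  resolution 1.0.

Geodesics are unweighted: tie weights encode relationship *strength*, not
distance, so path length is counted in hops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .networks import DegenerateNetworkError, OneModeNetwork, reciprocity, symmetrize

__all__ = [
    "CentralityTable",
    "Partition",
    "attach_metrics",
    "detect_communities",
    "group_summary",
    "influence",
    "influencers_for",
    "mediation",
    "mediators_for",
    "popularity",
]

logger = logging.getLogger(__name__)

INFLUENCE_DAMPING = 0.85
INFLUENCE_TOL = 1e-9


@dataclass(frozen=True)
class CentralityTable:
    """Per-node popularity/mediation/influence, as a tidy DataFrame."""

    table: pd.DataFrame  # index: node id; columns: popularity_raw, popularity, mediation, influence
    network_id: str
    wave: str

    def ranked(self, column: str) -> list[str]:
        """Node ids best-first; ties broken by node id for determinism."""
        df = self.table.sort_values([column, "node"], ascending=[False, True], kind="mergesort")
        return list(df["node"])


@dataclass(frozen=True)
class Partition:
    labels: Mapping[str, int]
    q: float

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    def community_sizes(self) -> list[int]:
        sizes: dict[int, int] = {}
        for c in self.labels.values():
            sizes[c] = sizes.get(c, 0) + 1
        return sorted(sizes.values(), reverse=True)


def popularity(net: OneModeNetwork) -> pd.DataFrame:
    """Raw in-degree and in-degree/(n−1) per node."""
    g = net.graph
    n = g.number_of_nodes()
    degree = g.in_degree() if net.directed else g.degree()
    rows = [
        {"node": v, "popularity_raw": d, "popularity": (d / (n - 1)) if n > 1 else 0.0}
        for v, d in degree
    ]
    return pd.DataFrame(rows).sort_values("node", kind="mergesort").reset_index(drop=True)


def mediation(net: OneModeNetwork) -> pd.DataFrame:
    """Shortest-path betweenness, raw and normalized.

    Normalization divides by (n−1)(n−2) for directed networks and half that
    for undirected; unreachable pairs contribute nothing.
    """
    g = net.graph
    n = g.number_of_nodes()
    if n < 3:
        raw = {v: 0.0 for v in g}
    else:
        raw = nx.betweenness_centrality(g, normalized=False, weight=None)
    denom = (n - 1) * (n - 2) if net.directed else (n - 1) * (n - 2) / 2
    rows = [
        {"node": v, "mediation_raw": r, "mediation": (r / denom) if n >= 3 else 0.0}
        for v, r in raw.items()
    ]
    return pd.DataFrame(rows).sort_values("node", kind="mergesort").reset_index(drop=True)


def influence(net: OneModeNetwork) -> pd.DataFrame:
    """Damped random-surfer scores on reversed name-edges, summing to 1."""
    g = net.graph
    if g.number_of_edges() == 0:
        raise DegenerateNetworkError("influence is undefined on an edgeless network")
    reversed_g = g.reverse() if net.directed else g
    scores = nx.pagerank(
        reversed_g, alpha=INFLUENCE_DAMPING, tol=INFLUENCE_TOL, max_iter=1000, weight="weight"
    )
    total = sum(scores.values())
    rows = [{"node": v, "influence": s / total} for v, s in scores.items()]
    return pd.DataFrame(rows).sort_values("node", kind="mergesort").reset_index(drop=True)


def centrality_table(net: OneModeNetwork, network_id: str = "") -> CentralityTable:
    pop = popularity(net)
    med = mediation(net)
    try:
        infl = influence(net)
    except DegenerateNetworkError:
        infl = pd.DataFrame({"node": pop["node"], "influence": 0.0})
    df = pop.merge(med, on="node").merge(infl, on="node")
    return CentralityTable(table=df, network_id=network_id or net.relation_label, wave=net.wave)


def detect_communities(net: OneModeNetwork, seed: int = 0) -> Partition:
    """Two-phase Louvain modularity maximization (resolution 1.0).

    Directed inputs are symmetrized with rule ``any`` (weight max) first,
    and that coercion is logged.  An edgeless network yields singleton
    communities with Q = 0.
    """
    work = net
    if net.directed:
        logger.info("symmetrizing directed network %r (rule=any, weight=max) for community detection",
                    net.relation_label)
        work = symmetrize(net, rule="any", weight_rule="max")
    g = work.graph
    if g.number_of_edges() == 0:
        return Partition(labels={v: i for i, v in enumerate(sorted(g.nodes))}, q=0.0)
    communities = nx.community.louvain_communities(g, weight="weight", resolution=1.0, seed=seed)
    labels = {v: i for i, comm in enumerate(sorted(communities, key=min)) for v in comm}
    q = nx.community.modularity(g, communities, weight="weight", resolution=1.0)
    return Partition(labels=labels, q=q)


def influencers_for(net: OneModeNetwork, person: str, k: int = 3) -> list[str]:
    """Top-k of the ego's named alters by global influence score."""
    g = net.graph
    if person not in g:
        raise KeyError(f"person {person!r} not in network")
    neighbors = list(g.successors(person)) if net.directed else list(g.neighbors(person))
    if not neighbors:
        return []
    scores = influence(net).set_index("node")["influence"]
    ranked = sorted(neighbors, key=lambda v: (-scores.get(v, 0.0), v))
    return ranked[:k]


def _bfs_counts(g: nx.DiGraph | nx.Graph, source: str, reverse: bool = False):
    """Distances and geodesic counts from source (or *to* source if reverse)."""
    neigh = (g.predecessors if (reverse and g.is_directed()) else
             g.successors if g.is_directed() else g.neighbors)
    dist = {source: 0}
    sigma = {source: 1}
    queue = [source]
    while queue:
        nxt = []
        for u in queue:
            for v in neigh(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    sigma[v] = 0
                    nxt.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
        queue = nxt
    return dist, sigma


def mediators_for(net: OneModeNetwork, person: str, k: int = 3) -> list[str]:
    """Top-k nodes by ego-targeted betweenness.

    A candidate's score is the number of geodesics ending at the ego that
    pass through it, summed over all sources; the ego itself and path
    endpoints are excluded.
    """
    g = net.graph
    if person not in g:
        raise KeyError(f"person {person!r} not in network")
    dist_to_ego, sigma_to_ego = _bfs_counts(g, person, reverse=True)
    scores: dict[str, float] = {}
    for source in g:
        if source == person or source not in dist_to_ego:
            continue
        dist_from_s, sigma_from_s = _bfs_counts(g, source)
        if person not in dist_from_s:
            continue
        d_total = dist_from_s[person]
        for v in g:
            if v in (person, source):
                continue
            if (v in dist_from_s and v in dist_to_ego
                    and dist_from_s[v] + dist_to_ego[v] == d_total):
                scores[v] = scores.get(v, 0.0) + sigma_from_s[v] * sigma_to_ego[v]
    ranked = sorted((v for v, s in scores.items() if s > 0), key=lambda v: (-scores[v], v))
    return ranked[:k]


@dataclass(frozen=True)
class GroupSummary:
    n_nodes: int
    n_edges: int
    density: float
    reciprocity: float | None
    mean_in_degree: float
    n_communities: int
    modularity: float
    score_assortativity: float | None

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "reciprocity": self.reciprocity,
            "mean_in_degree": self.mean_in_degree,
            "n_communities": self.n_communities,
            "modularity": self.modularity,
            "score_assortativity": self.score_assortativity,
        }


def score_assortativity(net: OneModeNetwork, score_attr: str) -> float | None:
    """Pearson correlation of a node score across symmetrized edges.

    The homophily statistic: positive values mean ties tend to connect
    individuals with similar scores.  None when undefined (no edges with
    scores on both endpoints, or zero variance).
    """
    und = symmetrize(net, rule="any", weight_rule="max") if net.directed else net
    xs, ys = [], []
    for a, b in und.graph.edges:
        xa = und.graph.nodes[a].get(score_attr)
        xb = und.graph.nodes[b].get(score_attr)
        if xa is None or xb is None:
            continue
        xs.extend([float(xa), float(xb)])
        ys.extend([float(xb), float(xa)])
    if not xs:
        return None
    xs_a, ys_a = np.asarray(xs), np.asarray(ys)
    if xs_a.std() == 0 or ys_a.std() == 0:
        # all endpoint scores identical: ties connect only same-scored people
        return 1.0 if np.allclose(xs_a, ys_a) else None
    return float(np.corrcoef(xs_a, ys_a)[0, 1])


def group_summary(
    net: OneModeNetwork,
    score_attr: str = "audit_total",
    seed: int = 0,
) -> GroupSummary:
    """Network-level description: density, reciprocity, mean in-degree,
    communities, and score homophily."""
    g = net.graph
    n = g.number_of_nodes()
    if n < 2:
        raise DegenerateNetworkError("group summary needs at least 2 people")
    m = g.number_of_edges()
    possible = n * (n - 1) if net.directed else n * (n - 1) / 2
    try:
        recip = reciprocity(net) if net.directed else None
    except DegenerateNetworkError:
        recip = None
    partition = detect_communities(net, seed=seed)
    mean_in = m / n if net.directed else 2 * m / n
    return GroupSummary(
        n_nodes=n,
        n_edges=m,
        density=m / possible,
        reciprocity=recip,
        mean_in_degree=mean_in,
        n_communities=partition.n_communities,
        modularity=partition.q,
        score_assortativity=score_assortativity(net, score_attr),
    )


def attach_metrics(net: OneModeNetwork, seed: int = 0) -> tuple[CentralityTable, Partition]:
    """Compute centralities and communities and attach them as node attributes."""
    table = centrality_table(net)
    partition = detect_communities(net, seed=seed)
    indexed = table.table.set_index("node")
    for v in net.graph.nodes:
        net.graph.nodes[v]["popularity"] = float(indexed.loc[v, "popularity"])
        net.graph.nodes[v]["popularity_raw"] = int(indexed.loc[v, "popularity_raw"])
        net.graph.nodes[v]["mediation"] = float(indexed.loc[v, "mediation"])
        net.graph.nodes[v]["influence"] = float(indexed.loc[v, "influence"])
        net.graph.nodes[v]["community"] = int(partition.labels[v])
    return table, partition
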