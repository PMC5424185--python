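"""Independent brute-force oracles used to check the network metrics.

Everything here is written for clarity at tiny n, not speed, and stays
independent of the implementation paths it checks: betweenness by explicit
path enumeration, modularity by exhaustive search over all set partitions,
and influence by a scripted power iteration.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import networkx as nx
import numpy as np


def brute_in_degrees(g: nx.DiGraph) -> dict:
    """Count incident edges per target by scanning the edge list."""
    counts = {v: 0 for v in g}
    for _, v in g.edges:
        counts[v] += 1
    return counts


def brute_betweenness(g) -> dict:
    """Raw betweenness by enumerating all simple paths per ordered pair,
    keeping the shortest, and crediting intermediate nodes fractionally."""
    score = {v: 0.0 for v in g}
    for s, t in itertools.permutations(g.nodes, 2):
        if not g.is_directed() and s > t:
            continue  # count each unordered pair once for undirected graphs
        paths = list(nx.all_simple_paths(g, s, t))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        for p in geodesics:
            for v in p[1:-1]:
                score[v] += 1.0 / len(geodesics)
    return score


def brute_reciprocity(g: nx.DiGraph) -> float:
    edges = list(g.edges)
    returned = sum(1 for a, b in edges if (b, a) in set(edges))
    return returned / len(edges)


def brute_symmetrize_mutual(g: nx.DiGraph) -> set:
    out = set()
    for a, b in itertools.combinations(sorted(g.nodes), 2):
        if g.has_edge(a, b) and g.has_edge(b, a):
            out.add((a, b))
    return out


def brute_symmetrize_any(g: nx.DiGraph) -> set:
    out = set()
    for a, b in itertools.combinations(sorted(g.nodes), 2):
        if g.has_edge(a, b) or g.has_edge(b, a):
            out.add((a, b))
    return out


@lru_cache(maxsize=None)
def set_partitions(n: int) -> tuple[tuple[int, ...], ...]:
    """All set partitions of range(n) as restricted-growth label strings."""
    results: list[tuple[int, ...]] = []

    def grow(labels: list[int], next_label: int):
        if len(labels) == n:
            results.append(tuple(labels))
            return
        for lab in range(next_label + 1):
            grow(labels + [lab], max(next_label, lab + 1))

    grow([0], 1)
    return tuple(results)


def modularity_of(g: nx.Graph, labels: dict) -> float:
    """Newman modularity evaluated directly from its definition."""
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    deg = dict(g.degree())
    for u, v in itertools.combinations_with_replacement(sorted(g.nodes), 2):
        if labels[u] != labels[v]:
            continue
        a = 1.0 if g.has_edge(u, v) else 0.0
        expected = deg[u] * deg[v] / (2 * m)
        factor = 1.0 if u == v else 2.0
        q += factor * (a - expected) / (2 * m)
    return q


def exhaustive_max_modularity(g: nx.Graph) -> tuple[float, dict]:
    """Search every partition of the nodes; vectorized over partitions."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    m = g.number_of_edges()
    if m == 0:
        return 0.0, {v: i for i, v in enumerate(nodes)}
    deg = a.sum(axis=1)
    parts = np.array(set_partitions(n))  # (P, n)
    same = parts[:, :, None] == parts[:, None, :]  # (P, n, n)
    within = (same * a).sum(axis=(1, 2)) / 2.0
    deg_outer = np.outer(deg, deg)
    deg_term = (same * deg_outer).sum(axis=(1, 2))
    q = within / m - deg_term / (4.0 * m * m)
    best = int(q.argmax())
    labels = {v: int(parts[best, i]) for i, v in enumerate(nodes)}
    return float(q[best]), labels


def power_iteration_influence(g: nx.DiGraph, damping: float = 0.85,
                              tol: float = 1e-12, weight: str = "weight") -> dict:
    """Random-surfer scores on the reversed graph via an explicit loop."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    # surfer walks along reversed edges: from alter back to the ego who named them
    w = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        w[idx[v], idx[u]] += data.get(weight, 1.0)
    row_sums = w.sum(axis=1)
    x = np.full(n, 1.0 / n)
    for _ in range(10000):
        nxt = np.full(n, (1.0 - damping) / n)
        for i in range(n):
            if row_sums[i] == 0:
                nxt += damping * x[i] / n  # dangling: uniform teleport
            else:
                nxt += damping * x[i] * w[i] / row_sums[i]
        if np.abs(nxt - x).max() < tol:
            x = nxt
            break
        x = nxt
    x = x / x.sum()
    return {v: float(x[idx[v]]) for v in nodes}


def random_connected_digraph(rng: np.random.Generator, n: int, p: float) -> nx.DiGraph:
    """Random directed graph whose underlying undirected graph is connected."""
    while True:
        g = nx.DiGraph()
        g.add_nodes_from(range(n))
        for a, b in itertools.permutations(range(n), 2):
            if rng.random() < p:
                g.add_edge(a, b, weight=float(rng.integers(1, 4)))
        if g.number_of_edges() and nx.is_connected(g.to_undirected()):
            return g
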