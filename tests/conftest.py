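"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive re-implementations (recursive path
enumeration, dense power iteration, exhaustive shortest-path counting,
combinatorial hypergeometric tails) used only to check the package's
optimised paths; they never share code with the implementation.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from tfcascade.config import SimulationConfig


# ---------------------------------------------------------------- oracles

def brute_force_maximal_paths(graph: nx.DiGraph) -> set[tuple[str, ...]]:
    """All maximal simple directed paths from in-degree-0 nodes, recursively."""
    out: set[tuple[str, ...]] = set()

    def extend(path: list) -> None:
        nxt = [v for v in graph.successors(path[-1]) if v not in path]
        if not nxt:
            if len(path) >= 2:
                out.add(tuple(path))
            return
        for v in nxt:
            extend(path + [v])

    for node in graph.nodes:
        if graph.in_degree(node) == 0:
            extend([node])
    return out


def power_iteration_pagerank(graph: nx.DiGraph, damping: float = 0.85,
                             iterations: int = 10,
                             init: float = 0.25) -> dict:
    """Dense-matrix fixed-iteration PageRank with uniform dangling spread."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for u in nodes:
        succ = list(graph.successors(u))
        if succ:
            for v in succ:
                M[idx[v], idx[u]] = 1.0 / len(succ)
        else:
            M[:, idx[u]] = 1.0 / n
    x = np.full(n, float(init))
    for _ in range(iterations):
        x = (1 - damping) / n + damping * (M @ x)
    x = x / x.sum()
    return {v: x[idx[v]] for v in nodes}


def brute_force_betweenness(graph: nx.DiGraph) -> dict:
    """Normalised directed betweenness by explicit shortest-path enumeration."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.permutations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            score[v] += through / len(paths)
    scale = 1.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
    return {v: score[v] * scale for v in nodes}


def brute_force_closeness_wf(graph: nx.Graph) -> dict:
    """Undirected closeness with the Wasserman-Faust component correction."""
    out = {}
    n = graph.number_of_nodes()
    for v in graph.nodes:
        dist = nx.single_source_shortest_path_length(graph, v)
        reach = len(dist) - 1
        total = sum(dist.values())
        if total > 0 and n > 1:
            out[v] = (reach / total) * (reach / (n - 1))
        else:
            out[v] = 0.0
    return out


def dense_leading_eigenvector(graph: nx.Graph) -> np.ndarray:
    """|leading eigenvector| of the undirected adjacency at unit 2-norm."""
    nodes = sorted(graph.nodes)
    A = nx.to_numpy_array(graph, nodelist=nodes)
    vals, vecs = np.linalg.eigh(A)
    v = np.abs(vecs[:, np.argmax(vals)])
    return v / np.linalg.norm(v)


def hypergeom_tail_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n) as an exact rational."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, x) * math.comb(N - K, n - x), total)
    return acc


def random_dag(n_nodes: int, edge_prob: float, rng: np.random.Generator) -> nx.DiGraph:
    """Random DAG: edges only forward along a random topological order."""
    order = rng.permutation(n_nodes)
    g = nx.DiGraph()
    g.add_nodes_from(f"N{i}" for i in range(n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                g.add_edge(f"N{order[i]}", f"N{order[j]}")
    g.remove_nodes_from([v for v in list(g.nodes) if g.degree(v) == 0])
    return g


def random_digraph(n_nodes: int, edge_prob: float,
                   rng: np.random.Generator) -> nx.DiGraph:
    """Random digraph (cycles allowed, no self-loops)."""
    g = nx.DiGraph()
    g.add_nodes_from(f"N{i}" for i in range(n_nodes))
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < edge_prob:
                g.add_edge(f"N{i}", f"N{j}")
    return g


# ---------------------------------------------------------------- fixtures

@pytest.fixture()
def small_config() -> SimulationConfig:
    """Desk-scale study conditions with noise off (exact ground truth)."""
    return SimulationConfig(seed=7, extra_edge_prob=0.0)


@pytest.fixture()
def noisy_config() -> SimulationConfig:
    """Default study conditions (noise on)."""
    return SimulationConfig(seed=7)
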