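"""Extraction-graph construction, PageRank, centralities and prioritization.

The extraction graph unites the consecutive TF pairs of all cascades into
one simple directed graph with per-edge occurrence counts. TFs are ranked
by a fixed-iteration PageRank (damping 0.85, 10 iterations, every node
initialised at 0.25, L1-normalised for reporting) plus degree, betweenness,
closeness and eigenvector centralities, and prioritized by the
three-criteria rule: top-decile centrality in at least two measures,
membership in enough cascades, and non-zero alteration frequency in
multiple cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .cascades import Cascade

logger = logging.getLogger(__name__)

CENTRALITY_MEASURES = ("pagerank", "eigenvector", "closeness", "betweenness")


def build_extraction_graph(cascades: Iterable[Cascade]) -> nx.DiGraph:
    """Union of consecutive cascade pairs with occurrence counts.

    Edge attribute ``occurrence_count`` is the number of cascades in which
    the ordered pair appears consecutively; node attribute ``cascade_count``
    is the number of cascades containing the TF anywhere.
    """
    g = nx.DiGraph()
    node_counts: dict[str, int] = {}
    for c in cascades:
        for tf in c.chain:
            node_counts[tf] = node_counts.get(tf, 0) + 1
        for u, v in zip(c.chain[:-1], c.chain[1:]):
            if g.has_edge(u, v):
                g[u][v]["occurrence_count"] += 1
            else:
                g.add_edge(u, v, occurrence_count=1)
    nx.set_node_attributes(g, node_counts, "cascade_count")
    logger.info("extraction graph: %d nodes, %d unique edges, %d weight units",
                g.number_of_nodes(), g.number_of_edges(),
                sum(d["occurrence_count"] for _, _, d in g.edges(data=True)))
    return g


def pagerank(graph: nx.DiGraph,
             damping: float = 0.85,
             iterations: int = 10,
             init: float = 0.25,
             converge_tol: Optional[float] = None) -> dict[str, float]:
    """Fixed-iteration power method on the directed graph.

    Update: x'(v) = (1-d)/N + d * sum_{u->v} x(u)/outdeg(u), with the mass
    of dangling nodes redistributed uniformly. All nodes start at ``init``
    (the procedure is run verbatim even though 0.25 does not sum to 1) and
    the final vector is L1-normalised for reporting. With ``converge_tol``
    set, iteration continues past ``iterations`` until the L1 change drops
    below the tolerance.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("pagerank of an empty graph")
    idx = {v: i for i, v in enumerate(nodes)}
    outdeg = np.array([graph.out_degree(v) for v in nodes], dtype=float)
    dangling = outdeg == 0
    rows, cols = [], []
    for u, v in graph.edges:
        rows.append(idx[v])
        cols.append(idx[u])
    x = np.full(n, float(init))
    it = 0
    while True:
        share = np.where(dangling, 0.0, x / np.where(dangling, 1.0, outdeg))
        inflow = np.zeros(n)
        np.add.at(inflow, rows, share[cols])
        x_new = (1.0 - damping) / n + damping * (inflow + x[dangling].sum() / n)
        delta = np.abs(x_new - x).sum()
        x = x_new
        it += 1
        if converge_tol is not None:
            if delta < converge_tol and it >= iterations:
                break
            if it >= 10_000:
                break
        elif it >= iterations:
            break
    x = x / x.sum()
    return {v: float(x[idx[v]]) for v in nodes}


def centralities(graph: nx.DiGraph, directed: bool = False) -> pd.DataFrame:
    """Degree, betweenness, closeness and eigenvector centralities.

    Degree is total (in + out) degree; betweenness is normalised
    shortest-path betweenness on the directed graph. Closeness and
    eigenvector are computed on the undirected view by default (the
    extraction graph is near-acyclic, where directed eigenvector centrality
    collapses to ~0 on sources); closeness uses the Wasserman-Faust
    component-size correction so disconnected graphs are handled. The
    eigenvector is the non-negative leading eigenvector at unit Euclidean
    norm. Set ``directed=True`` for the strict directed variants.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("centralities of an empty graph")
    nodes = sorted(graph.nodes)
    degree = {v: graph.degree(v) for v in nodes}
    btw = nx.betweenness_centrality(graph, normalized=True)
    view = graph if directed else graph.to_undirected(as_view=False)
    clo = nx.closeness_centrality(view, wf_improved=True)
    try:
        eig = nx.eigenvector_centrality_numpy(view)
    except (nx.NetworkXException, np.linalg.LinAlgError, TypeError, ValueError):
        eig = {v: 0.0 for v in nodes}
    evec = np.array([eig[v] for v in nodes], dtype=float)
    evec = np.abs(evec)
    norm = np.linalg.norm(evec)
    if norm > 0:
        evec = evec / norm
    return pd.DataFrame({
        "TF": nodes,
        "degree": [int(degree[v]) for v in nodes],
        "betweenness": [float(btw[v]) for v in nodes],
        "closeness": [float(clo[v]) for v in nodes],
        "eigenvector": evec,
    })


def rank_table(graph: nx.DiGraph,
               damping: float = 0.85,
               iterations: int = 10,
               init: float = 0.25,
               directed_centrality: bool = False) -> pd.DataFrame:
    """Per-TF PageRank + centralities + cascade_count, sorted by PageRank.

    Ties in the PageRank ordering break lexicographically by symbol.
    """
    pr = pagerank(graph, damping=damping, iterations=iterations, init=init)
    tab = centralities(graph, directed=directed_centrality)
    tab.insert(1, "pagerank", [pr[v] for v in tab["TF"]])
    counts = nx.get_node_attributes(graph, "cascade_count")
    tab["cascade_count"] = [int(counts.get(v, 0)) for v in tab["TF"]]
    tab = tab.sort_values(["pagerank", "TF"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    tab.insert(0, "rank", np.arange(1, len(tab) + 1))
    return tab


def _top_decile(values: pd.Series, quantile: float = 0.9) -> pd.Series:
    """Membership in the >= 90th-percentile set, ties at the cut included."""
    threshold = values.quantile(quantile)
    return values >= threshold


def prioritize_tfs(rank_tab: pd.DataFrame,
                   cascade_counts: Mapping[str, int],
                   alteration_table: pd.DataFrame,
                   min_cascades: int = 1000,
                   min_cohorts: int = 2,
                   quantile: float = 0.9) -> pd.DataFrame:
    """Three-criteria prioritization with per-criterion pass/fail columns.

    (i) top-decile score in >= 2 of PageRank, eigenvector, closeness,
    betweenness; (ii) presence in >= ``min_cascades`` cascades; (iii)
    alteration frequency > 0 in >= ``min_cohorts`` cohorts. ``prioritized``
    is the conjunction.
    """
    tab = rank_tab.copy()
    n_top = pd.Series(0, index=tab.index)
    for m in CENTRALITY_MEASURES:
        flag = _top_decile(tab[m], quantile)
        tab[f"top_decile_{m}"] = flag
        n_top = n_top + flag.astype(int)
    tab["criterion_centrality"] = n_top >= 2
    tab["cascade_count"] = [int(cascade_counts.get(tf, 0)) for tf in tab["TF"]]
    tab["criterion_cascades"] = tab["cascade_count"] >= min_cascades

    cohorts = [c for c in alteration_table.columns if c != "gene"]
    alt = alteration_table.set_index("gene")
    n_altered = []
    for tf in tab["TF"]:
        if tf in alt.index and cohorts:
            n_altered.append(int((alt.loc[tf, cohorts] > 0).sum()))
        else:
            n_altered.append(0)
    tab["n_cohorts_altered"] = n_altered
    tab["criterion_alterations"] = tab["n_cohorts_altered"] >= min_cohorts
    tab["prioritized"] = (tab["criterion_centrality"]
                          & tab["criterion_cascades"]
                          & tab["criterion_alterations"])
    return tab


def top_k_tables(rank_tab: pd.DataFrame, k: int = 10) -> dict[str, pd.DataFrame]:
    """Top-k views per measure (PageRank plus the three centralities)."""
    out = {}
    out["pagerank"] = (rank_tab.sort_values(["pagerank", "TF"],
                                            ascending=[False, True])
                       .head(k)[["TF", "pagerank"]].reset_index(drop=True))
    for m in ("betweenness", "closeness", "eigenvector"):
        out[m] = (rank_tab.sort_values([m, "TF"], ascending=[False, True])
                  .head(k)[["TF", "degree", m]].reset_index(drop=True))
    return out
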