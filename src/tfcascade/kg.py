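"""Attributed directed multigraph of TFs and enriched pathways.

TF -> TF edges carry weight 1 per cascade occurrence (parallel edges
accumulate across cascades); each cascade whose enrichment passes the
significance filter contributes an edge from its terminal TF to the
pathway node, attributed with the test statistics and weighted
1 - adjusted p (clipped to [0, 1]). TF nodes record the (cascade id,
level) pairs they participate in — serialised as a JSON string so GraphML
round-trips losslessly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .cascades import Cascade

logger = logging.getLogger(__name__)

EXPORT_FORMATS = ("graphml", "edgelist", "json")


def assemble_kg(cascades: Iterable[Cascade],
                enrichment_results: Optional[pd.DataFrame] = None,
                alpha: float = 0.05,
                link_all_members: bool = False) -> nx.MultiDiGraph:
    """Build the knowledge graph from cascades and per-cascade enrichment.

    ``enrichment_results`` must carry a ``cascade_id`` column referring to
    1-based positions in the cascade list; rows with p_adjusted <= alpha
    create TF -> pathway edges from the cascade's terminal TF (or from
    every member with ``link_all_members``).
    """
    cascades = list(cascades)
    kg = nx.MultiDiGraph()
    levels: dict[str, list[tuple[int, int]]] = {}
    for cid, c in enumerate(cascades, start=1):
        for tf in c.chain:
            levels.setdefault(tf, []).append((cid, c.level))
        for u, v in zip(c.chain[:-1], c.chain[1:]):
            kg.add_edge(u, v, weight=1.0, cascade_id=cid)
    for tf, pairs in levels.items():
        kg.add_node(tf, kind="TF", cascade_levels=json.dumps(pairs))

    if enrichment_results is not None and len(enrichment_results):
        if "cascade_id" not in enrichment_results.columns:
            raise ValueError("enrichment results lack a cascade_id column")
        known = set(range(1, len(cascades) + 1))
        bad = set(enrichment_results["cascade_id"]) - known
        if bad:
            raise ValueError(f"enrichment rows cite unknown cascade id(s): "
                             f"{sorted(bad)[:5]}")
        sig = enrichment_results[enrichment_results["p_adjusted"] <= alpha]
        for row in sig.itertuples(index=False):
            c = cascades[int(row.cascade_id) - 1]
            pathway = str(row.pathway)
            if not kg.has_node(pathway):
                kg.add_node(pathway, kind="pathway", name=pathway)
            weight = float(np.clip(1.0 - row.p_adjusted, 0.0, 1.0))
            members = c.chain if link_all_members else (c.chain[-1],)
            for tf in members:
                kg.add_edge(tf, pathway, weight=weight,
                            p=float(row.p), z=float(row.z),
                            combined=float(row.combined),
                            p_adjusted=float(row.p_adjusted),
                            cascade_id=int(row.cascade_id))
    logger.info("knowledge graph: %d nodes, %d edges",
                kg.number_of_nodes(), kg.number_of_edges())
    return kg


def tf_nodes(kg: nx.MultiDiGraph) -> list[str]:
    return sorted(n for n, d in kg.nodes(data=True) if d.get("kind") == "TF")


def pathway_nodes(kg: nx.MultiDiGraph) -> list[str]:
    return sorted(n for n, d in kg.nodes(data=True) if d.get("kind") == "pathway")


def tf_subgraph(kg: nx.MultiDiGraph) -> nx.DiGraph:
    """Simple directed TF-TF view with occurrence counts (for ranking/ML)."""
    g = nx.DiGraph()
    tfs = set(tf_nodes(kg))
    for u, v, d in kg.edges(data=True):
        if u in tfs and v in tfs:
            if g.has_edge(u, v):
                g[u][v]["occurrence_count"] += 1
            else:
                g.add_edge(u, v, occurrence_count=1)
    return g


def kg_summary(kg: nx.MultiDiGraph) -> dict:
    """Node counts by kind, edge counts by kind, TF->pathway weight stats."""
    kinds = nx.get_node_attributes(kg, "kind")
    n_tf = sum(1 for k in kinds.values() if k == "TF")
    n_path = sum(1 for k in kinds.values() if k == "pathway")
    tf_tf = 0
    tf_path = 0
    weights = []
    for u, v, d in kg.edges(data=True):
        if kinds.get(v) == "pathway":
            tf_path += 1
            weights.append(float(d.get("weight", 0.0)))
        else:
            tf_tf += 1
    w = np.array(weights) if weights else np.array([])
    return {
        "n_tf_nodes": n_tf,
        "n_pathway_nodes": n_path,
        "n_total_nodes": kg.number_of_nodes(),
        "n_tf_tf_edges": tf_tf,
        "n_tf_pathway_edges": tf_path,
        "n_total_edges": kg.number_of_edges(),
        "tf_pathway_weight": {
            "min": float(w.min()) if w.size else None,
            "max": float(w.max()) if w.size else None,
            "mean": float(w.mean()) if w.size else None,
            "sd": float(w.std(ddof=1)) if w.size > 1 else None,
        },
    }


def export_kg(kg: nx.MultiDiGraph, path: str | Path, format: str = "graphml") -> Path:
    """Write the KG; graphml and json round-trip losslessly, edgelist is lossy."""
    path = Path(path)
    if format not in EXPORT_FORMATS:
        raise ValueError(f"format must be one of {EXPORT_FORMATS}")
    if format == "graphml":
        nx.write_graphml(kg, path)
    elif format == "json":
        data = nx.node_link_data(kg, edges="edges")
        path.write_text(json.dumps(data, indent=1, sort_keys=True))
    else:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, d in kg.edges(data=True):
                fh.write(f"{u}\t{v}\t{d.get('weight', 1.0)}\n")
    return path


def import_kg(path: str | Path, format: str = "graphml") -> nx.MultiDiGraph:
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
        # graphml stores edge keys as strings; normalise back to ints
        out = nx.MultiDiGraph()
        out.add_nodes_from(g.nodes(data=True))
        for u, v, k, d in g.edges(keys=True, data=True):
            try:
                k = int(k)
            except (TypeError, ValueError):
                pass
            out.add_edge(u, v, key=k, **d)
        return out
    if format == "json":
        data = json.loads(Path(path).read_text())
        return nx.node_link_graph(data, directed=True, multigraph=True,
                                  edges="edges")
    raise ValueError("only graphml and json imports are lossless")
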