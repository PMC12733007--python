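#!/usr/bin/env python
"""Assemble and export the TF/pathway knowledge graph.

TF -> TF multigraph edges (weight 1 per cascade occurrence) plus terminal
TF -> pathway edges for enrichments passing q <= 0.05, weighted
1 - adjusted p and attributed with p, z and the combined score. Writes
GraphML and JSON exports and prints the node/edge accounting.
"""

from pathlib import Path

import pandas as pd

from tfcascade.cascades import table_to_cascades
from tfcascade.enrichment import enrich_cascades, load_gmt
from tfcascade.kg import assemble_kg, export_kg, kg_summary

ROOT = Path(__file__).resolve().parent.parent / "results"
ALPHA = 0.05


def main() -> None:
    table = pd.read_csv(ROOT / "cascades.csv")
    library = load_gmt(ROOT / "inputs" / "pathways.gmt")
    results, _ = enrich_cascades(table, library, alpha=ALPHA)
    kg = assemble_kg(table_to_cascades(table), results, alpha=ALPHA)
    export_kg(kg, ROOT / "kg.graphml", format="graphml")
    export_kg(kg, ROOT / "kg.json", format="json")

    s = kg_summary(kg)
    print(f"knowledge graph: {s['n_total_nodes']} nodes "
          f"({s['n_tf_nodes']} TF, {s['n_pathway_nodes']} pathway), "
          f"{s['n_total_edges']} edges "
          f"({s['n_tf_tf_edges']} TF->TF + {s['n_tf_pathway_edges']} "
          f"TF->pathway)")
    w = s["tf_pathway_weight"]
    if w["mean"] is not None:
        print(f"TF->pathway weights: min {w['min']:.4g}, max {w['max']:.4g}, "
              f"mean {w['mean']:.4g}, sd {w['sd'] if w['sd'] is None else round(w['sd'], 4)}")


if __name__ == "__main__":
    main()
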