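#!/usr/bin/env python
"""Parse the actions table and distil high-confidence directed TF-TF edges.

Applies the four retention rules (registry membership on both endpoints,
combined score >= 700, directional, activation/inhibition mode), orients
each edge regulator -> target, maps protein IDs to gene symbols and
deduplicates. Writes results/edges.tsv and prints the rejection tally.
"""

from pathlib import Path

from tfcascade.extraction import (collapse_modes, edges_to_frame,
                                  filter_tf_edges, load_actions, load_id_map,
                                  load_registry, map_and_dedupe,
                                  registry_to_protein_ids)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    loaded = load_actions(ROOT / "inputs" / "actions.tsv")
    registry = load_registry(ROOT / "inputs" / "tf_registry.txt")
    id_map = load_id_map(ROOT / "inputs" / "id_map.tsv")
    print(f"parsed {len(loaded.records)} action rows "
          f"({len(loaded.rejected)} malformed)")

    filtered = filter_tf_edges(loaded.records,
                               registry_to_protein_ids(registry, id_map))
    deduped = map_and_dedupe(filtered.edges, id_map)
    edges = collapse_modes(deduped.edges)
    edges_to_frame(edges).to_csv(ROOT / "edges.tsv", sep="\t", index=False)

    print(f"retained {len(edges)} directed TF-TF edges "
          f"(dropped: {dict(filtered.reject_counts)}; "
          f"{deduped.n_duplicates} duplicates collapsed, "
          f"{deduped.n_self_loops} self-loops removed)")
    print(f"wrote {ROOT / 'edges.tsv'}")


if __name__ == "__main__":
    main()
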