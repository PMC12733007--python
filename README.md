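# tfcascade

Transcription factors (TFs) regulate other TFs, forming *cascades*: ordered
chains TF₁ → TF₂ → … → TFₖ in which each factor activates or inhibits the
next. Dysregulated cascades are implicated in cancer, and the TFs that sit at
the convergence points of many cascades are candidate therapeutic targets.
`tfcascade` is a toolkit for building and interrogating a cascade compendium
from a STRING-actions style interaction table: it is aimed at computational
biologists who want a reproducible, offline-testable version of this
analysis, with every stage exercisable against a synthetic generator that
plants known structure.

## What it computes

- **Edge extraction** — from a tab-separated actions table
  (`item_id_a, item_id_b, mode, action, is_directional, a_is_acting, score`),
  keep rows where both endpoints are registry TFs, the combined confidence
  score is ≥ 700 (of 1000), the interaction is directional and the mode is
  activation or inhibition; orient each edge regulator → target
  (`item_a` if `a_is_acting` else `item_b`), map protein IDs to gene symbols
  and deduplicate keeping the maximum score.
- **Cascade enumeration** — on the directed TF graph G = (V, E), every
  *maximal simple directed path* starting from a source node (in-degree 0),
  found by depth-first search with visited-set cycle pruning. Chain length is
  the number of TFs; the cascade level is L = length − 1 (a 3-TF chain is
  labelled `L2`). Cascades are reported as a wide, NA-padded table
  (`cascade_id, Level, TF 1 … TF n`) with a chain-length histogram and a
  univariate EDA summary.
- **TF ranking** — the *extraction graph* unites consecutive cascade pairs
  into one simple directed graph. PageRank is the fixed-iteration power
  method x′(v) = (1−d)/N + d·Σ_{u→v} x(u)/outdeg(u) with damping d = 0.85,
  10 iterations, every node initialised at 0.25 and the final vector
  L1-normalised; degree, betweenness, closeness (Wasserman–Faust) and
  eigenvector centralities complete the rank table. A TF is *prioritized*
  when it is top-decile in ≥ 2 measures, appears in enough cascades, and has
  a non-zero alteration frequency in ≥ 2 cohorts.
- **Pathway enrichment** — one-sided hypergeometric over-representation of
  each cascade's TF set against a GMT library:
  p = P(X ≥ k), X ~ Hypergeom(N, K, n), with Haldane-corrected odds ratio,
  hypergeometric z-score, combined score −ln(p)·z and Benjamini–Hochberg
  FDR adjustment across the library (α = 0.05).
- **Knowledge graph** — a directed multigraph with TF and pathway nodes:
  TF→TF edges weight 1 per cascade occurrence, and terminal-TF→pathway edges
  for significant enrichments, weighted 1 − q and attributed with p, z and
  the combined score. Lossless GraphML/JSON export.
- **Link prediction** — node2vec-style second-order random walks (10 walks
  per node, length 80) feed a skip-gram model with negative sampling; link
  features from the Hadamard (u⊙v), L1 (|u−v|), L2 ((u−v)²) and average
  ((u+v)/2) operators are scored by a logistic classifier on a 75:25 split
  with uniformly sampled non-edge negatives, reporting ROC-AUC per operator.
  Next-TF candidates for a cascade prefix are ranked by cosine similarity to
  the terminal TF. The default `holdout` protocol embeds only the training
  subgraph; the `full` (transductive) protocol is available but warns that
  its AUC is optimistic.
- **Survival comparison** — Kaplan–Meier product-limit curves
  S(t) = Π_{tᵢ≤t} (1 − dᵢ/nᵢ) and the unweighted log-rank test compare
  altered vs unaltered patients across four endpoints (disease-specific,
  overall, progression-free, disease-free), with BH q-values across the
  endpoints.

The bundled generator (`tfcascade.synthetic`) emits all six inputs — actions
table, TF registry, ID map, GMT library, alteration table, survival
cohort — with planted cascades, planted enriched pathways and a planted
hazard ratio, so the full pipeline closes the loop against known truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 1), writing tables under `results/`:

```sh
python analysis/01_simulate_inputs.py
python analysis/02_extract_edges.py
python analysis/03_enumerate_cascades.py
python analysis/04_rank_tfs.py
python analysis/05_pathway_enrichment.py
python analysis/06_knowledge_graph.py
python analysis/07_link_prediction.py
python analysis/08_survival_analysis.py
```

Selected output:

```
planted cascades: 7 (lengths [4, 4, 4, 4, 4, 7, 7])
...
retained 32 directed TF-TF edges (dropped: {'undirected': 3, 'low_score': 4,
  'non_regulatory_mode': 5, 'non_tf_endpoint': 20}; 7 duplicates collapsed)
...
11 cascades; chain-length histogram: {2: 3, 3: 1, 4: 4, 6: 1, 7: 2}
planted chains contained in an enumerated cascade: 7/7
...
next-TF candidates after TF0040->TF0018->TF0020->TF0056->TF0038->TF0005
  (true continuation TF0022):
    TF  similarity
TF0022    0.982663
...
   Survival Type  Number of Patients      chi2      p-Value      q-Value
Disease Specific                 500 36.778356 1.323515e-09 5.294060e-09
```

Reading this: with noise edges on, the seven planted chains are all
recovered inside the 11 enumerated cascades (noise adds short spurious
chains); the embedding ranks the held-out true continuation of the longest
cascade first by cosine similarity (0.98); and the planted 2× hazard ratio
in a 500-patient cohort yields a decisive log-rank separation on every
endpoint, with BH q-values adjusted across the four tests.

A `tfcascade` console script exposes the same stages
(`simulate | extract | cascades | rank | enrich | kg | linkpred | survival |
run`); `tfcascade run --config cfg.yaml` executes them end to end with a
JSON + markdown run report.

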