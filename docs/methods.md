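# Methods

## Scope and model

`tfcascade` treats transcription-factor regulation as a directed graph over
TFs and defines a cascade as a maximal simple directed path rooted at a
source node (in-degree 0). This is a deliberately structural model: edges
come from a curated interaction table with directionality and an
activation/inhibition mode, not from expression dynamics, and a cascade
asserts only that a chain of directed regulatory links exists. Chain length
counts TFs; the cascade level L = length − 1 counts regulatory steps and is
reported as the label `L{n}`.

## Edge extraction

The actions dialect carries a 0–1000 combined confidence score. Four
retention rules are applied in a fixed order and tallied per rejection
reason: both endpoints in the TF registry, score ≥ 700 (inclusive — the
high-confidence convention), `is_directional` true, and mode in
{activation, inhibition}. Orientation follows the acting-partner flag:
regulator = `item_a` iff `a_is_acting`. Other action modes (binding,
catalysis, expression, …) are excluded because the cascade definition is
about regulation; `filter_tf_edges(..., modes=...)` widens the set if a
user wants, e.g., expression-mode edges. Duplicates on
(regulator, target, mode) keep the maximum score — deterministic and
conservative; both orientations of a reciprocal pair are distinct edges.
Self-loops created by many-to-one protein→symbol mapping are dropped and
counted. Registry matching is exact-string after upper-casing; no alias
expansion, trading recall for reproducibility. Because filtering precedes
symbol mapping, the registry (kept in symbol space on disk) is translated
to protein space with `registry_to_protein_ids` before filtering.

## Cascade enumeration

Depth-first search from every source, with visited-set pruning (a
neighbour already on the current path is skipped — this is what bounds the
search on cyclic graphs) and lexicographic neighbour order so output is
identical across platforms. Only *maximal* paths are emitted — a path ends
when no out-neighbour can extend it without revisiting a node — because
counting every prefix as its own cascade makes counts scale-dependent and
redundant; `include_prefixes=True` provides the alternative reading.
Components with no in-degree-0 node (pure cycles) yield no cascades and
raise an explicit warning rather than an exception. Simple-path
enumeration is exponential in the worst case, so safety caps default to
`max_length=64` and `max_cascades=1e6` with loud `TruncationWarning`s;
truncation is never silent. Missing cells in the wide cascade table are
structurally missing (the cascade is shorter than the column) and are
written as empty CSV cells.

## Ranking

PageRank is run as a fixed-iteration power method: damping 0.85, exactly
10 iterations, every node initialised at 0.25, dangling mass redistributed
uniformly. The 0.25 initialisation does not sum to 1; the update is run
verbatim from that vector and the result is L1-normalised only for
reporting, which preserves the fixed-iteration ranking while making scores
comparable. A `converge_tol` option iterates to tolerance instead (and
then agrees with networkx's PageRank). Degree is total (in + out);
betweenness is normalised shortest-path betweenness on the directed graph;
closeness and eigenvector centrality are computed on the undirected view
by default because the extraction graph is near-acyclic and directed
eigenvector centrality collapses to ~0 on all source-side nodes
(`directed=True` gives the strict variants). Closeness uses the
Wasserman–Faust component-size correction since extraction graphs are
frequently disconnected; the eigenvector is reported non-negative at unit
Euclidean norm.

Prioritization conjoins three criteria: top-decile (≥ 90th percentile,
ties included) in at least two of {PageRank, eigenvector, closeness,
betweenness}; membership in ≥ `min_cascades` cascades (default 1000,
set to 2 in the desk-scale analysis scripts since the synthetic compendium
has tens, not tens of thousands, of cascades); and alteration frequency
> 0 in ≥ 2 cohorts, reading "multiple cohorts" as at least two. Each
criterion's pass/fail is a column, so the conjunction is auditable.

## Enrichment

Over-representation only (one-sided): for overlap k between a size-n query
and a size-K set in a size-N universe, p = P(X ≥ k) under
Hypergeom(N, K, n) (scipy's survival function). The odds ratio uses the
2×2 table with a Haldane 0.5 correction when any cell is zero. The z-score
standardises k by the hypergeometric mean nK/N and variance
n(K/N)(1−K/N)(N−n)/(N−1), and the combined score is −ln(p)·z — the
Enrichr-style composite, documented here as an approximation of that web
tool's rank-based z rather than a reproduction of it. BH step-up
(q(i) = min_{j≥i} p(j)·m/j, capped at 1) runs across all sets of one
library; the default universe is the query ∪ library gene union,
configurable when a larger background is appropriate. Per-cascade batch
mode shares one universe across cascades so p-values are comparable, and
reports both the total and the significant results-per-cascade means.

## Knowledge graph

A directed multigraph. TF→TF edges carry weight 1 per cascade occurrence,
so parallel edges accumulate and total TF→TF multiplicity equals
Σ(length−1) over cascades. For each cascade with an enrichment at
q ≤ α, an edge runs from the cascade's *terminal* TF to the pathway node —
the terminal TF is the cascade's convergence point — with
`link_all_members=True` for the broader every-member linkage. The
TF→pathway weight is 1 − q clipped to [0, 1]: a convention chosen to be
monotone in significance and bounded, not an estimate of anything. TF
nodes carry their (cascade id, level) list serialised as a JSON string so
GraphML round-trips losslessly; GraphML and node-link JSON exports are
verified import(export(kg)) = kg on nodes, edges and attributes, while the
edge-list export is documented as lossy.

## Embeddings and link prediction

Walks are second-order (node2vec) with return parameter p and in-out
parameter q (defaults p = q = 1, i.e. unbiased), 10 walks per node of
length 80 on the undirected view (`directed=True` available); a dead end
terminates a walk early, so the corpus size law |walks| = num_walks·|V|
holds exactly. The skip-gram-with-negative-sampling trainer is implemented
in numpy: word2vec-style dynamic window shrinking, 5 negatives per pair
from the unigram^0.75 distribution, mini-batched SGD with a linear
learning-rate decay. One numerical choice matters on graph-sized
vocabularies: within a batch, gradients accumulated on the same embedding
row are *averaged*, not summed — with tens of nodes every row recurs
~100× per batch and summed updates multiply the effective learning rate
until training diverges. The exported vector is the mean of the input and
output matrices, which denoises small corpora; `combine="input"` gives
centre vectors only. Training is single-threaded and deterministic given
the seed.

Link features use four elementwise operators: Hadamard u⊙v, L1 |u−v|,
L2 (u−v)² (squared difference; `l2_root=True` gives the rooted variant,
which coincides with L1) and average (u+v)/2. Positives are the graph's
unordered edges split 75:25; negatives are sampled uniformly from
non-adjacent unordered pairs, never coincide with a true edge, and are
disjoint between train and test. A logistic classifier is fit per operator
and ROC-AUC reported on the test split. The default `holdout` protocol
removes test edges before walking/embedding so test links are unseen; the
`full` protocol embeds the whole graph first, leaks test-edge structure
into the features, and warns that its AUC is optimistic — the package
reports both but treats only holdout AUC as meaningful. Next-TF prediction
scores every embedded candidate outside the prefix by cosine similarity to
the terminal prefix TF, descending with lexicographic tie-break.

## Survival

Kaplan–Meier curves and the unweighted log-rank test are delegated to
lifelines. Ties follow the standard convention (events before censorings
at equal times); the median is the smallest time with S(t) ≤ 0.5, with no
interpolation, and is undefined (NaN) when S never reaches 0.5. Exactly
four endpoints are analysed and their p-values BH-adjusted into q-values;
BH is used because step-up adjustment of four p-values is the standard
multiple-comparison treatment at this scale and reproduces the reference
worked example (0.004188, 0.0318, 0.0328, 0.604 → 0.0168, 0.0437, 0.0437,
0.604) exactly — note the naive p·m/rank would give 0.0636 for the second
endpoint; the monotonisation step is what the worked example certifies.

## Synthetic data: what it emulates and what it does not

The generator's defaults define the study conditions: 60 TFs + 40 non-TF
genes; seven planted node-disjoint chains (five of length 4, two of
length 7); planted edges directional, activation-biased (70%), scores
uniform in [700, 990]; noise comprising sub-threshold, undirected,
binding-mode, and non-TF rows plus (rate `extra_edge_prob = 0.05`)
high-confidence extra TF–TF edges that never point into a planted-path
interior; a 20-set GMT library whose first sets fully contain the first
planted chains (recoverable enrichment); three alteration cohorts where
planted-chain members are always altered; and a 500-patient four-endpoint
cohort with exponential event times at hazard ratio 2 for the 15% altered
fraction and 30% independent censoring (baseline medians 90/75/60/120
months by endpoint). With noise off, the enumerated cascade set equals the
planted set exactly — the closed-loop oracle used by the end-to-end tests.

What passing these tests shows: the pipeline's algebra and bookkeeping are
correct under known structure. What it does not show: robustness to real
STRING score calibration, alias ambiguity, tissue-specific expression, or
non-exponential survival — planted identifiers are clean, noise is
independent, and hazards are proportional by construction.

## Test scale and numerical choices

Oracle suites run at sizes where brute force is exact: maximal-path
enumeration on 500 random DAGs of ≤ 12 nodes (plus 200 cyclic digraphs of
≤ 8 nodes); PageRank against an independent dense power iteration to
1e−12, and betweenness/closeness against explicit shortest-path counting,
exhaustively over all weakly-connected 3-node digraphs plus a seeded
random sample of 4–6-node graphs; hypergeometric p against exact rational
enumeration for N ≤ 25. Link-prediction properties use 60-node planted
two-community graphs (within-community edge probability 0.4, across 0.01)
and 40-node Erdős–Rényi nulls with 10 seeds each, embedding at d = 32,
window 4, 4 epochs — sizes chosen so the full suite runs in about a
minute while the planted/null AUC gap stays wide. Log-rank calibration
uses 200 null replicates of 40 + 40 uncensored patients; KM median
recovery uses n = 2000 exponential draws. All randomness in tests and
scripts flows from fixed seeds; hypothesis property tests run
derandomised.

## Known limitations

- Cascade counts depend on the maximality convention; compendia built with
  prefix-counting semantics are not directly comparable (both modes are
  provided).
- The extraction graph's unique-edge count and its occurrence-weight sum
  are different quantities; summaries report both rather than reconciling
  them.
- The z and combined enrichment scores approximate the Enrichr composite;
  only the hypergeometric p and BH q are exact statistics.
- The SGNS trainer is tuned for graph-sized vocabularies (10²–10⁴ nodes);
  it is not a general-purpose word2vec replacement.
- No Cox regression or competing-risks handling; the survival module
  compares two groups nonparametrically.
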