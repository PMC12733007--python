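"""Link prediction on the TF graph with edge-embedding operators.

Node embeddings (see ``embeddings``) are combined into link features by
four elementwise operators — Hadamard u*v, L1 |u-v|, L2 (u-v)^2 and
average (u+v)/2 — and scored with a logistic classifier on a 75:25
positive/negative split. ROC-AUC is reported per operator; candidate
next-TF links are ranked by cosine similarity to a cascade's terminal TF.

Two evaluation protocols are provided. The default ``holdout`` mode trains
embeddings on the training subgraph only (test edges removed), so test
links are genuinely unseen. ``full`` (transductive) mode embeds the whole
graph first, which leaks test-edge structure into the features and yields
optimistic AUCs; it is kept for comparison and warns when used.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .embeddings import EmbeddingMatrix, WalkCorpus, random_walks, train_embeddings

logger = logging.getLogger(__name__)

OPERATORS = ("hadamard", "l1", "l2", "average")


@dataclass
class EdgeSplit:
    train_pos: list[tuple[str, str]]
    train_neg: list[tuple[str, str]]
    test_pos: list[tuple[str, str]]
    test_neg: list[tuple[str, str]]


@dataclass
class LinkPredictionReport:
    auc: dict[str, float]
    best_operator: str
    mode: str
    seed: int
    split_sizes: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [(op.capitalize() if op != "average" else "Average",
                 self.auc[op]) for op in self.auc]
        return pd.DataFrame(rows, columns=["Operator", "ROC-AUC Score"])


def edge_features(u_vec: np.ndarray, v_vec: np.ndarray, operator: str,
                  l2_root: bool = False) -> np.ndarray:
    """Combine two node vectors into one link feature vector.

    L2 is the elementwise squared difference by default (the printed
    formula); ``l2_root`` gives |u-v| rooted elementwise, i.e. the absolute
    difference — equivalent to L1 — kept only for the documented variant.
    """
    u = np.asarray(u_vec, dtype=float)
    v = np.asarray(v_vec, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    if operator == "hadamard":
        return u * v
    if operator == "l1":
        return np.abs(u - v)
    if operator == "l2":
        d2 = (u - v) ** 2
        return np.sqrt(d2) if l2_root else d2
    if operator == "average":
        return (u + v) / 2.0
    raise ValueError(f"unknown operator {operator!r}; choose from {OPERATORS}")


def split_edges(graph: nx.Graph,
                train_frac: float = 0.75,
                neg_ratio: float = 1.0,
                seed: int = 0) -> EdgeSplit:
    """Random 75:25 positive split plus disjoint negative samples.

    Positives are the graph's unordered edges; negatives are sampled
    uniformly from unordered non-adjacent node pairs, never coinciding with
    a true edge, and kept disjoint between train and test.
    """
    und = graph.to_undirected(as_view=False)
    edges = sorted(tuple(sorted(e)) for e in und.edges)
    edges = sorted(set(edges))
    if len(edges) < 4:
        raise ValueError("need at least 4 edges to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(edges))
    n_train = int(round(train_frac * len(edges)))
    train_pos = [edges[i] for i in perm[:n_train]]
    test_pos = [edges[i] for i in perm[n_train:]]

    nodes = sorted(und.nodes)
    edge_set = set(edges)
    n_neg = int(round(neg_ratio * len(train_pos))) + int(
        round(neg_ratio * len(test_pos)))
    negatives: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    max_possible = len(nodes) * (len(nodes) - 1) // 2 - len(edge_set)
    n_neg = min(n_neg, max_possible)
    attempts = 0
    while len(negatives) < n_neg and attempts < 100 * max(1, n_neg):
        attempts += 1
        i, j = rng.integers(len(nodes), size=2)
        if i == j:
            continue
        pair = tuple(sorted((nodes[i], nodes[j])))
        if pair in edge_set or pair in seen:
            continue
        seen.add(pair)
        negatives.append(pair)
    n_train_neg = int(round(neg_ratio * len(train_pos)))
    return EdgeSplit(train_pos=train_pos,
                     train_neg=negatives[:n_train_neg],
                     test_pos=test_pos,
                     test_neg=negatives[n_train_neg:])


def _features(pairs: Sequence[tuple[str, str]], emb: EmbeddingMatrix,
              operator: str) -> np.ndarray:
    return np.array([edge_features(emb[u], emb[v], operator) for u, v in pairs])


def evaluate_link_prediction(graph: nx.Graph,
                             operators: Sequence[str] = OPERATORS,
                             mode: str = "holdout",
                             seed: int = 0,
                             train_frac: float = 0.75,
                             num_walks: int = 10,
                             walk_length: int = 80,
                             p: float = 1.0,
                             q: float = 1.0,
                             dim: int = 64,
                             window: int = 5,
                             epochs: int = 10) -> LinkPredictionReport:
    """Train/evaluate the link classifier and report ROC-AUC per operator."""
    if mode not in ("holdout", "full"):
        raise ValueError("mode must be 'holdout' or 'full'")
    split = split_edges(graph, train_frac=train_frac, seed=seed)
    if mode == "full":
        embed_graph = graph.to_undirected(as_view=False)
        warnings.warn(
            "full-graph embeddings are trained on test edges too; the "
            "reported AUC is optimistic", UserWarning,
        )
    else:
        embed_graph = graph.to_undirected(as_view=False)
        embed_graph.remove_edges_from(split.test_pos)
    corpus = random_walks(embed_graph, num_walks=num_walks,
                          walk_length=walk_length, p=p, q=q, seed=seed)
    emb = train_embeddings(corpus, dim=dim, window=window, epochs=epochs,
                           seed=seed)

    def covered(pairs):
        return [(u, v) for u, v in pairs if u in emb and v in emb]

    train_pairs = covered(split.train_pos) + covered(split.train_neg)
    y_train = ([1] * len(covered(split.train_pos))
               + [0] * len(covered(split.train_neg)))
    test_pairs = covered(split.test_pos) + covered(split.test_neg)
    y_test = ([1] * len(covered(split.test_pos))
              + [0] * len(covered(split.test_neg)))
    if len(set(y_test)) < 2 or len(set(y_train)) < 2:
        raise ValueError("degenerate split: a partition lacks both classes")

    auc: dict[str, float] = {}
    for op in operators:
        X_train = _features(train_pairs, emb, op)
        X_test = _features(test_pairs, emb, op)
        clf = LogisticRegression(max_iter=2000)
        clf.fit(X_train, y_train)
        auc[op] = float(roc_auc_score(y_test,
                                      clf.predict_proba(X_test)[:, 1]))
    best = max(auc, key=lambda k: (auc[k], k))
    return LinkPredictionReport(
        auc=auc, best_operator=best, mode=mode, seed=seed,
        split_sizes={
            "train_pos": len(split.train_pos),
            "train_neg": len(split.train_neg),
            "test_pos": len(split.test_pos),
            "test_neg": len(split.test_neg),
        },
    )


def predict_next_tf(embeddings: EmbeddingMatrix,
                    cascade_prefix: Sequence[str],
                    top_k: int = 10,
                    candidates: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Rank candidate next TFs by cosine similarity to the terminal TF.

    Candidates default to all embedded nodes outside the prefix. Ties break
    lexicographically; the result has columns TF and similarity.
    """
    prefix = list(cascade_prefix)
    if not prefix:
        raise ValueError("empty cascade prefix")
    missing = [t for t in prefix if t not in embeddings]
    if missing:
        raise KeyError(f"prefix TF(s) not embedded: {missing}")
    terminal = prefix[-1]
    pool = (sorted(set(candidates)) if candidates is not None
            else embeddings.nodes)
    pool = [c for c in pool if c not in set(prefix) and c in embeddings]
    scored = [(c, embeddings.cosine(terminal, c)) for c in pool]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return pd.DataFrame(scored[:top_k], columns=["TF", "similarity"])
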