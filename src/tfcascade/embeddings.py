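"""Node embeddings: second-order biased random walks + skip-gram training.

The walk generator implements node2vec semantics: from the step t -> v the
next node x is drawn with unnormalised weight 1/p if x = t (return), 1 if
x neighbours t, and 1/q otherwise (in-out). The walk corpus is fed to a
skip-gram model with negative sampling (SGNS) implemented in numpy:
mini-batched SGD over (centre, context) pairs generated with word2vec-style
dynamic window shrinking, negatives drawn from the unigram^0.75
distribution. Training is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.special import expit

logger = logging.getLogger(__name__)


@dataclass
class WalkCorpus:
    """Random-walk corpus plus the parameters that produced it."""

    walks: list[list[str]]
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.walks)


@dataclass
class EmbeddingMatrix:
    """Dense node -> vector map; rows of ``matrix`` follow ``nodes`` order."""

    nodes: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.nodes)}

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def __getitem__(self, node: str) -> np.ndarray:
        return self.matrix[self._index[node]]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def cosine(self, a: str, b: str) -> float:
        u, v = self[a], self[b]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            return 0.0
        return float(u @ v / (nu * nv))


def random_walks(graph: nx.Graph,
                 num_walks: int = 10,
                 walk_length: int = 80,
                 p: float = 1.0,
                 q: float = 1.0,
                 seed: int = 0,
                 directed: bool = False) -> WalkCorpus:
    """Second-order biased walks; ``num_walks`` starts per node.

    ``walk_length`` counts nodes; a node with no (out-)neighbours ends its
    walk early, so an isolated node yields length-1 walks. The graph is
    walked on its undirected view unless ``directed`` is set. Corpus size is
    exactly ``num_walks * |V|``.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot walk an empty graph")
    if walk_length < 1:
        raise ValueError("walk_length must be >= 1")
    view = graph if (directed and graph.is_directed()) else graph.to_undirected(as_view=False)
    nodes = sorted(view.nodes)
    nbrs = {n: sorted(view.successors(n)) if view.is_directed()
            else sorted(view.neighbors(n)) for n in nodes}
    nbr_sets = {n: set(v) for n, v in nbrs.items()}
    rng = np.random.default_rng(seed)
    walks: list[list[str]] = []
    for _ in range(num_walks):
        for start in nodes:
            walk = [start]
            while len(walk) < walk_length:
                cur = walk[-1]
                cand = nbrs[cur]
                if not cand:
                    break
                if len(walk) == 1 or (p == 1.0 and q == 1.0):
                    nxt = cand[rng.integers(len(cand))]
                else:
                    prev = walk[-2]
                    prev_nbrs = nbr_sets[prev]
                    w = np.array([
                        1.0 / p if x == prev
                        else (1.0 if x in prev_nbrs else 1.0 / q)
                        for x in cand
                    ])
                    w /= w.sum()
                    nxt = cand[rng.choice(len(cand), p=w)]
                walk.append(nxt)
            walks.append(walk)
    return WalkCorpus(walks=walks, params={
        "num_walks": num_walks, "walk_length": walk_length,
        "p": p, "q": q, "seed": seed, "n_nodes": len(nodes),
    })


def _training_pairs(walks_idx: list[np.ndarray], window: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(centre, context) index pairs with dynamic window shrinking."""
    centres: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    for w in walks_idx:
        L = len(w)
        if L < 2:
            continue
        spans = rng.integers(1, window + 1, size=L)
        for i in range(L):
            s = spans[i]
            lo, hi = max(0, i - s), min(L, i + s + 1)
            ctx = np.concatenate([w[lo:i], w[i + 1:hi]])
            if ctx.size:
                centres.append(np.full(ctx.size, w[i]))
                contexts.append(ctx)
    if not centres:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(centres), np.concatenate(contexts)


def train_embeddings(corpus: WalkCorpus,
                     dim: int = 128,
                     window: int = 10,
                     epochs: int = 10,
                     negative: int = 5,
                     alpha: float = 0.5,
                     min_alpha: float = 0.01,
                     batch_size: int = 1024,
                     seed: int = 0,
                     combine: str = "mean") -> EmbeddingMatrix:
    """Skip-gram with negative sampling over the walk corpus.

    Every node appearing in the corpus is embedded. The learning rate
    decays linearly from ``alpha`` to ``min_alpha`` across all batches.
    ``combine`` selects the exported vectors: "mean" averages the input
    (centre) and output (context) matrices, which denoises small corpora;
    "input" returns the centre vectors alone.
    """
    if combine not in ("mean", "input"):
        raise ValueError("combine must be 'mean' or 'input'")
    if not corpus.walks:
        raise ValueError("empty walk corpus")
    vocab = sorted({n for w in corpus.walks for n in w})
    index = {n: i for i, n in enumerate(vocab)}
    V = len(vocab)
    walks_idx = [np.array([index[n] for n in w], dtype=np.int64)
                 for w in corpus.walks]
    counts = np.zeros(V)
    for w in walks_idx:
        np.add.at(counts, w, 1.0)
    noise = counts ** 0.75
    noise /= noise.sum()

    rng = np.random.default_rng(seed)
    W = (rng.random((V, dim)) - 0.5) / dim  # input (centre) vectors
    C = np.zeros((V, dim))                  # output (context) vectors

    # pre-count batches for the linear learning-rate schedule
    pair_estimate = sum(max(0, len(w) - 1) for w in walks_idx) * (window + 1)
    total_batches = max(1, epochs * max(1, pair_estimate // batch_size))
    step = 0
    for epoch in range(epochs):
        centres, contexts = _training_pairs(walks_idx, window, rng)
        if centres.size == 0:
            break
        perm = rng.permutation(centres.size)
        centres, contexts = centres[perm], contexts[perm]
        for off in range(0, centres.size, batch_size):
            lr = max(min_alpha,
                     alpha * (1.0 - step / total_batches))
            step += 1
            c_idx = centres[off:off + batch_size]
            o_idx = contexts[off:off + batch_size]
            B = c_idx.size
            neg = rng.choice(V, size=(B, negative), p=noise)

            wc = W[c_idx]                       # (B, d)
            co = C[o_idx]                       # (B, d)
            cn = C[neg]                         # (B, neg, d)

            pos_score = expit(np.sum(wc * co, axis=1))
            neg_score = expit(np.einsum("bd,bnd->bn", wc, cn))

            g_pos = (pos_score - 1.0)[:, None]          # (B, 1)
            g_neg = neg_score[:, :, None]               # (B, neg, 1)

            grad_wc = g_pos * co + np.einsum("bnd,bn->bd", cn, neg_score)
            grad_co = g_pos * wc
            grad_cn = g_neg * wc[:, None, :]

            # average (not sum) gradients over duplicate indices within the
            # batch: with a small vocabulary every node recurs many times per
            # batch and summed updates blow the effective learning rate up
            acc_w = np.zeros_like(W)
            np.add.at(acc_w, c_idx, grad_wc)
            cnt_w = np.bincount(c_idx, minlength=V)[:, None]
            W -= lr * acc_w / np.maximum(cnt_w, 1)

            acc_c = np.zeros_like(C)
            np.add.at(acc_c, o_idx, grad_co)
            np.add.at(acc_c, neg.ravel(), grad_cn.reshape(-1, dim))
            cnt_c = (np.bincount(o_idx, minlength=V)
                     + np.bincount(neg.ravel(), minlength=V))[:, None]
            C -= lr * acc_c / np.maximum(cnt_c, 1)
    if not np.all(np.isfinite(W)) or not np.all(np.isfinite(C)):
        raise FloatingPointError("embedding training diverged")
    out = (W + C) / 2.0 if combine == "mean" else W
    return EmbeddingMatrix(nodes=vocab, matrix=out)
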