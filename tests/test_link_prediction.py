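"""Walk corpus laws, operator algebra, splits, AUC behaviour, next-TF ranking."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from tfcascade.embeddings import (EmbeddingMatrix, random_walks,
                                  train_embeddings)
from tfcascade.linkpred import (OPERATORS, edge_features,
                                evaluate_link_prediction, predict_next_tf,
                                split_edges)


def planted_two_community_graph(n_per=30, p_in=0.30, p_out=0.01, seed=0):
    return nx.planted_partition_graph(2, n_per, p_in, p_out, seed=seed)


class TestWalks:
    def test_isolated_node_dead_ends(self):
        g = nx.Graph()
        g.add_node("A")
        corpus = random_walks(g, num_walks=10, walk_length=80, seed=0)
        assert len(corpus) == 10
        assert all(w == ["A"] for w in corpus.walks)

    def test_corpus_size_law(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            g = nx.gnp_random_graph(int(rng.integers(2, 20)), 0.3,
                                    seed=int(rng.integers(1 << 16)))
            corpus = random_walks(g, num_walks=7, walk_length=5, seed=1)
            assert len(corpus) == 7 * g.number_of_nodes()

    def test_two_cycle_alternates(self):
        g = nx.Graph([("A", "B")])
        corpus = random_walks(g, num_walks=2, walk_length=6, seed=0)
        for w in corpus.walks:
            assert len(w) == 6
            for a, b in zip(w[:-1], w[1:]):
                assert {a, b} == {"A", "B"}

    def test_walks_start_at_assigned_nodes(self):
        g = nx.path_graph(5)
        corpus = random_walks(g, num_walks=3, walk_length=4, seed=2)
        starts = [w[0] for w in corpus.walks]
        assert starts == sorted(g.nodes) * 3

    def test_every_step_is_an_edge(self):
        g = nx.gnp_random_graph(12, 0.3, seed=3)
        und = g.to_undirected()
        corpus = random_walks(g, num_walks=2, walk_length=10, p=0.5, q=2.0,
                              seed=4)
        for w in corpus.walks:
            for a, b in zip(w[:-1], w[1:]):
                assert und.has_edge(a, b)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            random_walks(nx.Graph(), seed=0)


class TestEmbeddings:
    def test_every_node_embedded_with_dim(self):
        g = nx.path_graph(3)
        corpus = random_walks(g, num_walks=3, walk_length=5, seed=0)
        emb = train_embeddings(corpus, dim=16, epochs=2, seed=0)
        assert sorted(emb.nodes) == sorted(g.nodes)
        assert emb.matrix.shape == (3, 16)
        assert np.all(np.isfinite(emb.matrix))

    def test_deterministic_given_seed(self):
        g = nx.gnp_random_graph(10, 0.4, seed=1)
        corpus = random_walks(g, num_walks=3, walk_length=10, seed=5)
        a = train_embeddings(corpus, dim=8, epochs=2, seed=6)
        b = train_embeddings(corpus, dim=8, epochs=2, seed=6)
        assert np.array_equal(a.matrix, b.matrix)

    def test_empty_corpus_rejected(self):
        from tfcascade.embeddings import WalkCorpus
        with pytest.raises(ValueError):
            train_embeddings(WalkCorpus(walks=[]))

    def test_communities_closer_than_cross_pairs(self):
        """Within-community similarity beats cross-community (median, 10 seeds)."""
        margins = []
        for seed in range(10):
            g = planted_two_community_graph(n_per=15, p_in=0.5, p_out=0.02,
                                            seed=seed)
            corpus = random_walks(g, num_walks=10, walk_length=20, seed=seed)
            emb = train_embeddings(corpus, dim=16, window=4, epochs=4,
                                   seed=seed)
            rng = np.random.default_rng(seed)
            within, cross = [], []
            for _ in range(50):
                a, b = rng.integers(0, 15, size=2)
                if a != b:
                    within.append(emb.cosine(a, b))
                c = int(rng.integers(0, 15))
                d = int(rng.integers(15, 30))
                cross.append(emb.cosine(c, d))
            margins.append(np.mean(within) - np.mean(cross))
        assert np.median(margins) > 0.1


class TestOperators:
    def test_average_arithmetic(self):
        out = edge_features(np.array([1.0, 3.0]), np.array([3.0, 1.0]),
                            "average")
        assert out == pytest.approx([2.0, 2.0])

    def test_identical_vectors_zero_l1_l2(self):
        u = np.array([0.5, -1.0])
        assert edge_features(u, u, "l1") == pytest.approx([0, 0])
        assert edge_features(u, u, "l2") == pytest.approx([0, 0])

    def test_hadamard_orthogonal_support(self):
        out = edge_features(np.array([2.0, 0.0]), np.array([0.0, 5.0]),
                            "hadamard")
        assert out == pytest.approx([0.0, 0.0])

    def test_l2_is_squared_difference(self):
        out = edge_features(np.array([3.0]), np.array([1.0]), "l2")
        assert out == pytest.approx([4.0])
        rooted = edge_features(np.array([3.0]), np.array([1.0]), "l2",
                               l2_root=True)
        assert rooted == pytest.approx([2.0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            edge_features(np.zeros(2), np.zeros(3), "l1")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=8),
           st.lists(st.floats(-10, 10), min_size=1, max_size=8))
    def test_all_operators_symmetric(self, u, v):
        n = min(len(u), len(v))
        u, v = np.array(u[:n]), np.array(v[:n])
        for op in OPERATORS:
            assert edge_features(u, v, op) == pytest.approx(
                edge_features(v, u, op))


class TestSplit:
    def test_75_25_partition(self):
        g = nx.gnp_random_graph(30, 0.25, seed=7)
        n_edges = g.number_of_edges()
        split = split_edges(g, train_frac=0.75, seed=0)
        assert len(split.train_pos) == round(0.75 * n_edges)
        assert len(split.train_pos) + len(split.test_pos) == n_edges

    def test_negatives_never_true_edges_and_disjoint(self):
        g = nx.gnp_random_graph(20, 0.3, seed=8)
        split = split_edges(g, seed=1)
        edge_set = {tuple(sorted(e)) for e in g.edges}
        negs = split.train_neg + split.test_neg
        assert not (set(negs) & edge_set)
        assert not (set(split.train_neg) & set(split.test_neg))

    def test_seeds_change_partition_not_sizes(self):
        g = nx.gnp_random_graph(25, 0.3, seed=9)
        s1, s2 = split_edges(g, seed=1), split_edges(g, seed=2)
        assert sorted(s1.train_pos) != sorted(s2.train_pos)
        assert len(s1.train_pos) == len(s2.train_pos)
        assert len(s1.test_neg) == len(s2.test_neg)

    def test_too_few_edges_rejected(self):
        with pytest.raises(ValueError):
            split_edges(nx.path_graph(3), seed=0)


class TestEvaluate:
    def test_null_graph_auc_near_chance(self):
        """Erdos-Renyi has no link structure: AUC in the chance band."""
        aucs = []
        for seed in range(10):
            g = nx.gnp_random_graph(40, 0.12, seed=100 + seed)
            rep = evaluate_link_prediction(
                g, operators=("hadamard",), mode="holdout", seed=seed,
                num_walks=10, walk_length=20, dim=16, window=4, epochs=3)
            aucs.append(rep.auc["hadamard"])
        assert 0.4 <= float(np.median(aucs)) <= 0.6

    def test_planted_communities_recovered(self):
        """Dense intra-community structure is learnable: median AUC >= 0.8."""
        aucs = []
        for seed in range(10):
            g = planted_two_community_graph(n_per=30, p_in=0.4, p_out=0.01,
                                            seed=seed)
            rep = evaluate_link_prediction(
                g, operators=("hadamard",), mode="holdout", seed=seed,
                num_walks=10, walk_length=20, dim=32, window=4, epochs=4)
            aucs.append(rep.auc["hadamard"])
        assert float(np.median(aucs)) >= 0.8

    def test_single_operator_report(self):
        g = nx.gnp_random_graph(20, 0.3, seed=11)
        rep = evaluate_link_prediction(g, operators=("average",), seed=0,
                                       num_walks=5, walk_length=10, dim=8,
                                       window=3, epochs=2)
        assert list(rep.auc) == ["average"]
        assert rep.best_operator == "average"
        assert len(rep.to_frame()) == 1

    def test_full_graph_mode_warns_about_leakage(self):
        g = nx.gnp_random_graph(20, 0.3, seed=12)
        with pytest.warns(UserWarning, match="optimistic"):
            evaluate_link_prediction(g, operators=("hadamard",),
                                     mode="full", seed=0, num_walks=5,
                                     walk_length=10, dim=8, window=3,
                                     epochs=2)

    def test_holdout_not_above_full_graph_mode_typically(self):
        """Full-graph embeddings leak test edges, so their AUC wins mostly."""
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            g = planted_two_community_graph(n_per=20, p_in=0.35, p_out=0.03,
                                            seed=300 + seed)
            kw = dict(operators=("hadamard",), seed=seed, num_walks=8,
                      walk_length=15, dim=16, window=4, epochs=3)
            hold = evaluate_link_prediction(g, mode="holdout", **kw)
            with pytest.warns(UserWarning):
                full = evaluate_link_prediction(g, mode="full", **kw)
            wins += full.auc["hadamard"] >= hold.auc["hadamard"]
        assert wins >= 0.7 * n_seeds


class TestNextTF:
    @staticmethod
    def _emb(vectors: dict) -> EmbeddingMatrix:
        nodes = sorted(vectors)
        return EmbeddingMatrix(nodes=nodes,
                               matrix=np.array([vectors[n] for n in nodes],
                                               dtype=float))

    def test_exhausted_candidates_empty(self):
        emb = self._emb({"A": [1, 0], "B": [0, 1]})
        out = predict_next_tf(emb, ["A", "B"])
        assert len(out) == 0

    def test_identical_embedding_ranks_first(self):
        emb = self._emb({"A": [1, 0], "B": [1, 0], "C": [0, 1]})
        out = predict_next_tf(emb, ["A"], top_k=2)
        assert out.iloc[0]["TF"] == "B"
        assert out.iloc[0]["similarity"] == pytest.approx(1.0)

    def test_missing_prefix_tf_rejected(self):
        emb = self._emb({"A": [1, 0]})
        with pytest.raises(KeyError):
            predict_next_tf(emb, ["A", "Z"])

    def test_planted_chain_successor_ranks_highly(self):
        """On a chain-rich graph the true next TF lands in the top 20%."""
        ranks = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            g = nx.Graph()
            chain = [f"C{i}" for i in range(6)]
            nx.add_path(g, chain)
            others = [f"X{i}" for i in range(24)]
            for x in others:
                a, b = rng.choice(others, size=2, replace=False)
                g.add_edge(x, a) if x != a else None
                g.add_edge(x, b) if x != b else None
            g.remove_edges_from(nx.selfloop_edges(g))
            corpus = random_walks(g, num_walks=10, walk_length=20, seed=seed)
            emb = train_embeddings(corpus, dim=16, window=4, epochs=4,
                                   seed=seed)
            out = predict_next_tf(emb, chain[:3], top_k=len(g))
            pos = out.index[out["TF"] == chain[3]][0] + 1
            ranks.append(pos / len(out))
        assert float(np.median(ranks)) <= 0.2


class TestShuffledLabels:
    def test_auc_centres_on_half_under_label_shuffle(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(0)
        aucs = []
        for seed in range(20):
            g = planted_two_community_graph(n_per=15, p_in=0.4, p_out=0.05,
                                            seed=seed)
            rep_rng = np.random.default_rng(seed)
            split = split_edges(g, seed=seed)
            corpus = random_walks(g, num_walks=5, walk_length=10, seed=seed)
            emb = train_embeddings(corpus, dim=8, window=3, epochs=2,
                                   seed=seed)
            from tfcascade.linkpred import _features
            from sklearn.linear_model import LogisticRegression
            X_tr = _features(split.train_pos + split.train_neg, emb,
                             "hadamard")
            y_tr = [1] * len(split.train_pos) + [0] * len(split.train_neg)
            X_te = _features(split.test_pos + split.test_neg, emb, "hadamard")
            y_te = np.array([1] * len(split.test_pos)
                            + [0] * len(split.test_neg))
            rep_rng.shuffle(y_te)
            if len(set(y_te)) < 2:
                continue
            clf = LogisticRegression(max_iter=1000).fit(X_tr, y_tr)
            aucs.append(roc_auc_score(y_te, clf.predict_proba(X_te)[:, 1]))
        assert abs(float(np.mean(aucs)) - 0.5) <= 0.1
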