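"""Vectorization, NMF factorization, coherence/silhouette and selection."""

import math

import numpy as np
import pytest
import scipy.sparse as sp

from contratopics.synth import GeneratorConfig, generate_corpus
from contratopics.textprep import TokenStream, prepare_corpus
from contratopics.topics import (UNASSIGNED, DocumentTermMatrix, build_tfidf,
                                 coherence_score, dominant_topic, fit_nmf,
                                 select_model, silhouette_on_topics,
                                 top_terms)


def streams_of(*docs):
    return [TokenStream(str(i), tuple(d)) for i, d in enumerate(docs)]


def brute_force_tfidf(docs):
    """Independent recomputation of tf * (ln((1+N)/(1+df)) + 1), L2 rows."""
    vocab = sorted({t for d in docs for t in d})
    n = len(docs)
    df = {t: sum(t in set(d) for d in docs) for t in vocab}
    A = np.zeros((n, len(vocab)))
    for i, d in enumerate(docs):
        for j, t in enumerate(vocab):
            tf = d.count(t)
            A[i, j] = tf * (math.log((1 + n) / (1 + df[t])) + 1)
        norm = np.linalg.norm(A[i])
        if norm > 0:
            A[i] /= norm
    return A, vocab


class TestBuildTfidf:
    def test_single_term_corpus_is_symmetric(self):
        dtm = build_tfidf(streams_of(["x"], ["x"]), min_df=1, max_df=1.0)
        A = dtm.A.toarray()
        assert A[0, 0] == pytest.approx(A[1, 0]) == pytest.approx(1.0)

    def test_hand_example_rare_term_outweighs_common(self):
        dtm = build_tfidf(streams_of(["a", "a", "b"], ["b"]), min_df=1,
                          max_df=1.0)
        A = dtm.A.toarray()
        a, b = dtm.term_index.index("a"), dtm.term_index.index("b")
        assert A[0, a] > A[0, b]

    def test_ubiquitous_term_gets_minimum_idf(self):
        # with smoothing, a term in every document still has idf ln(1)+1 = 1
        docs = [["everywhere", f"rare{i}"] for i in range(4)]
        dtm = build_tfidf(streams_of(*docs), min_df=1, max_df=1.0)
        A, vocab = brute_force_tfidf(docs)
        got = dtm.A.toarray()[:, [dtm.term_index.index(t) for t in vocab]]
        np.testing.assert_allclose(got, A, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_corpora(self, seed):
        rng = np.random.default_rng(seed)
        words = [f"w{i}" for i in range(12)]
        docs = [[words[j] for j in rng.integers(0, 12, size=rng.integers(3, 15))]
                for _ in range(10)]
        dtm = build_tfidf(streams_of(*docs), min_df=1)
        A, vocab = brute_force_tfidf(docs)
        assert dtm.term_index == vocab
        np.testing.assert_allclose(dtm.A.toarray(), A, atol=1e-12)

    def test_df_pruning_bounds_vocabulary(self):
        # "common" sits in all 10 docs (> 95%), "rare" in one (< min_df),
        # "mid" in half of them (kept)
        docs = [["common", "mid"] if i < 5 else ["common", "pad"]
                for i in range(10)]
        docs[0] = docs[0] + ["rare"]
        dtm = build_tfidf(streams_of(*docs), min_df=2, max_df=0.95)
        assert "common" not in dtm.term_index
        assert "rare" not in dtm.term_index
        assert "mid" in dtm.term_index and "pad" in dtm.term_index

    def test_empty_vocabulary_is_fatal_with_diagnostic(self):
        with pytest.raises(ValueError, match="empty vocabulary"):
            build_tfidf(streams_of(["a"], ["b"]), min_df=3)


class TestFitNmf:
    def test_rank_one_matrix_recovered_exactly(self):
        rng = np.random.default_rng(0)
        u, v = rng.random(15) + 0.1, rng.random(25) + 0.1
        A = np.outer(u, v)
        m = fit_nmf(A, k=1, seed=0, max_iter=2000, tol=1e-14)
        rel_err = np.linalg.norm(A - m.W @ m.H) / np.linalg.norm(A)
        assert rel_err < 1e-6

    def test_objective_trace_never_increases(self):
        rng = np.random.default_rng(1)
        A = rng.random((20, 30))
        m = fit_nmf(A, k=4, seed=3, max_iter=200, tol=0)
        tr = np.array(m.objective_trace)
        assert np.all(np.diff(tr) <= 1e-9 * tr[0])

    def test_identical_seed_identical_model(self):
        rng = np.random.default_rng(2)
        A = sp.csr_matrix(rng.random((15, 12)))
        m1 = fit_nmf(A, k=3, seed=7)
        m2 = fit_nmf(A, k=3, seed=7)
        np.testing.assert_array_equal(m1.W, m2.W)
        np.testing.assert_array_equal(m1.H, m2.H)
        assert m1.objective_trace == m2.objective_trace

    def test_factors_nonnegative_and_h_rows_unit_norm(self):
        rng = np.random.default_rng(3)
        A = rng.random((30, 20))
        m = fit_nmf(A, k=5, seed=0)
        assert np.all(m.W >= 0) and np.all(m.H >= 0)
        np.testing.assert_allclose(np.linalg.norm(m.H, axis=1), 1.0,
                                   atol=1e-8)

    def test_renormalization_preserves_reconstruction(self):
        # the unit-norm-H convention rescales (W, H) without changing WH:
        # the final traced objective must match the returned factors exactly
        rng = np.random.default_rng(4)
        A = rng.random((25, 18))
        m = fit_nmf(A, k=4, seed=1, max_iter=100, tol=0)
        err = np.linalg.norm(A - m.W @ m.H) ** 2
        assert err == pytest.approx(m.objective_trace[-1], rel=1e-8)

    def test_invalid_k_and_zero_matrix_fatal(self):
        with pytest.raises(ValueError, match="k="):
            fit_nmf(np.ones((3, 4)), k=5)
        with pytest.raises(ValueError, match="all-zero"):
            fit_nmf(np.zeros((3, 4)), k=2)

    def test_comparable_to_reference_nmf(self):
        # independent cross-check: sklearn's NMF on the same matrix should
        # reach a similar Frobenius objective
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(5)
        A = rng.random((40, 30))
        ours = fit_nmf(A, k=5, seed=0, max_iter=1000, tol=1e-9)
        err_ours = np.linalg.norm(A - ours.W @ ours.H)
        ref = NMF(n_components=5, solver="mu", max_iter=1000, tol=1e-9,
                  init="random", random_state=0).fit(A)
        err_ref = np.linalg.norm(A - ref.transform(A) @ ref.components_)
        assert err_ours <= err_ref * 1.05


class TestDominantTopic:
    def test_argmax_tie_and_sentinel(self):
        W = np.array([[0.1, 0.7, 0.2],
                      [0.5, 0.5, 0.0],
                      [0.0, 0.0, 0.0]])
        labels = dominant_topic(W)
        assert labels.tolist() == [1, 0, UNASSIGNED]


class TestTopTerms:
    def test_descending_order_and_alphabetical_ties(self):
        H = np.array([[0.5, 0.2, 0.5, 0.1]])
        terms = top_terms(H, ["zeta", "mid", "alpha", "low"], n=3)
        assert terms == [["alpha", "zeta", "mid"]]

    def test_n_truncated_to_vocabulary(self):
        H = np.array([[0.5, 0.1]])
        assert top_terms(H, ["a", "b"], n=10) == [["a", "b"]]

    def test_planted_lexicons_dominate_top_terms(self):
        from contratopics import resources

        cfg = GeneratorConfig(n_reviews=400, k_topics=4, separation=0.95,
                              seed=11)
        rev, truth = generate_corpus(cfg)
        unfav = rev[rev.rating <= 5]
        streams, _ = prepare_corpus(list(zip(unfav.uniqueID, unfav.review)))
        dtm = build_tfidf(streams, min_df=2)
        m = fit_nmf(dtm, 4, seed=0)
        lex = resources.default_topic_lexicons()
        for terms in top_terms(m.H, dtm.term_index, n=5):
            hits = max(sum(t in set(lex[name]) for t in terms)
                       for name in cfg.topic_names)
            assert hits >= 4  # >= 4 of 5 top terms from one planted lexicon


class TestCoherence:
    def test_always_cooccurring_pair_scores_positive(self):
        docs = streams_of(*[["w1", "w2"] for _ in range(5)])
        scores, mean = coherence_score([["w1", "w2"]], docs)
        assert scores[0] == pytest.approx(math.log(6 / 5))
        assert mean > 0

    def test_never_cooccurring_pair_scores_negative(self):
        docs = streams_of(["w1"], ["w1"], ["w1"], ["w2"])
        scores, _ = coherence_score([["w1", "w2"]], docs)
        # D(w1) = 3, no co-occurrence: ln(1/3)
        assert scores[0] == pytest.approx(math.log(1 / 3))

    def test_absent_conditioning_term_pair_skipped(self):
        docs = streams_of(["w1"])
        scores, _ = coherence_score([["ghost", "w1"]], docs)
        assert scores[0] == 0.0  # the (w1 | ghost) pair cannot be scored

    def test_planted_k_more_coherent_than_doubled_k(self):
        cfg = GeneratorConfig(n_reviews=600, k_topics=3, separation=0.95,
                              seed=13)
        rev, _ = generate_corpus(cfg)
        unfav = rev[rev.rating <= 5]
        streams, _ = prepare_corpus(list(zip(unfav.uniqueID, unfav.review)))
        dtm = build_tfidf(streams, min_df=2)

        def mean_coh(k):
            m = fit_nmf(dtm, k, seed=0)
            _, mean = coherence_score(top_terms(m.H, dtm.term_index, 10),
                                      streams)
            return mean

        assert mean_coh(3) > mean_coh(6)


class TestSilhouette:
    def test_orthogonal_groups_near_one(self):
        rng = np.random.default_rng(0)
        W = np.zeros((40, 2))
        W[:20, 0] = 1 + 0.01 * rng.random(20)
        W[20:, 1] = 1 + 0.01 * rng.random(20)
        labels = dominant_topic(W)
        assert silhouette_on_topics(W, labels) > 0.9

    def test_single_cluster_returns_sentinel(self):
        W = np.ones((5, 2))
        assert math.isnan(silhouette_on_topics(W, np.zeros(5, dtype=int)))

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(42)
        W = rng.random((200, 4))
        labels = rng.integers(0, 4, size=200)
        assert abs(silhouette_on_topics(W, labels)) < 0.2


class TestSelectModel:
    def test_singleton_grid_returns_that_k(self):
        rng = np.random.default_rng(1)
        docs = [[f"w{j}" for j in rng.integers(0, 10, size=8)]
                for _ in range(20)]
        streams = streams_of(*docs)
        dtm = build_tfidf(streams, min_df=1)
        report = select_model(dtm, streams, k_grid=[2], seeds=(0,))
        assert report.chosen_k == 2

    def test_deterministic_given_seeds(self):
        rng = np.random.default_rng(2)
        docs = [[f"w{j}" for j in rng.integers(0, 12, size=10)]
                for _ in range(25)]
        streams = streams_of(*docs)
        dtm = build_tfidf(streams, min_df=1)
        r1 = select_model(dtm, streams, k_grid=[2, 3], seeds=(0, 1))
        r2 = select_model(dtm, streams, k_grid=[2, 3], seeds=(0, 1))
        assert r1.chosen_k == r2.chosen_k
        assert r1.to_frame().equals(r2.to_frame())


class TestPersistence:
    def test_dtm_and_model_round_trip(self, tmp_path):
        docs = streams_of(["a", "b", "a"], ["b", "c"], ["a", "c", "c"])
        dtm = build_tfidf(docs, min_df=1)
        dtm.save(tmp_path / "dtm")
        back = DocumentTermMatrix.load(tmp_path / "dtm")
        np.testing.assert_allclose(back.A.toarray(), dtm.A.toarray())
        assert back.term_index == dtm.term_index
        assert back.doc_index == dtm.doc_index

        m = fit_nmf(dtm, 2, seed=0)
        m.save(tmp_path / "model")
        from contratopics.topics import TopicModel
        m2 = TopicModel.load(tmp_path / "model")
        np.testing.assert_allclose(m2.W, m.W, atol=1e-12)
        np.testing.assert_allclose(m2.H, m.H, atol=1e-12)
        assert m2.k == m.k and m2.seed == m.seed
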