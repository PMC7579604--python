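"""Embedding training, TF-IDF formulas, and narrative vector properties."""

import math

import numpy as np
import pytest

from mineinjury.narrative_vectors import (
    EmbeddingModel,
    EmbeddingParams,
    TfidfStats,
    compute_tfidf,
    nearest_neighbors,
    score,
    train_embedding,
    vectorize_corpus,
    vectorize_narrative,
)
from tests.conftest import FAST_EMBEDDING


def _toy_model(tokens_vectors: dict[str, list[float]]) -> EmbeddingModel:
    tokens = list(tokens_vectors)
    mat = np.array([tokens_vectors[t] for t in tokens], dtype=np.float32)
    return EmbeddingModel(mat.shape[1], tokens, mat, EmbeddingParams(dimension=mat.shape[1]))


def _cos(model, a, b):
    va, vb = model.vector(a), model.vector(b)
    return float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))


class TestTrainEmbedding:
    def test_cooccurring_tokens_closer_than_strangers(self):
        """Tokens that always share a context should end up more similar than
        tokens that never do, for a majority of seeds."""
        docs = ([["x", "y", "a"], ["x", "y", "b"], ["x", "y", "c"],
                 ["z", "w", "d"], ["z", "w", "e"]] * 30)
        wins = 0
        for seed in range(5):
            m = train_embedding(docs, EmbeddingParams(dimension=16, epochs=20, seed=seed))
            wins += _cos(m, "x", "y") > _cos(m, "x", "z")
        assert wins >= 3

    def test_default_dimension_is_300(self):
        m = train_embedding([["alpha", "beta"], ["beta", "gamma"]], EmbeddingParams(epochs=1))
        assert m.dimension == 300
        assert all(len(m.vector(t)) == 300 for t in m.tokens)

    def test_min_count_excludes_rare_tokens(self):
        docs = [["common", "common", "rare"], ["common", "other", "other"]]
        m = train_embedding(docs, EmbeddingParams(dimension=8, epochs=1, min_count=2))
        assert "common" in m and "other" in m and "rare" not in m

    def test_seed_reproducibility(self):
        docs = [["a", "b", "c"], ["b", "c", "d"]] * 10
        p = EmbeddingParams(dimension=8, epochs=3, seed=5)
        m1, m2 = train_embedding(docs, p), train_embedding(docs, p)
        np.testing.assert_array_equal(m1.matrix, m2.matrix)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty corpus"):
            train_embedding([], FAST_EMBEDDING)

    def test_skipgram_architecture_trains(self):
        docs = [["a", "b"], ["a", "c"]] * 20
        m = train_embedding(docs, EmbeddingParams(architecture="skipgram", dimension=8, epochs=2))
        assert set(m.tokens) == {"a", "b", "c"}

    def test_word2vec_text_round_trip(self, tmp_path):
        m = train_embedding([["a", "b", "c"]] * 5, EmbeddingParams(dimension=4, epochs=1))
        path = tmp_path / "vecs.txt"
        m.save_word2vec_text(path)
        back = EmbeddingModel.load_word2vec_text(path)
        assert back.tokens == m.tokens
        np.testing.assert_allclose(back.matrix, m.matrix, rtol=1e-4)


class TestNearestNeighbors:
    def test_cosine_order_and_self_exclusion(self):
        m = _toy_model({"q": [1, 0], "near": [2, 0.1], "far": [-1, 0], "mid": [1, 1]})
        assert nearest_neighbors(m, "q", 2) == ["near", "mid"]

    def test_lexicographic_tie_break(self):
        m = _toy_model({"q": [1, 0], "bb": [2, 0], "aa": [3, 0], "cc": [-1, 0]})
        assert nearest_neighbors(m, "q", 2) == ["aa", "bb"]  # both cosine 1.0

    def test_unknown_token(self):
        m = _toy_model({"a": [1.0]})
        with pytest.raises(KeyError):
            nearest_neighbors(m, "zzz", 1)


class TestTfidf:
    def test_hand_computed_scores(self):
        stats = compute_tfidf([["a", "b", "a"], ["a", "c"]])
        assert stats.n_docs == 2
        assert stats.doc_freq == {"a": 2, "b": 1, "c": 1}
        # "a" appears in both docs: idf = log(2/2) = 0 -> score 0
        assert score(stats, "a", ["a", "b", "a"]) == pytest.approx(0.0)
        # "b" in 1 of 2 docs: tf = 1/3, idf = log 2
        assert score(stats, "b", ["a", "b", "a"]) == pytest.approx(math.log(2) / 3)

    def test_idf_of_singleton_token(self):
        stats = compute_tfidf([["t"]] + [["x"]] * 9)
        assert stats.idf("t") == pytest.approx(math.log(10))

    def test_tf_of_whole_narrative(self):
        stats = compute_tfidf([["solo"], ["other"]])
        assert score(stats, "solo", ["solo"]) == pytest.approx(1.0 * math.log(2))

    def test_unknown_token_scores_zero(self):
        stats = compute_tfidf([["a"], ["b"]])
        assert score(stats, "zzz", ["a"]) == 0.0

    def test_empty_narrative_rejected(self):
        stats = compute_tfidf([["a"]])
        with pytest.raises(ValueError):
            score(stats, "a", [])


class TestVectorize:
    def test_single_token_gives_weight_times_vector(self):
        m = _toy_model({"u": [1.0, 2.0, 3.0], "pad": [0.0, 0.0, 0.0]})
        stats = TfidfStats(n_docs=4, doc_freq={"u": 1})
        out = vectorize_narrative(["u"], m, stats)
        w = 1.0 * math.log(4)
        np.testing.assert_allclose(out, w * np.array([1.0, 2.0, 3.0]))

    def test_two_tokens_same_vector_average_weights(self):
        m = _toy_model({"s": [2.0, 0.0], "t": [2.0, 0.0]})
        stats = TfidfStats(n_docs=8, doc_freq={"s": 1, "t": 2})
        out = vectorize_narrative(["s", "t"], m, stats)
        w1 = 0.5 * math.log(8)
        w2 = 0.5 * math.log(4)
        np.testing.assert_allclose(out, ((w1 + w2) / 2) * np.array([2.0, 0.0]))

    def test_oov_tokens_skipped_and_excluded_from_divisor(self):
        m = _toy_model({"known": [4.0]})
        stats = TfidfStats(n_docs=2, doc_freq={"known": 1, "oov": 1})
        out = vectorize_narrative(["known", "oov"], m, stats)
        np.testing.assert_allclose(out, [0.5 * math.log(2) * 4.0])  # divisor 1, tf 1/2

    def test_all_oov_gives_zero_vector_with_flag(self):
        m = _toy_model({"known": [1.0, 1.0]})
        stats = TfidfStats(n_docs=2, doc_freq={})
        mat, empty = vectorize_corpus([["zzz", "qqq"], ["known"]], m, stats)
        np.testing.assert_array_equal(mat[0], [0.0, 0.0])
        assert empty.tolist() == [True, False]

    def test_empty_narrative_gives_zero_vector(self):
        m = _toy_model({"a": [1.0]})
        out = vectorize_narrative([], m, TfidfStats(1, {"a": 1}))
        np.testing.assert_array_equal(out, [0.0])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        tokens = list("abcdef")
        m = _toy_model({t: rng.standard_normal(5).tolist() for t in tokens})
        stats = compute_tfidf([tokens[:3], tokens[2:], tokens])
        doc = ["a", "c", "e", "c", "f"]
        base = vectorize_narrative(doc, m, stats)
        for _ in range(5):
            shuffled = list(rng.permutation(doc))
            np.testing.assert_allclose(vectorize_narrative(shuffled, m, stats), base)

    def test_linearity_in_tfidf_weights(self):
        """Scaling every idf (hence every tf-idf weight) by c scales the vector by c."""
        m = _toy_model({"a": [1.0, 0.5], "b": [0.0, 2.0]})
        stats = TfidfStats(n_docs=4, doc_freq={"a": 1, "b": 2})
        scaled = TfidfStats(n_docs=16, doc_freq={"a": 1, "b": 4})  # idf doubled for both
        doc = ["a", "b"]
        np.testing.assert_allclose(
            vectorize_narrative(doc, m, scaled), 2.0 * vectorize_narrative(doc, m, stats)
        )

    def test_output_dimension_matches_embedding(self):
        docs = [["alpha", "beta", "gamma"]] * 4
        m = train_embedding(docs, FAST_EMBEDDING)
        stats = compute_tfidf(docs)
        mat, _ = vectorize_corpus(docs, m, stats)
        assert mat.shape == (4, FAST_EMBEDDING.dimension)
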