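import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from drugchatter import (
    CorpusSpec,
    EmbeddingModel,
    Hyperparams,
    PlantedPair,
    cosine_similarity,
    generate_corpus,
    load_word2vec_text,
    nearest_neighbors,
    preprocess,
    save_word2vec_text,
    train_skipgram,
)

SMALL_HP = Hyperparams(d=8, window=2, negatives=3, epochs=2, seed=7)


@pytest.fixture(scope="module")
def planted_model():
    spec = CorpusSpec(
        seed=3,
        n_tweets=500,
        drugs=("drugx",),
        drug_mention_rate=0.5,
        misspelling_rate=0.0,
        planted_pairs=[PlantedPair("drugx", "nausea", 1.0)],
        background_terms=["umbrella"],
        background_term_rate=0.3,
    )
    tweets, _ = generate_corpus(spec)
    corpus = [preprocess(t.text) for t in tweets]
    return train_skipgram(corpus, Hyperparams(d=16, window=2, epochs=5, seed=1))


class TestTrainSkipgram:
    def test_vector_shape_matches_hyperparams(self, tiny_token_corpus):
        model = train_skipgram(tiny_token_corpus, SMALL_HP)
        assert model.vectors.shape == (len(model.vocabulary), SMALL_HP.d)

    def test_same_seed_bitwise_identical(self, tiny_token_corpus):
        m1 = train_skipgram(tiny_token_corpus, SMALL_HP)
        m2 = train_skipgram(tiny_token_corpus, SMALL_HP)
        assert m1.vocabulary == m2.vocabulary
        assert np.array_equal(m1.vectors, m2.vectors)

    def test_different_seed_differs(self, tiny_token_corpus):
        m1 = train_skipgram(tiny_token_corpus, SMALL_HP)
        m2 = train_skipgram(tiny_token_corpus, SMALL_HP, seed=8)
        assert not np.array_equal(m1.vectors, m2.vectors)

    def test_vectors_finite(self, tiny_token_corpus):
        model = train_skipgram(tiny_token_corpus, SMALL_HP)
        assert np.isfinite(model.vectors).all()

    def test_empty_after_pruning_rejected(self):
        with pytest.raises(ValueError):
            train_skipgram([["a", "b"]], SMALL_HP, min_count=5)

    def test_planted_pair_beats_non_cooccurring(self, planted_model):
        m = planted_model
        planted = cosine_similarity(m.vector("drugx"), m.vector("nausea"))
        control = cosine_similarity(m.vector("drugx"), m.vector("umbrella"))
        assert planted > control


class TestCosineSimilarity:
    @pytest.mark.parametrize(
        "u,v,expected",
        [((1, 0), (0, 1), 0.0), ((1, 2), (2, 4), 1.0), ((1, 1), (1, -1), 0.0)],
    )
    def test_known_values(self, u, v, expected):
        assert cosine_similarity(np.array(u, float), np.array(v, float)) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(3), np.ones(3))

    @given(
        hnp.arrays(np.float64, 4, elements=st.floats(-5, 5)),
        hnp.arrays(np.float64, 4, elements=st.floats(-5, 5)),
        st.floats(0.1, 10),
    )
    def test_symmetric_and_scale_invariant(self, u, v, scale):
        if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
            return
        s = cosine_similarity(u, v)
        assert -1.0 - 1e-9 <= s <= 1.0 + 1e-9
        assert cosine_similarity(v, u) == pytest.approx(s)
        assert cosine_similarity(scale * u, v) == pytest.approx(s, abs=1e-9)


class TestNearestNeighbors:
    def test_two_token_vocabulary_forced(self):
        model = EmbeddingModel(["a", "b"], np.array([[1.0, 0.0], [1.0, 1.0]]))
        assert nearest_neighbors(model, "a", k=1)[0][0] == "b"

    def test_similarities_non_increasing(self, tiny_token_corpus):
        model = train_skipgram(tiny_token_corpus, SMALL_HP)
        sims = [s for _, s in nearest_neighbors(model, "a", k=4)]
        assert sims == sorted(sims, reverse=True)

    def test_query_token_excluded(self, tiny_token_corpus):
        model = train_skipgram(tiny_token_corpus, SMALL_HP)
        assert "a" not in [t for t, _ in nearest_neighbors(model, "a", k=10)]

    def test_oov_token_named_in_error(self, tiny_token_corpus):
        model = train_skipgram(tiny_token_corpus, SMALL_HP)
        with pytest.raises(KeyError, match="zzz"):
            nearest_neighbors(model, "zzz", k=1)

    def test_planted_term_in_top_neighbors(self):
        # focused corpus: drug and reaction share a small context vocabulary
        rng = np.random.default_rng(0)
        ctx, fill = ["took", "dose", "feel"], ["rain", "game", "road", "song"]
        sents = []
        for i in range(300):
            if i % 2 == 0:
                a, b = rng.choice(ctx, 2, replace=False)
                sents.append([str(a), "drugx", "nausea", str(b)])
            else:
                sents.append([str(w) for w in rng.choice(fill, 4)])
        model = train_skipgram(sents, Hyperparams(d=16, window=2, epochs=5, seed=1))
        assert "nausea" in [t for t, _ in nearest_neighbors(model, "drugx", k=3)]

    def test_planted_term_outranks_control_in_full_ranking(self, planted_model):
        ranking = [t for t, _ in nearest_neighbors(planted_model, "drugx", k=len(planted_model.vocabulary))]
        assert ranking.index("nausea") < ranking.index("umbrella")


class TestWord2VecText:
    def test_round_trip_within_tolerance(self, tiny_token_corpus, tmp_path):
        model = train_skipgram(tiny_token_corpus, SMALL_HP)
        path = tmp_path / "vec.txt"
        save_word2vec_text(model, path)
        back = load_word2vec_text(path)
        assert back.vocabulary == model.vocabulary
        assert np.abs(back.vectors - model.vectors).max() < 1e-6

    def test_header_matches_body(self, tiny_token_corpus, tmp_path):
        path = tmp_path / "vec.txt"
        save_word2vec_text(train_skipgram(tiny_token_corpus, SMALL_HP), path)
        lines = path.read_text().strip().splitlines()
        v, d = map(int, lines[0].split())
        assert len(lines) - 1 == v
        assert all(len(l.split()) == d + 1 for l in lines[1:])

    def test_hand_written_file_reproduced(self, tmp_path):
        path = tmp_path / "vec.txt"
        path.write_text("2 3\nalpha 1.0 2.0 3.0\nbeta -1.0 0.5 0.25\n", encoding="utf-8")
        model = load_word2vec_text(path)
        assert model.vocabulary == ["alpha", "beta"]
        assert model.vector("beta").tolist() == [-1.0, 0.5, 0.25]

    def test_dimension_mismatch_names_line(self, tmp_path):
        path = tmp_path / "vec.txt"
        path.write_text("2 3\nalpha 1.0 2.0 3.0\nbeta -1.0 0.5\n", encoding="utf-8")
        with pytest.raises(ValueError, match="line 3"):
            load_word2vec_text(path)
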