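import math
import random

import pytest

from drugchatter import NGramModel, export_arpa, import_arpa, train_ngram
from drugchatter.ngram_lm import BOS, EOS, UNK


def random_corpus(rng, vocab="abcde", n_sent=6, max_len=8):
    return [
        [rng.choice(vocab) for _ in range(rng.randint(1, max_len))]
        for _ in range(rng.randint(1, n_sent))
    ]


class TestTraining:
    def test_mle_bigram_hand_counts(self):
        m = train_ngram([["a", "b", "a", "b", "a"]], n=2, mode="mle")
        assert m.cond_prob("b", ("a",)) == pytest.approx(2 / 3)
        assert m.cond_prob("a", ("b",)) == pytest.approx(1.0)

    def test_deterministic(self, tiny_token_corpus):
        m1 = train_ngram(tiny_token_corpus, n=3)
        m2 = train_ngram(tiny_token_corpus, n=3)
        for gram in m1.counts[3]:
            assert m1.cond_prob(gram[-1], gram[:-1]) == m2.cond_prob(gram[-1], gram[:-1])

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_ngram([], n=2)

    @pytest.mark.parametrize("n", [1, 5])
    def test_order_out_of_range_rejected(self, n):
        with pytest.raises(ValueError):
            train_ngram([["a", "b"]], n=n)

    def test_min_count_maps_rare_tokens_to_unk(self):
        m = train_ngram([["a", "a", "a", "rare"]], n=2, min_count=2)
        assert "rare" not in m.vocab and UNK in m.vocab


class TestConditionalProbability:
    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_normalizes_over_every_observed_context(self, tiny_token_corpus, n):
        m = train_ngram(tiny_token_corpus, n=n)
        contexts = {g[:-1] for g in m.counts[n]}
        for ctx in contexts:
            assert sum(m.cond_prob(w, ctx) for w in m.predict_vocab) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_normalizes_on_random_corpora(self, n):
        rng = random.Random(1234)
        for _ in range(10):
            m = train_ngram(random_corpus(rng), n=n)
            for ctx in {g[:-1] for g in m.counts[n]}:
                total = sum(m.cond_prob(w, ctx) for w in m.predict_vocab)
                assert total == pytest.approx(1.0, abs=1e-6)

    def test_probabilities_strictly_positive(self, tiny_token_corpus):
        m = train_ngram(tiny_token_corpus, n=3)
        for w in list(m.predict_vocab) + ["never-seen"]:
            p = m.cond_prob(w, ("a", "b"))
            assert 0.0 < p <= 1.0

    def test_unseen_context_backs_off_to_lower_order(self, tiny_token_corpus):
        m = train_ngram(tiny_token_corpus, n=3)
        assert ("e", "e") not in {g[:-1] for g in m.counts[3]}
        # unseen history: full weight passes to the continuation estimate
        assert m.cond_prob("a", ("e", "e")) == pytest.approx(m.cond_prob("a", ("e",)))

    def test_context_truncated_to_model_order(self, tiny_token_corpus):
        m = train_ngram(tiny_token_corpus, n=2)
        assert m.cond_prob("b", ("x", "y", "a")) == m.cond_prob("b", ("a",))


class TestSequenceScoring:
    def test_single_sentence_corpus_reproduces_itself(self):
        m = train_ngram([["a", "b"]], n=2, mode="mle")
        assert math.exp(m.sequence_logprob(["a", "b"])) == pytest.approx(1.0)

    def test_one_token_chain_rule(self, tiny_token_corpus):
        m = train_ngram(tiny_token_corpus, n=2)
        expected = math.log(m.cond_prob("a", (BOS,))) + math.log(m.cond_prob(EOS, ("a",)))
        assert m.sequence_logprob(["a"]) == pytest.approx(expected)

    def test_prefix_logprob_monotone_in_appended_tokens(self, tiny_token_corpus):
        # each appended token multiplies in a factor <= 1
        m = train_ngram(tiny_token_corpus, n=3)
        tokens = ["a", "b", "c", "zzz", "a"]
        padded = [BOS] * 2 + tokens
        prefix_lp, prev = 0.0, 0.0
        for i in range(2, len(padded)):
            prefix_lp += math.log(m.cond_prob(padded[i], tuple(padded[i - 2 : i])))
            assert prefix_lp <= prev + 1e-12
            prev = prefix_lp
        # terminating with the end marker only lowers the score further
        assert m.sequence_logprob(tokens) <= prefix_lp + 1e-12

    def test_uniform_branching_perplexity_closed_form(self):
        # four equiprobable one-token sentences: P(x|start)=1/4, P(end|x)=1,
        # two transitions each -> perplexity sqrt(4) = 2
        m = train_ngram([["a"], ["b"], ["c"], ["d"]], n=2, mode="mle")
        assert m.perplexity([["a"], ["b"], ["c"], ["d"]]) == pytest.approx(2.0)

    def test_perplexity_at_least_one(self, tiny_token_corpus):
        m = train_ngram(tiny_token_corpus, n=2)
        assert m.perplexity(tiny_token_corpus) >= 1.0

    def test_higher_order_fits_training_corpus_no_worse(self, tiny_token_corpus):
        m2 = train_ngram(tiny_token_corpus, n=2)
        m4 = train_ngram(tiny_token_corpus, n=4)
        assert m4.perplexity(tiny_token_corpus) <= m2.perplexity(tiny_token_corpus)

    def test_empty_corpus_perplexity_rejected(self, tiny_token_corpus):
        m = train_ngram(tiny_token_corpus, n=2)
        with pytest.raises(ValueError):
            m.perplexity([])


class TestArpa:
    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_round_trip_preserves_probabilities(self, tiny_token_corpus, tmp_path, n):
        m = train_ngram(tiny_token_corpus, n=n)
        path = tmp_path / "m.arpa"
        export_arpa(m, path)
        m2 = import_arpa(path)
        queries = [(g[-1], g[:-1]) for g in m.counts[n]]
        queries += [("zzz", ("a",) * (n - 1)), ("a", ("zzz",) * (n - 1)), ("e", ())]
        for w, ctx in queries:
            assert m2.cond_prob(w, ctx) == pytest.approx(m.cond_prob(w, ctx), abs=1e-6)

    def test_declared_counts_match_sections(self, tiny_token_corpus, tmp_path):
        path = tmp_path / "m.arpa"
        export_arpa(train_ngram(tiny_token_corpus, n=3), path)
        lines = path.read_text().splitlines()
        declared = {int(l.split()[1].split("=")[0]): int(l.split("=")[1]) for l in lines if l.startswith("ngram")}
        for k, cnt in declared.items():
            start = lines.index(f"\\{k}-grams:") + 1
            body = 0
            for line in lines[start:]:
                if not line.strip() or line.startswith("\\"):
                    break
                body += 1
            assert body == cnt

    def test_hand_written_unigram_file(self, tmp_path):
        path = tmp_path / "uni.arpa"
        path.write_text(
            "\\data\\\nngram 1=2\n\n\\1-grams:\n-0.301030\tyes\n-0.698970\tno\n\n\\end\\\n",
            encoding="utf-8",
        )
        m = import_arpa(path)
        assert m.cond_prob("yes") == pytest.approx(10 ** -0.301030)
        assert m.cond_prob("no") == pytest.approx(10 ** -0.698970)

    def test_count_mismatch_reported(self, tmp_path):
        path = tmp_path / "bad.arpa"
        path.write_text(
            "\\data\\\nngram 1=3\n\n\\1-grams:\n-0.3\tyes\n-0.7\tno\n\n\\end\\\n",
            encoding="utf-8",
        )
        with pytest.raises(ValueError, match="declares 3"):
            import_arpa(path)

    def test_malformed_header_names_line(self, tmp_path):
        path = tmp_path / "bad.arpa"
        path.write_text("\\data\\\nnot a count line\n", encoding="utf-8")
        with pytest.raises(ValueError, match="line 2"):
            import_arpa(path)
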