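"""Train an order-4 Kneser-Ney language model and exchange it via ARPA.

Shows conditional probabilities, sentence scoring, perplexity, and that the
ARPA round trip preserves the model.
"""

import math
import tempfile
from pathlib import Path

from drugchatter import (
    CorpusSpec,
    export_arpa,
    generate_health_corpus,
    import_arpa,
    preprocess,
    train_ngram,
)

tweets, _ = generate_health_corpus(CorpusSpec(seed=30, n_tweets=1500, health_fraction=1.0))
corpus = [preprocess(t.text) for t in tweets]

model = train_ngram(corpus, n=4)
print(f"vocabulary size: {len(model.predict_vocab)}")
print(f"training perplexity (order 4): {model.perplexity(corpus[:200]):.2f}")
print(f"training perplexity (order 2): {train_ngram(corpus, n=2).perplexity(corpus[:200]):.2f}")

sent = corpus[0]
lp = model.sequence_logprob(sent)
print(f"log P({' '.join(sent[:5])}...) = {lp:.2f}  "
      f"({math.exp(lp / (len(sent) + 1)):.4f} per transition)")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "model.arpa"
    export_arpa(model, path)
    back = import_arpa(path)
    diff = abs(back.sequence_logprob(sent) - lp)
    print(f"ARPA round-trip |delta log P| = {diff:.2e}")

# the higher-order model fits its training corpus at least as tightly as the
# bigram, and the ARPA file reproduces scores to printing precision.
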