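"""Mine drug-adverse reaction association signals from word embeddings.

Generates chatter in which four reaction terms genuinely co-occur with the
drug, trains skip-gram vectors, and compares cosine similarities of known
versus non-associated terms.
"""

from drugchatter import (
    CorpusSpec,
    Hyperparams,
    PlantedPair,
    association_profile,
    generate_corpus,
    preprocess,
    separation_statistic,
    train_skipgram,
)

known = ["nausea", "headache", "dizziness", "fatigue"]
candidates = ["umbrella", "guitar", "sunset", "pizza", "soccer", "novel"]

spec = CorpusSpec(
    seed=11, n_tweets=2000, drugs=("drugx",), drug_mention_rate=0.5,
    misspelling_rate=0.1,
    planted_pairs=[PlantedPair("drugx", t, 0.8) for t in known],
    background_terms=candidates, background_term_rate=0.1,
)
tweets, _ = generate_corpus(spec)
model = train_skipgram([preprocess(t.text) for t in tweets],
                       Hyperparams(d=16, window=2, epochs=5, seed=11))

profile = association_profile(model, "drugx", known + candidates)
for s in profile:
    group = "known" if s.term.surface in known else "candidate"
    print(f"  {s.term.surface:<10} {s.score:+.3f}  ({group})")

diff, concordance = separation_statistic(profile, known, candidates)
print(f"mean(known) - mean(candidate) = {diff:+.3f}; concordance = {concordance:.2f}")

# concordance 1.0 means every known reaction scores above every candidate:
# the cosine profile alone separates planted associations from noise.
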