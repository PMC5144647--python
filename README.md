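# drugchatter

Tools for mining drug-related chatter from short social-media posts, aimed
at pharmacovigilance researchers and NLP practitioners working with noisy
user-generated health text.

People discuss prescription drugs on social media constantly — effects,
side effects, misuse — but collecting and modeling that chatter poses three
linked problems this package addresses end to end:

1. **Collection misses misspellings.** Drug names are misspelled so often
   that keyword collection by correct spellings alone loses recall. The
   `misspellings` module generates plausible misspelling variants in three
   stages: enumerate every string within Levenshtein distance 1 of the
   keyword, keep only candidates with the same phonetic code (a documented
   consonant-skeleton encoding, pluggable), and keep only candidates a
   frequency oracle attests people actually write. The `corpus` module then
   filters tweet streams against the expanded lexicon by exact-token
   matching and summarizes monthly and per-keyword counts.
2. **Sequential structure.** The `ngram_lm` module trains order-n
   (n = 2–4) language models with interpolated Kneser–Ney smoothing,
   assigning a sentence probability by the chain rule
   P(w₁…w_m) = ∏ₖ P(wₖ | wₖ₋ₙ₊₁…wₖ₋₁), with standard ARPA import/export.
   The `healthclass` module applies the tetra-gram model to score texts
   (average log-probability per transition, min–max scaled to [0,1]) and
   separate health-related from other text.
3. **Semantic structure.** The `embeddings` module trains skip-gram
   word vectors with negative sampling — maximizing P(w | t; H) for context
   words w in a symmetric window around each term t — from scratch, single
   threaded and deterministic per seed, with word2vec text interchange. The
   `adr_signal` module turns a model into drug–adverse-reaction association
   signals: the signal for (drug, term) is the cosine similarity of their
   vectors (mean over tokens for multi-word terms), and a profile over known
   vs. candidate reaction terms is summarized by mean difference and
   pairwise concordance.

Because real drug-chatter corpora cannot be redistributed, the `synthdata`
module generates tweet-like corpora with controllable mention, misspelling
and drug–reaction co-occurrence rates, per-drug topic vocabularies, and a
health/non-health vocabulary-overlap parameter — with ground-truth records —
so the whole pipeline is testable offline.

## Worked example

`examples/adr_association.py` plants four reaction terms that co-occur with
a drug (probability 0.8 per mention) in 2,000 generated tweets, six terms
that never do, trains 16-dimensional skip-gram vectors (window 2), and
prints the association profile:

```
  nausea     +0.507  (known)
  headache   +0.489  (known)
  dizziness  +0.511  (known)
  fatigue    +0.507  (known)
  umbrella   +0.145  (candidate)
  ...
mean(known) - mean(candidate) = +0.353; concordance = 1.00
```

Every planted reaction scores well above every non-associated term;
concordance 1.0 means all 24 known/candidate pairs are ordered correctly —
the cosine profile alone recovers the planted associations. The other
scripts in `examples/` demonstrate variant generation, corpus filtering,
language-model training with ARPA round-trip, and health-text
classification the same way.

A command-line interface covers the same ground for shell use, e.g.:

```sh
drugchatter simulate --seed 7 --n 1000 --pair xanax:nausea:0.8 corpus
drugchatter variants --oracle corpus:texts.txt adderall
drugchatter lm train --order 4 texts.txt model.arpa
drugchatter adr-signal --model vectors.txt --drug xanax --terms terms.txt
```

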