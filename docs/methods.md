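# Methods

This note documents the models implemented in `drugchatter`, the parameter
choices that matter, what the synthetic corpora do and do not emulate, and
the numerical decisions a maintainer should know about.

## Misspelling-variant generation

A keyword's candidate misspellings are exactly the strings at Levenshtein
distance 1 (one insertion, deletion or substitution), built over the ASCII
lowercase alphabet united with the word's own letters. Words shorter than
two characters are rejected, since a deletion variant would be empty.

The phonetic filter keeps candidates whose code equals the keyword's under
a pluggable encoder. The shipped encoder, `metaphone_lite`, is a
consonant-skeleton code applied in a fixed order: collapse runs of repeated
letters; rewrite digraphs ph→f, ck→k, gh→g; map q→k, x→ks, z→s, j→g; c→s
before e/i/y, else c→k; drop h unless word-initial; drop vowels except a
word-initial one; collapse repeats the rewrites may have recreated.
Collapsing doubles *first* guarantees that doubled-letter misspellings
("adderall"/"adderal", "seroquel"/"seroquell") always share a code — the
most common misspelling class for drug names. Like any vowel-dropping
encoding it is deliberately permissive about vowel substitutions
("adderoll" passes); the frequency stage is what prunes unattested forms.

The frequency stage is an interface: any callable from string to a
non-negative number. The default `CorpusFrequencyOracle` counts token
occurrences in a user-supplied reference corpus, which makes "frequently
used" reproducible and testable; a web-search count source could be dropped
in but cannot be version-pinned. `min_count` defaults to 1 ("observed at
least once"); an optional `top_k` keeps only the most frequent survivors.

## n-gram language model

Sentences are padded with n−1 start markers and one end marker, so the
model is a proper distribution over variable-length sentences; the start
marker is never a predicted outcome, and k-grams ending in it are excluded
from the count tables (they are not continuations and would break
normalization of the continuation distributions).

Smoothing is interpolated Kneser–Ney with a single absolute discount
D = 0.75 (configurable in (0,1)); this is the established default of the
modern n-gram tool family. The highest order uses raw counts; lower orders
use continuation counts N₁₊(·, g) (number of distinct left extensions); the
unigram level interpolates with a uniform 1/V floor over the predictable
vocabulary, so every token — including the unknown symbol — has strictly
positive probability. Tokens below `min_count` are replaced by `<unk>`
before counting (default 1, i.e. no replacement). An un-smoothed MLE mode
exists purely as a hand-checkable diagnostic; it assigns zero to unseen
events by design.

ARPA export writes log₁₀ probabilities at 8 decimals with per-context
backoff weights λ(c) = D·N₁₊(c·)/denominator(c). Interpolated Kneser–Ney is
exactly representable in backoff form, so export→import reproduces every
conditional probability to print precision (observed ≲ 1e-8, asserted
≤ 1e-6). Unigram-only ARPA files load for interchange even though training
is restricted to orders 2–4. Perplexity is exp(−mean log-probability per
transition), counting each token plus the end marker.

## Skip-gram embeddings

Skip-gram with negative sampling: for each (center, context) pair within a
fixed symmetric window, the context's output vector is pushed up and K
noise words — drawn from the unigram distribution raised to 0.75, the
de-facto standard — are pushed down, via logistic loss. Defaults: K = 5,
5 epochs, learning rate 0.025 decayed linearly, input vectors initialized
uniform in ±0.5/d, output vectors at zero; the stored embeddings are the
input vectors. Training is single-threaded and deterministic given the
seed; the window is fixed (no random shrinking).

Gradients are accumulated per sentence and applied in one vectorized
update (duplicate indices handled with `np.add.at`) rather than pair by
pair. This is a mini-batch variant of the usual SGD: it is
order-deterministic, roughly 30× faster in pure numpy, and converges
equivalently on the corpora this package targets. Reference configuration
for association mining is d = 400, window = 9; the tests and examples use
d = 16, window = 2, which already recover planted associations perfectly at
2,000 tweets — larger settings only slow the checks down. A sweep command
produces one model file per (d, window) combination.

## Drug–ADR association signal

The signal for (drug, term) is the cosine similarity of their vectors; a
multi-word term is scored by the unweighted mean over its in-vocabulary
tokens. Out-of-vocabulary tokens are skipped, not zero-filled — zero
filling would bias scores toward 0 and fabricate "no association" — and
coverage (covered/total tokens) is reported; a fully out-of-vocabulary term
is reported as missing. Scores receive no normalization or tuning.
A known-vs-candidate profile is summarized by the mean score difference and
by pairwise concordance (fraction of (known, candidate) pairs ordered
correctly, ties ½): concordance 1.0 is perfect separation, 0.5 is chance.

## Health-text scoring

Texts are scored by the order-4 model's log-probability divided by the
number of transitions (tokens + end marker). Normalizing by length matters:
min–max over raw sums would mostly rank texts by length, not content. The
batch is then min–max scaled to [0,1] (order-preserving); a degenerate
batch with all raw scores equal — including a singleton — maps to 0.5, the
symmetric choice. Classification thresholds the scaled score (health iff
score ≥ threshold). Evaluation reports accuracy, precision, recall, F1 on
labels and AUC on the scaled scores (rank statistic, ties ½), via
scikit-learn.

## Synthetic corpora

`generate_corpus` emulates drug-keyword chatter: background tokens are
drawn from a Zipf distribution (exponent 1.1 over 500 types — tweet token
frequencies are heavy-tailed); sentence lengths are negative-binomial
(mean 12, dispersion 5 — tweet-scale); timestamps are uniform over a
four-month default window. Each tweet mentions a drug with
`drug_mention_rate`; the mention is misspelled with `misspelling_rate`
using a variant sampled from the misspelling generator's phonetic stage, so
phonetic equality holds by construction. A tweet mentioning a drug mixes in
tokens from a drug-specific topic vocabulary (`topic_mix` = 0.5 of
background draws, 100 types) — posts about a medication share
characteristic phrasing — and each planted ADR term appears somewhere in
the tweet with its co-occurrence probability. Sharing the drug's topic
contexts is what makes the association recoverable by a distributional
model; terms planted only adjacent to the drug would be predicted *by* it
without being distributionally similar *to* it. Non-associated
`background_terms` are scattered over tweets without a drug mention at
`background_term_rate`, which keeps them in-vocabulary while guaranteeing
no association. Ground truth (mention, surface, planted terms per tweet) is
returned alongside and suffices to recompute all planted rates.

`generate_health_corpus` draws each tweet's label Bernoulli(health
fraction, default 0.35 to mirror typical annotated health-tweet sets) and
its content tokens from one of two 200-type vocabularies sharing a fraction
δ of types. Shared types are interleaved evenly across frequency ranks, so
the label-specific vocabulary spans common and rare words; putting all
specific types in the Zipf tail would concentrate the signal in barely-used
words and understate separability at any δ. At δ = 1 the two conditional
distributions are identical by construction; at δ = 0 they are disjoint.

What the generator does **not** emulate: real orthographic/grammatical
variation beyond single-edit misspellings, topic drift over time, duplicate
and near-duplicate posts, multi-drug interactions within a tweet, and the
pragmatics of actual adverse-event reports. Passing the planted-recovery
checks therefore demonstrates that the pipeline's machinery is correct and
sensitive under its own assumptions, not that it achieves any particular
accuracy on real chatter.

## Numerical and interface decisions

- Tokenization: lowercase, whitespace split, strip peripheral
  non-alphanumerics per token (keeping internal apostrophes/hyphens);
  "#adderall" matches "adderall". Matching is exact-token only — substring
  matching would hit "adderallfan".
- Keyword statistics count tweets, not occurrences (a tweet mentioning a
  keyword twice counts once); top-k ties break lexicographically.
- Records with unparseable timestamps keep their text but are excluded from
  monthly statistics with a warning; malformed corpus lines are skipped and
  counted.
- Nearest-neighbor ties break lexicographically; the query token is
  excluded; zero vectors can never rank.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seed and configuration give bit-identical corpora and vectors.

## Problem sizes

The shipped checks use 500–3,000-tweet corpora, vocabulary ≤ ~700 types,
embedding dimension 16 and ten seeded replicates for the association study;
these sizes give stable statistics (binomial standard errors below the
asserted tolerances) while keeping a full run under a minute. The same code
paths scale to the reference configuration (d = 400, window = 9) unchanged.

## Known limitations

- The phonetic encoder handles ASCII alphabetic words only; accented brand
  names must be transliterated upstream.
- Kneser–Ney uses a single discount, not modified Kneser–Ney's three; at
  desk scale the difference is negligible, and D is configurable.
- The skip-gram trainer is pure numpy: fine to ~10⁵ sentences, not a
  substitute for a compiled trainer at web scale.
- Re-exporting an imported ARPA model is unsupported (count tables are not
  reconstructed from probabilities).
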