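"""Synthetic drug-chatter corpora with known ground truth.

Real drug-related social-media corpora cannot be redistributed, so every
pipeline stage here is exercised on generated corpora that reproduce the
statistical structure the stages assume:

* heavy-tailed background vocabulary (Zipf, exponent 1.1 by default);
* tweet-scale sentence lengths (negative binomial, mean 12);
* drug mentions at a controllable rate, misspelled at a controllable rate
  using phonetically equal variants from the misspelling generator (so the
  phonetic filter holds by construction);
* a per-drug topic vocabulary: a tweet mentioning a drug mixes drug-specific
  chatter tokens into its background, the way real posts about a medication
  share characteristic phrasing;
* planted drug–ADR co-occurrences: when a drug is mentioned, each of its
  planted ADR terms appears somewhere in the same tweet with its
  co-occurrence probability, so drug and reaction share the drug's topic
  contexts — the association a distributional model can recover;
  non-associated terms are scattered over tweets without a drug mention;
* a health / non-health split where the two label-conditional content
  vocabularies share a controllable fraction of types.

Every corpus comes with a truth record sufficient to recompute the planted
rates without regenerating, and round-trips through the corpus reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Sequence

import numpy as np

from .corpus import Tweet
from .misspellings import generate_misspellings

#: fixture lexicon of 50 widely used drug keywords (stimulants, sedatives,
#: antidepressants, pain medications, statins, antivirals, ...)
DEFAULT_DRUGS: tuple[str, ...] = (
    "abilify", "adderall", "ambien", "amoxicillin", "aspirin", "ativan",
    "celebrex", "celexa", "cialis", "clonidine", "codeine", "crestor",
    "cymbalta", "effexor", "gabapentin", "humira", "ibuprofen", "klonopin",
    "lamictal", "lexapro", "lipitor", "lisinopril", "lyrica", "melatonin",
    "metformin", "methadone", "morphine", "naproxen", "nexium", "oxycodone",
    "paxil", "percocet", "prednisone", "prozac", "ritalin", "seroquel",
    "synthroid", "tamiflu", "tramadol", "trazodone", "valium", "viagra",
    "vicodin", "vyvanse", "wellbutrin", "xanax", "zoloft", "zofran",
    "zyprexa", "zyrtec",
)

_EPOCH_START = datetime(2014, 11, 1, tzinfo=timezone.utc)
_EPOCH_END = datetime(2015, 3, 1, tzinfo=timezone.utc)


@dataclass(frozen=True)
class PlantedPair:
    drug: str
    term: str
    prob: float


@dataclass
class CorpusSpec:
    """Parameters of one synthetic corpus; every probability lies in [0,1]."""

    seed: int = 0
    n_tweets: int = 1000
    drugs: Sequence[str] = ("adderall", "xanax", "seroquel", "trazodone")
    drug_mention_rate: float = 1.0
    misspelling_rate: float = 0.1
    planted_pairs: Sequence[PlantedPair] = ()
    background_terms: Sequence[str] = ()
    background_term_rate: float = 0.1
    background_vocab: int = 500
    topic_vocab: int = 100
    topic_mix: float = 0.5
    zipf_exponent: float = 1.1
    length_mean: float = 12.0
    length_dispersion: float = 5.0
    date_start: datetime = _EPOCH_START
    date_end: datetime = _EPOCH_END
    health_fraction: float = 0.35
    vocab_overlap: float = 0.8
    content_vocab: int = 200

    def validate(self) -> None:
        if self.n_tweets < 1:
            raise ValueError("n_tweets must be >= 1")
        for p in (
            self.drug_mention_rate, self.misspelling_rate, self.topic_mix,
            self.background_term_rate, self.health_fraction, self.vocab_overlap,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        drugs = set(self.drugs)
        for pair in self.planted_pairs:
            if pair.drug not in drugs:
                raise ValueError(f"planted pair references undeclared drug {pair.drug!r}")
            if not 0.0 <= pair.prob <= 1.0:
                raise ValueError(f"co-occurrence probability out of [0,1]: {pair.prob}")
        if self.date_end <= self.date_start:
            raise ValueError("date_end must be after date_start")


@dataclass
class TruthRecord:
    """Per-tweet ground truth for one generated corpus."""

    records: list[dict] = field(default_factory=list)

    def mention_fraction(self) -> float:
        return sum(1 for r in self.records if r.get("drug")) / len(self.records)

    def misspelling_fraction(self) -> float:
        mentions = [r for r in self.records if r.get("drug")]
        if not mentions:
            return 0.0
        return sum(1 for r in mentions if r["misspelled"]) / len(mentions)

    def cooccurrence_fraction(self, drug: str, term: str) -> float:
        mentions = [r for r in self.records if r.get("drug") == drug]
        if not mentions:
            return 0.0
        return sum(1 for r in mentions if term in r["planted_terms"]) / len(mentions)

    def label_fraction(self) -> float:
        return sum(1 for r in self.records if r.get("label") == 1) / len(self.records)


def _zipf_cdf(size: int, exponent: float) -> np.ndarray:
    weights = np.arange(1, size + 1, dtype=np.float64) ** (-exponent)
    return np.cumsum(weights / weights.sum())


def _lengths(rng: np.random.Generator, spec: CorpusSpec, n: int) -> np.ndarray:
    r = spec.length_dispersion
    p = r / (r + spec.length_mean)
    return np.maximum(rng.negative_binomial(r, p, size=n), 3)


def _timestamps(rng: np.random.Generator, spec: CorpusSpec, n: int) -> list[datetime]:
    span = (spec.date_end - spec.date_start).total_seconds()
    return [spec.date_start + timedelta(seconds=float(s)) for s in rng.random(n) * span]


def generate_corpus(spec: CorpusSpec) -> tuple[list[Tweet], TruthRecord]:
    """Generate drug-chatter tweets plus their ground truth; deterministic
    given the spec's seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bg_cdf = _zipf_cdf(spec.background_vocab, spec.zipf_exponent)
    topic_cdf = _zipf_cdf(spec.topic_vocab, spec.zipf_exponent)
    background = [f"w{i:04d}" for i in range(spec.background_vocab)]
    topics = {
        d: [f"{d}_topic{i:03d}" for i in range(spec.topic_vocab)] for d in set(spec.drugs)
    }
    variants = {
        d: sorted(generate_misspellings(d).stage2) or [d] for d in set(spec.drugs)
    }
    pairs_by_drug: dict[str, list[PlantedPair]] = {}
    for pair in spec.planted_pairs:
        pairs_by_drug.setdefault(pair.drug, []).append(pair)

    lengths = _lengths(rng, spec, spec.n_tweets)
    stamps = _timestamps(rng, spec, spec.n_tweets)
    tweets, truth = [], TruthRecord()
    for i in range(spec.n_tweets):
        record: dict = {"drug": None, "surface": None, "misspelled": False, "planted_terms": []}
        drug = None
        if rng.random() < spec.drug_mention_rate:
            drug = spec.drugs[int(rng.integers(len(spec.drugs)))]
        tokens = []
        for _ in range(int(lengths[i])):
            if drug is not None and rng.random() < spec.topic_mix:
                tokens.append(topics[drug][int(np.searchsorted(topic_cdf, rng.random()))])
            else:
                tokens.append(background[int(np.searchsorted(bg_cdf, rng.random()))])
        if drug is not None:
            misspell = rng.random() < spec.misspelling_rate
            surface = variants[drug][int(rng.integers(len(variants[drug])))] if misspell else drug
            tokens.insert(int(rng.integers(len(tokens) + 1)), surface)
            record.update(drug=drug, surface=surface, misspelled=misspell and surface != drug)
            for pair in pairs_by_drug.get(drug, ()):
                if rng.random() < pair.prob:
                    at = int(rng.integers(len(tokens) + 1))
                    tokens[at:at] = pair.term.split()
                    record["planted_terms"].append(pair.term)
        else:
            for term in spec.background_terms:
                if rng.random() < spec.background_term_rate:
                    at = int(rng.integers(len(tokens) + 1))
                    tokens[at:at] = term.split()
        tweets.append(Tweet(id=f"t{i:06d}", timestamp=stamps[i], text=" ".join(tokens)))
        truth.records.append(record)
    return tweets, truth


def generate_health_corpus(spec: CorpusSpec) -> tuple[list[Tweet], TruthRecord]:
    """Generate a labeled health / non-health corpus.

    The two label-conditional content vocabularies share a fraction
    ``vocab_overlap`` of types at identical frequency ranks: overlap 1 makes
    the two conditional distributions identical by construction, overlap 0
    makes them disjoint.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    V = spec.content_vocab
    # shared types are interleaved evenly across frequency ranks, so the
    # label-specific vocabulary spans common and rare words alike
    health_vocab, other_vocab = [], []
    for i in range(V):
        if int((i + 1) * spec.vocab_overlap) > int(i * spec.vocab_overlap):
            health_vocab.append(f"s{i:04d}")
            other_vocab.append(f"s{i:04d}")
        else:
            health_vocab.append(f"h{i:04d}")
            other_vocab.append(f"n{i:04d}")
    cdf = _zipf_cdf(V, spec.zipf_exponent)

    lengths = _lengths(rng, spec, spec.n_tweets)
    stamps = _timestamps(rng, spec, spec.n_tweets)
    tweets, truth = [], TruthRecord()
    for i in range(spec.n_tweets):
        label = int(rng.random() < spec.health_fraction)
        vocab = health_vocab if label else other_vocab
        tokens = [vocab[j] for j in np.searchsorted(cdf, rng.random(lengths[i]))]
        tweets.append(Tweet(id=f"t{i:06d}", timestamp=stamps[i], text=" ".join(tokens)))
        truth.records.append({"label": label})
    return tweets, truth
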