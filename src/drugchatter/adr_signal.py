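"""Drug–adverse-reaction association signals from word embeddings.

The association between a drug keyword and an adverse-reaction (ADR) term is
the cosine similarity of their vectors; a multi-word term ("dry mouth") is
scored by the mean cosine over its in-vocabulary tokens.  Out-of-vocabulary
tokens inside a term are skipped, not zero-filled — a missing token is
absent evidence, not evidence of no association — and the coverage is
reported alongside the score.  Scores are used as-is: no normalization or
tuning is applied.

A profile over known ADR terms and candidate terms is summarized by the
mean score difference and the pairwise concordance (fraction of
known/candidate pairs with the known term scored higher; ties count 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus import preprocess
from .embeddings import EmbeddingModel, cosine_similarity


@dataclass(frozen=True)
class AdrTerm:
    """An adverse-reaction phrase and its preprocessed tokens."""

    surface: str
    tokens: tuple[str, ...]

    @classmethod
    def from_surface(cls, surface: str) -> "AdrTerm":
        tokens = tuple(preprocess(surface))
        if not tokens:
            raise ValueError(f"ADR term has no tokens: {surface!r}")
        return cls(surface=surface, tokens=tokens)


@dataclass(frozen=True)
class AssociationScore:
    """(drug, term) cosine-similarity signal; score is None when the term is
    fully out of vocabulary."""

    drug: str
    term: AdrTerm
    score: float | None
    covered_tokens: int
    total_tokens: int


def term_similarity(model: EmbeddingModel, drug: str, term: AdrTerm | str) -> AssociationScore:
    """Mean cosine between the drug vector and each in-vocabulary term token.

    Raises KeyError if the drug is out of vocabulary, ValueError if every
    token of the term is.
    """
    if isinstance(term, str):
        term = AdrTerm.from_surface(term)
    if drug not in model:
        raise KeyError(f"drug keyword not in vocabulary: {drug!r}")
    dvec = model.vector(drug)
    sims = [cosine_similarity(dvec, model.vector(t)) for t in term.tokens if t in model]
    if not sims:
        raise ValueError(f"every token of term {term.surface!r} is out of vocabulary")
    return AssociationScore(
        drug=drug,
        term=term,
        score=sum(sims) / len(sims),
        covered_tokens=len(sims),
        total_tokens=len(term.tokens),
    )


def association_profile(
    model: EmbeddingModel, drug: str, terms: Sequence[AdrTerm | str]
) -> list[AssociationScore]:
    """One score per term in input order; fully-OOV terms are reported with
    score None rather than dropped or zeroed."""
    profile = []
    for term in terms:
        t = AdrTerm.from_surface(term) if isinstance(term, str) else term
        try:
            profile.append(term_similarity(model, drug, t))
        except ValueError:
            profile.append(AssociationScore(drug, t, None, 0, len(t.tokens)))
    return profile


def separation_statistic(
    profile: Iterable[AssociationScore],
    known: Iterable[str],
    candidate: Iterable[str],
) -> tuple[float, float]:
    """(mean(known) − mean(candidate), pairwise concordance) over a profile.

    Concordance is the fraction of (known, candidate) score pairs with the
    known term higher; ties count 1/2.  Subsets must be disjoint, non-empty
    and scored.
    """
    known, candidate = set(known), set(candidate)
    if known & candidate:
        raise ValueError("known and candidate term sets overlap")
    scores = {s.term.surface: s.score for s in profile}
    ks = [scores[t] for t in sorted(known)]
    cs = [scores[t] for t in sorted(candidate)]
    if not ks or not cs:
        raise ValueError("both subsets must be non-empty")
    if any(v is None for v in ks + cs):
        missing = [t for t in sorted(known | candidate) if scores.get(t) is None]
        raise ValueError(f"unscored terms in subsets: {missing}")
    mean_diff = sum(ks) / len(ks) - sum(cs) / len(cs)
    wins = sum(1.0 if k > c else 0.5 if k == c else 0.0 for k in ks for c in cs)
    return mean_diff, wins / (len(ks) * len(cs))


def read_term_list(path) -> tuple[list[AdrTerm], dict[str, str]]:
    """Read an ADR term list: one phrase per line, optional tab-separated
    second column "known"/"candidate".  Returns terms plus a surface→group map."""
    from pathlib import Path

    terms, groups = [], {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        surface, _, group = line.partition("\t")
        term = AdrTerm.from_surface(surface.strip())
        terms.append(term)
        if group.strip():
            groups[term.surface] = group.strip().lower()
    return terms, groups
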