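"""Phonetic misspelling-variant generation for drug keywords.

Drug names are misspelled constantly in social-media chatter, so collecting
posts by correct spellings alone loses recall.  The generator runs in three
stages:

1. enumerate every string within Levenshtein distance exactly 1 of the
   keyword (single insertion, deletion or substitution);
2. keep only candidates whose phonetic code equals the keyword's, so the
   surviving misspellings sound like the drug name;
3. keep only candidates a frequency oracle says people actually write
   (by default, token counts over a reference corpus).

The phonetic encoder is pluggable.  The shipped default, ``metaphone_lite``,
is a documented consonant-skeleton encoding: collapse doubled letters, apply
a small digraph/letter table (ph→f, q→k, x→ks, z→s, soft/hard c), drop h
except word-initially, drop vowels except a word-initial one.  Homophonous
variants such as ``adderall``/``adderal`` share a code by construction.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable

logger = logging.getLogger(__name__)

ASCII_LOWER = "abcdefghijklmnopqrstuvwxyz"

#: ordered rewrite table applied left-to-right after doubled letters collapse
_DIGRAPHS = {"ph": "f", "ck": "k", "gh": "g"}
_LETTERS = {"q": "k", "x": "ks", "z": "s", "j": "g"}
_VOWELS = frozenset("aeiou")
_SOFTENERS = frozenset("eiy")  # c → s before these, else k


def levenshtein_distance(a: str, b: str) -> int:
    """Unit-cost edit distance by the classic two-row dynamic program."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def levenshtein1_variants(word: str, alphabet: Iterable[str] = ASCII_LOWER) -> set[str]:
    """All strings at Levenshtein distance exactly 1 from `word`.

    Built over ``alphabet ∪ letters(word)``; excludes `word` itself and the
    empty string.  Words shorter than 2 characters are rejected — a deletion
    variant would be empty.
    """
    if len(word) < 2:
        raise ValueError(f"word too short for variant generation: {word!r}")
    letters = sorted(set(alphabet) | set(word))
    if not letters:
        raise ValueError("alphabet is empty")
    out: set[str] = set()
    for i in range(len(word)):
        out.add(word[:i] + word[i + 1 :])  # deletion
        for ch in letters:
            if ch != word[i]:
                out.add(word[:i] + ch + word[i + 1 :])  # substitution
    for i in range(len(word) + 1):
        for ch in letters:
            out.add(word[:i] + ch + word[i:])  # insertion
    out.discard(word)
    out.discard("")
    return out


def metaphone_lite(word: str) -> str:
    """Consonant-skeleton phonetic code; deterministic, documented above.

    Raises ValueError on non-alphabetic input.
    """
    w = word.lower()
    if not w or not w.isalpha() or not w.isascii():
        raise ValueError(f"phonetic encoding needs a non-empty ascii-alphabetic word: {word!r}")
    # collapse runs of identical letters first so doubled-letter misspellings
    # ("adderall"/"adderal", "seroquell"/"seroquel") are homophones
    collapsed = [w[0]]
    for ch in w[1:]:
        if ch != collapsed[-1]:
            collapsed.append(ch)
    w = "".join(collapsed)

    out: list[str] = []
    i = 0
    while i < len(w):
        pair = w[i : i + 2]
        if pair in _DIGRAPHS:
            out.append(_DIGRAPHS[pair])
            i += 2
            continue
        ch = w[i]
        if ch == "c":
            out.append("s" if w[i + 1 : i + 2] in _SOFTENERS else "k")
        elif ch in _LETTERS:
            out.append(_LETTERS[ch])
        elif ch == "h":
            if i == 0:
                out.append("h")
        elif ch in _VOWELS:
            if i == 0:
                out.append(ch)
        else:
            out.append(ch)
        i += 1
    code = "".join(out)
    # rewrites may recreate doubles (e.g. "xs" → "kss")
    dedup = [code[0]]
    for ch in code[1:]:
        if ch != dedup[-1]:
            dedup.append(ch)
    return "".join(dedup)


#: default encoder used throughout the package
phonetic_code = metaphone_lite

Encoder = Callable[[str], str]
FrequencyOracle = Callable[[str], float]


def phonetic_filter(variants: Iterable[str], source: str, encoder: Encoder = phonetic_code) -> set[str]:
    """Keep variants whose phonetic code equals the source keyword's code.

    Variants the encoder rejects (non-alphabetic) are dropped with a warning.
    Idempotent.
    """
    target = encoder(source)
    kept = set()
    for v in variants:
        try:
            if encoder(v) == target:
                kept.add(v)
        except ValueError:
            logger.warning("dropping unencodable variant %r of %r", v, source)
    return kept


def frequency_filter(
    variants: Iterable[str],
    oracle: FrequencyOracle,
    min_count: float = 1,
    top_k: int | None = None,
) -> set[str]:
    """Keep variants the oracle reports at least `min_count` times.

    If `top_k` is given, additionally keep only the k most frequent survivors
    (ties broken lexicographically).  An oracle failure on a variant drops
    that variant with a warning.
    """
    scored: dict[str, float] = {}
    for v in variants:
        try:
            freq = oracle(v)
        except Exception:  # noqa: BLE001 - oracle is user-supplied
            logger.warning("frequency oracle failed on %r; dropping", v)
            continue
        if freq >= min_count:
            scored[v] = freq
    if top_k is not None:
        ranked = sorted(scored.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
        return {v for v, _ in ranked}
    return set(scored)


class CorpusFrequencyOracle:
    """Frequency oracle backed by token counts over a reference corpus.

    The reproducible stand-in for a web-search frequency source: a candidate
    misspelling is "frequently used" if people wrote it in the reference
    text.
    """

    def __init__(self, token_sequences: Iterable[Iterable[str]]):
        self.counts = Counter(tok for sent in token_sequences for tok in sent)

    def __call__(self, token: str) -> float:
        return float(self.counts[token])


@dataclass(frozen=True)
class Variant:
    """One surviving misspelling with its provenance."""

    surface: str
    edit: str  # deletion | substitution | insertion
    phonetic_code: str
    frequency: float | None = None


@dataclass
class VariantSet:
    """A keyword's variants after each generator stage (stage3 ⊆ stage2 ⊆ stage1)."""

    source: str
    stage1: dict[str, Variant] = field(default_factory=dict)
    stage2: set[str] = field(default_factory=set)
    stage3: set[str] = field(default_factory=set)

    def surviving(self) -> list[Variant]:
        return [self.stage1[s] for s in sorted(self.stage3)]


def _edit_type(source: str, variant: str) -> str:
    if len(variant) < len(source):
        return "deletion"
    if len(variant) > len(source):
        return "insertion"
    return "substitution"


def generate_misspellings(
    word: str,
    oracle: FrequencyOracle | None = None,
    min_count: float = 1,
    top_k: int | None = None,
    alphabet: Iterable[str] = ASCII_LOWER,
    encoder: Encoder = phonetic_code,
) -> VariantSet:
    """Run the three-stage generator for one keyword.

    With no oracle, stage 3 equals stage 2 (no frequency evidence available)
    and frequencies are left absent.
    """
    word = word.lower()
    stage1_surfaces = levenshtein1_variants(word, alphabet)
    stage2 = phonetic_filter(stage1_surfaces, word, encoder)
    if oracle is None:
        stage3 = set(stage2)
        freqs: dict[str, float | None] = {}
    else:
        stage3 = frequency_filter(stage2, oracle, min_count=min_count, top_k=top_k)
        freqs = {v: oracle(v) for v in stage3}
    stage1 = {}
    for surf in stage1_surfaces:
        code = None
        try:
            code = encoder(surf)
        except ValueError:
            code = ""
        stage1[surf] = Variant(
            surface=surf,
            edit=_edit_type(word, surf),
            phonetic_code=code,
            frequency=freqs.get(surf),
        )
    return VariantSet(source=word, stage1=stage1, stage2=stage2, stage3=stage3)
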