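"""Reading, preprocessing, filtering and summarizing tweet-like corpora.

A corpus here is a sequence of short user posts, each carrying an opaque id,
a UTC timestamp and raw text.  Posts are matched against a drug lexicon
(canonical keyword plus misspelling variants) by exact token equality after
light normalization: lowercase, whitespace split, peripheral punctuation
stripped.  Matching is deliberately recall-oriented — ``#adderall`` matches
``adderall`` — but never substring-based, so ``adderallfan`` does not.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

FORMATS = ("jsonl", "tsv")


@dataclass
class Tweet:
    """One post: id, UTC timestamp (None if unparseable), raw text, matches."""

    id: str
    timestamp: datetime | None
    text: str
    matched_keywords: set[str] = field(default_factory=set)


@dataclass
class DrugLexicon:
    """Canonical lowercase drug keywords plus their accepted spelling variants.

    Every variant maps back to exactly one canonical entry; a variant hit is
    always credited to its canonical form.
    """

    canonical: set[str] = field(default_factory=set)
    variants: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._variant_to_canonical: dict[str, str] = {}
        for canon, vset in self.variants.items():
            for v in vset:
                self._register(canon, v)

    def _register(self, canon: str, variant: str) -> None:
        owner = self._variant_to_canonical.get(variant)
        if owner is not None and owner != canon:
            raise ValueError(
                f"variant {variant!r} maps to both {owner!r} and {canon!r}"
            )
        self._variant_to_canonical[variant] = canon

    def add_variants(self, canonical: str, variants: Iterable[str]) -> None:
        if canonical not in self.canonical:
            raise KeyError(f"unknown canonical keyword {canonical!r}")
        bucket = self.variants.setdefault(canonical, set())
        for v in variants:
            self._register(canonical, v)
            bucket.add(v)

    def lookup(self, token: str) -> str | None:
        """Canonical keyword credited for `token`, or None."""
        if token in self.canonical:
            return token
        return self._variant_to_canonical.get(token)

    @classmethod
    def from_file(cls, path: str | Path, variants_path: str | Path | None = None) -> "DrugLexicon":
        """Read one canonical keyword per line; '#' starts a comment.

        `variants_path`, if given, holds one tab-separated
        ``canonical<TAB>variant`` pair per line.
        """
        canonical: set[str] = set()
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.split("#", 1)[0].strip().lower()
            if line:
                if any(ch.isspace() for ch in line):
                    raise ValueError(f"lexicon entry contains whitespace: {line!r}")
                canonical.add(line)
        lex = cls(canonical=canonical)
        if variants_path is not None:
            for raw in Path(variants_path).read_text(encoding="utf-8").splitlines():
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                canon, _, variant = line.partition("\t")
                lex.add_variants(canon.strip().lower(), [variant.strip().lower()])
        return lex


@dataclass
class CorpusStats:
    """Monthly tweet counts and per-keyword tweet counts (one count per tweet
    per keyword, however often the keyword recurs inside the tweet)."""

    monthly_counts: dict[tuple[int, int], int]
    keyword_counts: dict[str, int]
    top_keywords: list[tuple[str, int]]


def _parse_timestamp(value: str) -> datetime | None:
    try:
        ts = datetime.fromisoformat(value.replace("Z", "+00:00"))
    except (ValueError, TypeError):
        return None
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


_TSV_ESCAPES = {"\\\\": "\\", "\\t": "\t", "\\n": "\n"}


def _tsv_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _tsv_unescape(text: str) -> str:
    out, i = [], 0
    while i < len(text):
        if text[i] == "\\" and i + 1 < len(text):
            pair = text[i : i + 2]
            if pair in _TSV_ESCAPES:
                out.append(_TSV_ESCAPES[pair])
                i += 2
                continue
        out.append(text[i])
        i += 1
    return "".join(out)


def read_corpus(path: str | Path, format: str = "jsonl") -> Iterator[Tweet]:
    """Lazily yield tweets from a JSONL or TSV file, in file order.

    Malformed records are skipped; the skip count is logged once the file is
    exhausted.  An unknown format tag or unreadable file is fatal.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown corpus format {format!r}; expected one of {FORMATS}")
    path = Path(path)
    skipped = 0
    with path.open("r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            tweet = _parse_record(line, format, lineno)
            if tweet is None:
                skipped += 1
                continue
            yield tweet
    if skipped:
        logger.warning("skipped %d malformed record(s) in %s", skipped, path)


def _parse_record(line: str, format: str, lineno: int) -> Tweet | None:
    if format == "jsonl":
        try:
            obj = json.loads(line)
            tid, created, text = obj["id"], obj["created_at"], obj["text"]
        except (json.JSONDecodeError, KeyError, TypeError):
            logger.debug("malformed JSONL record at line %d", lineno)
            return None
    else:
        parts = line.split("\t")
        if len(parts) != 3:
            logger.debug("malformed TSV record at line %d", lineno)
            return None
        tid, created, text = parts[0], parts[1], _tsv_unescape(parts[2])
    tid, text = str(tid), str(text)
    if not tid or not text:
        return None
    ts = _parse_timestamp(str(created))
    if ts is None:
        logger.warning("unparseable timestamp %r at line %d; excluded from monthly stats", created, lineno)
    return Tweet(id=tid, timestamp=ts, text=text)


def write_corpus(tweets: Iterable[Tweet], path: str | Path, format: str = "jsonl") -> int:
    """Write tweets in the given dialect; returns the number written."""
    if format not in FORMATS:
        raise ValueError(f"unknown corpus format {format!r}; expected one of {FORMATS}")
    n = 0
    with Path(path).open("w", encoding="utf-8") as handle:
        for t in tweets:
            created = t.timestamp.isoformat() if t.timestamp else ""
            if format == "jsonl":
                handle.write(json.dumps({"id": t.id, "created_at": created, "text": t.text}) + "\n")
            else:
                handle.write(f"{t.id}\t{created}\t{_tsv_escape(t.text)}\n")
            n += 1
    return n


def preprocess(text: str) -> list[str]:
    """Lowercase, split on whitespace, strip peripheral punctuation per token.

    Internal apostrophes and hyphens survive ("don't", "extended-release");
    '@' and '#' prefixes are stripped so "#adderall" matches "adderall".
    Empty tokens are dropped.  Idempotent on its own output.
    """
    tokens = []
    for tok in text.lower().split():
        start, end = 0, len(tok)
        while start < end and not tok[start].isalnum():
            start += 1
        while end > start and not tok[end - 1].isalnum():
            end -= 1
        if end > start:
            tokens.append(tok[start:end])
    return tokens


def match_keywords(tokens: Iterable[str], lexicon: DrugLexicon) -> set[str]:
    """Canonical keywords whose canonical form or any variant equals a token."""
    hits = set()
    for tok in tokens:
        canon = lexicon.lookup(tok)
        if canon is not None:
            hits.add(canon)
    return hits


def filter_corpus(tweets: Iterable[Tweet], lexicon: DrugLexicon) -> Iterator[Tweet]:
    """Keep exactly the tweets mentioning at least one lexicon keyword,
    with ``matched_keywords`` populated (variant hits credited canonically)."""
    for tweet in tweets:
        hits = match_keywords(preprocess(tweet.text), lexicon)
        if hits:
            tweet.matched_keywords = hits
            yield tweet


def corpus_stats(tweets: Iterable[Tweet], lexicon: DrugLexicon, k: int = 10) -> CorpusStats:
    """Monthly (year, month) counts and top-k keyword table.

    Tweets without a parseable timestamp are excluded from the monthly table
    only.  Ties in the top-k are broken lexicographically.
    """
    monthly: Counter[tuple[int, int]] = Counter()
    keywords: Counter[str] = Counter()
    for tweet in tweets:
        if tweet.timestamp is not None:
            monthly[(tweet.timestamp.year, tweet.timestamp.month)] += 1
        hits = tweet.matched_keywords or match_keywords(preprocess(tweet.text), lexicon)
        for kw in hits:
            keywords[kw] += 1
    top = sorted(keywords.items(), key=lambda kv: (-kv[1], kv[0]))[: max(k, 0)]
    return CorpusStats(
        monthly_counts=dict(monthly),
        keyword_counts=dict(keywords),
        top_keywords=top,
    )
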