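"""Order-n (n = 2–4) sequence language models with ARPA interchange.

The model assigns a probability to a token sequence by the Markov chain rule
P(w_1..w_m) = Π_k P(w_k | w_{k-n+1}..w_{k-1}), with each sentence padded by
n−1 start markers and one end marker so the model is a proper distribution
over sentences.

Two estimation modes:

* ``kneser_ney`` (default): interpolated Kneser–Ney with a single absolute
  discount D ∈ (0,1).  The highest order uses raw counts; lower orders use
  continuation counts (number of distinct left contexts); the unigram level
  is interpolated with a uniform 1/V floor so every vocabulary item —
  including the unknown symbol — gets strictly positive mass.
* ``mle``: plain count ratios, for hand-checkable diagnostics.  Unseen
  events get probability 0 in this mode.

ARPA files follow the standard backoff layout (log10 probabilities, one
section per order, optional backoff weight per entry).  Because interpolated
Kneser–Ney is exactly representable in backoff form, export → import is the
identity on conditional probabilities up to print precision.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Sequence

BOS = "<s>"
EOS = "</s>"
UNK = "<unk>"

_ORDER_RANGE = (2, 4)


class NGramModel:
    """Trained or ARPA-loaded n-gram model exposing conditional probabilities.

    Query contexts are truncated to the last n−1 tokens and out-of-vocabulary
    tokens are mapped to the unknown symbol before lookup.
    """

    def __init__(self, n: int, discount: float = 0.75, mode: str = "kneser_ney"):
        # training is restricted to orders 2-4; order 1 is admitted so that
        # unigram ARPA files remain loadable for interchange
        if not 1 <= n <= _ORDER_RANGE[1]:
            raise ValueError(f"order must be in [1,{_ORDER_RANGE[1]}], got {n}")
        if mode not in ("kneser_ney", "mle"):
            raise ValueError(f"unknown mode {mode!r}")
        if not 0.0 < discount < 1.0:
            raise ValueError("discount must lie in (0,1)")
        self.n = n
        self.discount = discount
        self.mode = mode
        self.vocab: set[str] = set()
        # raw k-gram counts, k = 1..n
        self.counts: dict[int, Counter] = {k: Counter() for k in range(1, n + 1)}
        # right-extension totals: ctx (len k-1) -> sum of counts of ctx+(w,)
        self._ctx_total: dict[int, Counter] = {}
        # continuation counts N1+(. gram) for gram length 1..n-1
        self._cont: dict[int, Counter] = {}
        self._cont_den: dict[int, Counter] = {}
        self._types: dict[int, Counter] = {}  # distinct continuations of a context
        self._from_arpa = False
        self._arpa_logp: dict[int, dict[tuple, float]] = {}
        self._arpa_bow: dict[int, dict[tuple, float]] = {}

    # ------------------------------------------------------------------ train

    @property
    def predict_vocab(self) -> set[str]:
        """Tokens the model can emit (everything but the start marker)."""
        return self.vocab - {BOS}

    def _pad(self, sentence: Sequence[str]) -> list[str]:
        mapped = [t if t in self.vocab else UNK for t in sentence]
        return [BOS] * (self.n - 1) + mapped + [EOS]

    def _index(self) -> None:
        n = self.n
        self._ctx_total = {k: Counter() for k in range(2, n + 1)}
        self._types = {k: Counter() for k in range(2, n + 1)}
        for k in range(2, n + 1):
            for gram, c in self.counts[k].items():
                self._ctx_total[k][gram[:-1]] += c
                self._types[k][gram[:-1]] += 1
        self._cont = {k: Counter() for k in range(1, n)}
        self._cont_den = {k: Counter() for k in range(1, n)}
        for k in range(1, n):
            for gram in self.counts[k + 1]:
                self._cont[k][gram[1:]] += 1
        for k in range(1, n):
            for gram, c in self._cont[k].items():
                self._cont_den[k][gram[:-1]] += c
        # distinct continuation types per lower-order context
        self._cont_types: dict[int, Counter] = {k: Counter() for k in range(1, n)}
        for k in range(1, n):
            for gram in self._cont[k]:
                self._cont_types[k][gram[:-1]] += 1

    # ---------------------------------------------------------------- queries

    def cond_prob(self, word: str, context: Sequence[str] = ()) -> float:
        """P(word | context); context truncated to the last n−1 tokens."""
        w = word if word in self.vocab else UNK
        ctx = tuple(t if t in self.vocab else UNK for t in context)
        ctx = ctx[len(ctx) - self.n + 1 :] if self.n > 1 else ()
        if self._from_arpa:
            return self._arpa_prob(w, ctx)
        if self.mode == "mle":
            return self._mle(w, ctx)
        return self._kn(w, ctx)

    def _kn(self, w: str, ctx: tuple) -> float:
        k = len(ctx) + 1
        D = self.discount
        if k == 1:
            den = sum(self._cont[1].values())
            V = len(self.predict_vocab)
            if den == 0:
                return 1.0 / V
            num = max(self._cont[1][(w,)] - D, 0.0)
            t1 = len(self._cont[1])
            return num / den + D * t1 / den * (1.0 / V)
        if k == self.n:
            den = self._ctx_total[k][ctx]
            if den == 0:
                return self._kn(w, ctx[1:])
            num = max(self.counts[k][ctx + (w,)] - D, 0.0)
            lam = D * self._types[k][ctx] / den
            return num / den + lam * self._kn(w, ctx[1:])
        den = self._cont_den[k][ctx]
        if den == 0:
            return self._kn(w, ctx[1:])
        num = max(self._cont[k][ctx + (w,)] - D, 0.0)
        lam = D * self._cont_types[k][ctx] / den
        return num / den + lam * self._kn(w, ctx[1:])

    def _mle(self, w: str, ctx: tuple) -> float:
        k = len(ctx) + 1
        if k == 1:
            total = sum(c for g, c in self.counts[1].items() if g != (BOS,))
            return self.counts[1][(w,)] / total if total else 0.0
        den = self._ctx_total[k][ctx]
        if den == 0:
            return self._mle(w, ctx[1:])
        return self.counts[k][ctx + (w,)] / den

    def _arpa_prob(self, w: str, ctx: tuple) -> float:
        gram = ctx + (w,)
        logp = self._arpa_logp.get(len(gram), {}).get(gram)
        if logp is not None:
            return 10.0 ** logp
        if not ctx:
            # unknown unigram after UNK mapping should not happen; be safe
            return 10.0 ** self._arpa_logp[1].get((UNK,), -99.0)
        bow = self._arpa_bow.get(len(ctx), {}).get(ctx, 0.0)
        return 10.0 ** bow * self._arpa_prob(w, ctx[1:])

    def sequence_logprob(self, tokens: Sequence[str]) -> float:
        """Natural-log probability of a sentence, end-marker transition included."""
        padded = self._pad(tokens)
        total = 0.0
        for i in range(self.n - 1, len(padded)):
            p = self.cond_prob(padded[i], tuple(padded[i - self.n + 1 : i]))
            total += math.log(p) if p > 0 else float("-inf")
        return total

    def perplexity(self, corpus: Iterable[Sequence[str]]) -> float:
        """exp(−mean log-probability per scored transition) over a corpus."""
        total, transitions = 0.0, 0
        for sent in corpus:
            total += self.sequence_logprob(sent)
            transitions += len(sent) + 1  # tokens plus end marker
        if transitions == 0:
            raise ValueError("cannot compute perplexity of an empty corpus")
        return math.exp(-total / transitions)


def train_ngram(
    corpus: Iterable[Sequence[str]],
    n: int,
    min_count: int = 1,
    discount: float = 0.75,
    mode: str = "kneser_ney",
) -> NGramModel:
    """Train an order-n model on tokenized sentences.

    Tokens occurring fewer than `min_count` times are replaced by the unknown
    symbol before counting.  Deterministic: identical input gives identical
    models.
    """
    if not _ORDER_RANGE[0] <= n <= _ORDER_RANGE[1]:
        raise ValueError(f"training order must be in [{_ORDER_RANGE[0]},{_ORDER_RANGE[1]}], got {n}")
    sentences = [list(s) for s in corpus]
    if not sentences or all(not s for s in sentences):
        raise ValueError("training corpus is empty")
    model = NGramModel(n=n, discount=discount, mode=mode)
    raw = Counter(tok for sent in sentences for tok in sent)
    kept = {t for t, c in raw.items() if c >= min_count}
    model.vocab = kept | {BOS, EOS, UNK}
    for sent in sentences:
        padded = model._pad(sent)
        for k in range(1, n + 1):
            for i in range(len(padded) - k + 1):
                gram = tuple(padded[i : i + k])
                # k-grams ending in the start marker are never predicted and
                # would corrupt the continuation distributions
                if k > 1 and gram[-1] == BOS:
                    continue
                model.counts[k][gram] += 1
    model._index()
    return model


# --------------------------------------------------------------------- ARPA


def _stored_grams(model: NGramModel) -> dict[int, list[tuple]]:
    """Grams written per order: every observed k-gram, plus all vocabulary
    unigrams, plus every context of a stored higher-order gram (so backoff
    weights always have a carrier line)."""
    stored: dict[int, set[tuple]] = {k: set(model.counts[k]) for k in range(1, model.n + 1)}
    stored[1] |= {(w,) for w in model.vocab}
    for k in range(model.n, 1, -1):
        for gram in stored[k]:
            stored[k - 1].add(gram[:-1])
    return {k: sorted(v) for k, v in stored.items()}


def _backoff_weight(model: NGramModel, ctx: tuple) -> float:
    """λ(ctx) for queries one order above len(ctx); 1.0 for unseen contexts."""
    k = len(ctx) + 1
    D = model.discount
    if k == model.n:
        den = model._ctx_total[k][ctx]
        return D * model._types[k][ctx] / den if den else 1.0
    den = model._cont_den[k][ctx]
    return D * model._cont_types[k][ctx] / den if den else 1.0


def export_arpa(model: NGramModel, path: str | Path) -> None:
    """Write the model in standard ARPA backoff format (log10)."""
    if model.mode != "kneser_ney":
        raise ValueError("only kneser_ney models can be exported to ARPA")
    if model._from_arpa:
        raise ValueError("re-exporting an imported ARPA model is not supported")
    stored = _stored_grams(model)
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\\data\\\n")
        for k in range(1, model.n + 1):
            fh.write(f"ngram {k}={len(stored[k])}\n")
        for k in range(1, model.n + 1):
            fh.write(f"\n\\{k}-grams:\n")
            for gram in stored[k]:
                p = model.cond_prob(gram[-1], gram[:-1])
                logp = math.log10(p) if p > 0 else -99.0
                line = f"{logp:.8f}\t{' '.join(gram)}"
                if k < model.n:
                    line += f"\t{math.log10(_backoff_weight(model, gram)):.8f}"
                fh.write(line + "\n")
        fh.write("\n\\end\\\n")


def import_arpa(path: str | Path) -> NGramModel:
    """Read an ARPA file into a query-only model.

    Raises ValueError naming the offending line on malformed headers or on a
    mismatch between declared and actual n-gram counts.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    it = iter(enumerate(lines, start=1))
    declared: dict[int, int] = {}
    for lineno, line in it:
        if line.strip() == "\\data\\":
            break
        if line.strip():
            raise ValueError(f"line {lineno}: expected \\data\\ header")
    else:
        raise ValueError("missing \\data\\ header")
    for lineno, line in it:
        s = line.strip()
        if not s:
            break
        if not s.startswith("ngram "):
            raise ValueError(f"line {lineno}: malformed count line {s!r}")
        order_s, _, count_s = s[len("ngram "):].partition("=")
        declared[int(order_s)] = int(count_s)
    if not declared:
        raise ValueError("ARPA file declares no n-gram orders")
    n = max(declared)
    model = NGramModel(n=n)
    model._from_arpa = True
    model._arpa_logp = {k: {} for k in declared}
    model._arpa_bow = {k: {} for k in range(1, n)}
    current = None
    for lineno, line in it:
        s = line.strip()
        if not s:
            continue
        if s == "\\end\\":
            current = None
            break
        if s.startswith("\\") and s.endswith("-grams:"):
            current = int(s[1:].split("-", 1)[0])
            if current not in declared:
                raise ValueError(f"line {lineno}: undeclared order {current}")
            continue
        if current is None:
            raise ValueError(f"line {lineno}: entry outside any n-gram section")
        parts = s.split("\t") if "\t" in s else s.split()
        if "\t" in s:
            fields = parts
            gram = tuple(fields[1].split())
        else:
            fields = [parts[0], " ".join(parts[1 : 1 + current]), *parts[1 + current :]]
            gram = tuple(parts[1 : 1 + current])
        if len(gram) != current:
            raise ValueError(f"line {lineno}: expected a {current}-gram")
        model._arpa_logp[current][gram] = float(fields[0])
        if len(fields) > 2 and current < n:
            model._arpa_bow[current][gram] = float(fields[2])
    for k, cnt in declared.items():
        if len(model._arpa_logp[k]) != cnt:
            raise ValueError(
                f"ARPA declares {cnt} {k}-grams but {len(model._arpa_logp[k])} were read"
            )
    model.vocab = {g[0] for g in model._arpa_logp[1]}
    return model
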