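"""Skip-gram word embeddings with negative sampling, trained from scratch.

Each vocabulary term t receives a dense d-dimensional vector trained so that
the terms w observed inside a symmetric context window around t are scored
higher (by inner product) than K noise terms drawn from the unigram
distribution raised to the 3/4 power.  Contextually similar terms therefore
end up close in the vector space, which is what the downstream drug–adverse
reaction association signal exploits.

Training is deterministic for a given seed: a single thread, a fixed
symmetric window (no random shrinking), and per-sentence accumulated SGD —
gradients for all (center, context) pairs of a sentence are applied in one
vectorized update.  The reference configuration for association mining is
d = 400, window = 9; tests use much smaller dimensions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class Hyperparams:
    """Skip-gram training knobs (the network parameters H).

    d: vector size; window: symmetric context half-width; negatives: noise
    samples per positive pair; lr: initial learning rate, linearly decayed.
    """

    d: int = 100
    window: int = 5
    negatives: int = 5
    epochs: int = 5
    lr: float = 0.025
    min_count: int = 1
    seed: int = 0


@dataclass
class EmbeddingModel:
    vocabulary: list[str]
    vectors: np.ndarray  # (V, d)
    hyperparams: Hyperparams | None = None
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.vocabulary):
            raise ValueError("one vector per vocabulary token required")
        self.index = {tok: i for i, tok in enumerate(self.vocabulary)}

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.vectors[self.index[token]]
        except KeyError:
            raise KeyError(f"token not in vocabulary: {token!r}") from None


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def train_skipgram(
    corpus: Iterable[Sequence[str]],
    hp: Hyperparams | None = None,
    **overrides,
) -> EmbeddingModel:
    """Train skip-gram vectors on tokenized sentences.

    Deterministic given ``hp.seed``.  Raises ValueError if the corpus is
    empty after min-count pruning.
    """
    hp = replace(hp or Hyperparams(), **overrides)
    if hp.window < 1 or hp.d < 2 or hp.negatives < 1 or hp.epochs < 1:
        raise ValueError("window >= 1, d >= 2, negatives >= 1, epochs >= 1 required")
    sentences = [list(s) for s in corpus]
    counts = Counter(tok for sent in sentences for tok in sent)
    vocab = [t for t, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])) if c >= hp.min_count]
    if not vocab:
        raise ValueError("corpus empty after min_count pruning")
    index = {t: i for i, t in enumerate(vocab)}
    ids = [np.array([index[t] for t in sent if t in index], dtype=np.int64) for sent in sentences]
    ids = [s for s in ids if len(s) >= 2]
    if not ids:
        raise ValueError("no sentence has two in-vocabulary tokens")

    rng = np.random.default_rng(hp.seed)
    freqs = np.array([counts[t] for t in vocab], dtype=np.float64) ** 0.75
    noise_cdf = np.cumsum(freqs / freqs.sum())

    V, d = len(vocab), hp.d
    W = (rng.random((V, d)) - 0.5) / d  # input vectors (the embeddings)
    C = np.zeros((V, d))  # output/context vectors

    total_steps = hp.epochs * len(ids)
    step = 0
    for _epoch in range(hp.epochs):
        for sent in ids:
            lr = hp.lr * max(1.0 - step / total_steps, 1e-4)
            step += 1
            centers, contexts = [], []
            for i in range(len(sent)):
                lo, hi = max(0, i - hp.window), min(len(sent), i + hp.window + 1)
                for j in range(lo, hi):
                    if j != i:
                        centers.append(sent[i])
                        contexts.append(sent[j])
            if not centers:
                continue
            cen = np.array(centers, dtype=np.int64)
            pos = np.array(contexts, dtype=np.int64)
            neg = np.searchsorted(noise_cdf, rng.random((len(cen), hp.negatives)))
            targets = np.concatenate([pos[:, None], neg], axis=1)  # (P, 1+K)
            labels = np.zeros(targets.shape)
            labels[:, 0] = 1.0

            h = W[cen]  # (P, d)
            cvec = C[targets]  # (P, 1+K, d)
            scores = np.einsum("pd,pkd->pk", h, cvec)
            g = (_sigmoid(scores) - labels) * lr  # (P, 1+K)
            grad_w = np.einsum("pk,pkd->pd", g, cvec)
            grad_c = g[:, :, None] * h[:, None, :]
            np.add.at(W, cen, -grad_w)
            np.add.at(C, targets.reshape(-1), -grad_c.reshape(-1, d))

    if not np.isfinite(W).all():
        raise FloatingPointError("non-finite values after training")
    return EmbeddingModel(vocabulary=vocab, vectors=W, hyperparams=hp)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u·v / (‖u‖‖v‖); raises ValueError on a zero vector."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def nearest_neighbors(model: EmbeddingModel, token: str, k: int = 10) -> list[tuple[str, float]]:
    """Top-k vocabulary tokens by cosine similarity to `token` (query excluded,
    ties broken lexicographically)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if token not in model:
        raise KeyError(f"token not in vocabulary: {token!r}")
    q = model.vector(token)
    norms = np.linalg.norm(model.vectors, axis=1)
    norms[norms == 0.0] = np.inf  # zero vectors can never rank
    sims = model.vectors @ q / (norms * np.linalg.norm(q))
    order = sorted(
        (i for i in range(len(model.vocabulary)) if model.vocabulary[i] != token),
        key=lambda i: (-sims[i], model.vocabulary[i]),
    )
    return [(model.vocabulary[i], float(sims[i])) for i in order[:k]]


def save_word2vec_text(model: EmbeddingModel, path: str | Path) -> None:
    """Write the standard text interchange format: header "V d", then one
    "token v1 ... vd" line per token."""
    V, d = model.vectors.shape
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{V} {d}\n")
        for tok, vec in zip(model.vocabulary, model.vectors):
            fh.write(tok + " " + " ".join(f"{x:.8e}" for x in vec) + "\n")


def load_word2vec_text(path: str | Path) -> EmbeddingModel:
    """Read word2vec text format; raises ValueError naming the bad line."""
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("line 1: expected header 'V d'")
        V, d = int(header[0]), int(header[1])
        vocab: list[str] = []
        vectors = np.empty((V, d))
        lineno = 1
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(" ")
            if len(parts) != d + 1:
                raise ValueError(f"line {lineno}: expected token plus {d} values")
            if len(vocab) >= V:
                raise ValueError(f"line {lineno}: more rows than the header declares")
            vocab.append(parts[0])
            vectors[len(vocab) - 1] = [float(x) for x in parts[1:]]
    if len(vocab) != V:
        raise ValueError(f"header declares {V} rows but {len(vocab)} were read")
    return EmbeddingModel(vocabulary=vocab, vectors=vectors)
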