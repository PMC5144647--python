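"""Health-text scoring and classification with an n-gram language model.

A language model trained on drug-related chatter assigns higher sequence
probabilities to health-related text than to arbitrary text.  Each text in a
batch is scored by its average log-probability per transition (so length
alone does not dominate; the raw sum is available via a flag), then the
batch is min–max scaled into [0, 1] and thresholded.  The default model
order is 4 (a "tetra-gram" model).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .ngram_lm import NGramModel

HEALTH = "health"
NON_HEALTH = "non-health"
UNLABELED = "unlabeled"


@dataclass(frozen=True)
class ScoredText:
    text_id: str
    raw: float  # per-transition (or total, if length_normalize=False) log-prob
    scaled: float  # min-max scaled within the batch, in [0, 1]
    label: str = UNLABELED


def score_batch(
    model: NGramModel,
    texts: Sequence[Sequence[str]],
    ids: Sequence[str] | None = None,
    length_normalize: bool = True,
) -> list[ScoredText]:
    """Score token sequences and min–max scale within the batch.

    Scaling maps the lowest raw score to 0 and the highest to 1, preserving
    order; a degenerate batch (all raw scores equal, including a singleton
    batch) maps everything to 0.5.
    """
    if not texts:
        raise ValueError("cannot score an empty batch")
    if ids is None:
        ids = [str(i) for i in range(len(texts))]
    if len(ids) != len(texts):
        raise ValueError("ids and texts lengths differ")
    raws = []
    for toks in texts:
        lp = model.sequence_logprob(toks)
        raws.append(lp / (len(toks) + 1) if length_normalize else lp)
    lo, hi = min(raws), max(raws)
    if hi == lo:
        scaled = [0.5] * len(raws)
    else:
        scaled = [(r - lo) / (hi - lo) for r in raws]
    return [ScoredText(i, r, s) for i, r, s in zip(ids, raws, scaled)]


def classify(scored: Sequence[ScoredText], threshold: float = 0.5) -> list[ScoredText]:
    """Label each text health iff its scaled score >= threshold."""
    return [
        replace(s, label=HEALTH if s.scaled >= threshold else NON_HEALTH)
        for s in scored
    ]


def evaluate(labeled: Sequence[ScoredText], gold: Sequence[int]) -> dict[str, float]:
    """Binary metrics for health (positive = 1) predictions against gold.

    Accuracy/precision/recall/F1 use the hard labels; AUC is the rank
    statistic over scaled scores, with tied scores counted 1/2.
    """
    if len(labeled) != len(gold):
        raise ValueError("predictions and gold labels differ in length")
    pred = [1 if s.label == HEALTH else 0 for s in labeled]
    scores = [s.scaled for s in labeled]
    return {
        "accuracy": float(accuracy_score(gold, pred)),
        "precision": float(precision_score(gold, pred, zero_division=0)),
        "recall": float(recall_score(gold, pred, zero_division=0)),
        "f1": float(f1_score(gold, pred, zero_division=0)),
        "auc": float(roc_auc_score(gold, scores)),
    }
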