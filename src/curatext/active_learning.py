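"""Uncertainty-based sentence selection by normalized N-best entropy.

A sentence's informativeness is the Shannon entropy (base 2) of its top-N
predicted label sequences' conditional probabilities, renormalized to sum to
one, divided by log2(N) so the score lies in [0, 1].  Uniform top-N mass
scores 1 (maximal uncertainty); all mass on one sequence scores 0.  The
annotation protocol this supports: train on a small seed set, score an
unlabelled pool, hand the top-K sentences to the annotator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crf_tagger import FeatureRow, LabelHypothesis, TaggerModel, nbest

#: defaults of the selection protocol: top-3 hypotheses, batches of 500
DEFAULT_N = 3
DEFAULT_BATCH = 500


def normalized_entropy(probabilities, N: int) -> float:
    """Normalized entropy of top-N sequence probabilities, in [0, 1].

    Probabilities are renormalized by their sum; entropy uses log base 2
    with 0·log0 = 0; the normalizer is log2(N) regardless of how many
    hypotheses were actually returned (short sentences may have fewer than
    N), keeping scores comparable across sentences.
    """
    p = np.asarray(list(probabilities), dtype=float)
    if p.size == 0:
        raise ValueError("no probabilities given")
    if (p < 0).any():
        raise ValueError("negative probability")
    if not 1 <= p.size <= N:
        raise ValueError(f"expected between 1 and N={N} probabilities, got {p.size}")
    total = p.sum()
    if total <= 0:
        raise ValueError("probabilities sum to zero")
    if N == 1:
        return 0.0
    q = p / total
    nz = q[q > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return entropy / np.log2(N)


@dataclass(frozen=True)
class ALPoolItem:
    """One pool sentence with its top-N hypotheses and uncertainty score."""
    index: int
    hypotheses: tuple[LabelHypothesis, ...]
    score: float


def score_sentence(rows: list[FeatureRow], model: TaggerModel,
                   N: int = DEFAULT_N) -> tuple[tuple[LabelHypothesis, ...], float]:
    hyps = tuple(nbest(rows, model, N))
    if not hyps:
        return (), 0.0
    return hyps, normalized_entropy([h.probability for h in hyps], N)


def select_batch(
    pool: list[list[FeatureRow]],
    model: TaggerModel,
    N: int = DEFAULT_N,
    K: int = DEFAULT_BATCH,
) -> list[ALPoolItem]:
    """Rank pool sentences by normalized entropy, descending; return the top
    K.  Ties are broken by pool order (document, then sentence index), so
    selection is deterministic.  An empty pool yields an empty result."""
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    items = []
    for i, rows in enumerate(pool):
        hyps, score = score_sentence(rows, model, N)
        items.append(ALPoolItem(i, hyps, score))
    items.sort(key=lambda it: (-it.score, it.index))
    return items[:K]
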