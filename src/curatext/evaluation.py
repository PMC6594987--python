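"""Span-level evaluation: strict/relaxed matching, inter-annotator
agreement, and the train/test/validate corpus split.

Strict matching counts a predicted span as correct only when both character
boundaries equal a gold span's; relaxed matching accepts any character
overlap.  Under relaxed matching each gold span can be consumed at most once
(greedy left-to-right pairing), so several predictions overlapping one gold
span yield one true positive plus false positives.  Precision is defined as
0 when there are no predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus_io import SpanAnnotation

MODES = ("strict", "relaxed")


@dataclass(frozen=True)
class EvalReport:
    entity_type: str
    mode: str
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def _match_counts(
    predicted: list[SpanAnnotation],
    gold: list[SpanAnnotation],
    mode: str,
) -> tuple[int, int, int]:
    if mode == "strict":
        pred_set = {(s.begin, s.end) for s in predicted}
        gold_set = {(s.begin, s.end) for s in gold}
        tp = len(pred_set & gold_set)
        return tp, len(pred_set) - tp, len(gold_set) - tp
    # relaxed: greedy left-to-right pairing, each gold matched at most once
    preds = sorted(predicted, key=lambda s: (s.begin, s.end))
    golds = sorted(gold, key=lambda s: (s.begin, s.end))
    used = [False] * len(golds)
    tp = 0
    for p in preds:
        for j, g in enumerate(golds):
            if not used[j] and p.begin < g.end and g.begin < p.end:
                used[j] = True
                tp += 1
                break
    return tp, len(preds) - tp, len(golds) - tp


def prf(
    predicted: list[SpanAnnotation],
    gold: list[SpanAnnotation],
    mode: str = "strict",
) -> EvalReport:
    """Precision/recall/F1 of predicted against gold spans of one type."""
    if mode not in MODES:
        raise ValueError(f"unknown matching mode: {mode!r}")
    types = {s.entity_type for s in predicted} | {s.entity_type for s in gold}
    if len(types) > 1:
        raise ValueError(f"mixed entity types in one evaluation: {sorted(types)}")
    entity_type = next(iter(types)) if types else "none"
    tp, fp, fn = _match_counts(predicted, gold, mode)
    return EvalReport(entity_type, mode, tp, fp, fn)


def evaluate_by_type(
    predicted: list[SpanAnnotation],
    gold: list[SpanAnnotation],
    mode: str = "strict",
) -> dict[str, EvalReport]:
    """Split mixed-type span lists by entity type and evaluate each."""
    types = sorted({s.entity_type for s in predicted} | {s.entity_type for s in gold})
    return {
        t: prf([s for s in predicted if s.entity_type == t],
               [s for s in gold if s.entity_type == t], mode)
        for t in types
    }


def agreement_f1(
    annotations_a: dict[str, list[SpanAnnotation]],
    annotations_b: dict[str, list[SpanAnnotation]],
) -> tuple[dict[str, EvalReport], EvalReport]:
    """Inter-annotator agreement as strict-match F1, per type and overall.

    ``annotations_a``/``annotations_b`` map document ids to span lists; the
    annotators must cover a common document set.  Annotator A is the
    reference; F1 is symmetric under exchanging annotators (precision and
    recall swap).  Only annotated spans enter the score — agreement on
    unannotated tokens is never rewarded.
    """
    common = set(annotations_a) & set(annotations_b)
    if not common:
        raise ValueError("annotators share no documents")
    per_type_counts: dict[str, list[int]] = {}
    total = [0, 0, 0]
    for doc_id in sorted(common):
        a, b = annotations_a[doc_id], annotations_b[doc_id]
        types = sorted({s.entity_type for s in a} | {s.entity_type for s in b})
        for t in types:
            tp, fp, fn = _match_counts(
                [s for s in b if s.entity_type == t],
                [s for s in a if s.entity_type == t],
                "strict",
            )
            counts = per_type_counts.setdefault(t, [0, 0, 0])
            for i, v in enumerate((tp, fp, fn)):
                counts[i] += v
                total[i] += v
    per_type = {
        t: EvalReport(t, "strict", *c) for t, c in sorted(per_type_counts.items())
    }
    overall = EvalReport("all", "strict", *total)
    return per_type, overall


def split_corpus(
    sentences: list,
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Shuffle sentences with the seed and partition into
    (train, test, validate) at the given ratios (default 70/15/15).

    Test and validate sizes are the rounded ratio shares; rounding remainder
    goes to train.  Partitions are disjoint and cover the input.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    n = len(sentences)
    order = np.random.default_rng(seed).permutation(n)
    n_test = int(round(ratios[1] * n))
    n_val = int(round(ratios[2] * n))
    n_train = n - n_test - n_val
    if n_train < 0:
        raise ValueError("rounded test/validate shares exceed the corpus")
    train = [sentences[i] for i in order[:n_train]]
    test = [sentences[i] for i in order[n_train:n_train + n_test]]
    val = [sentences[i] for i in order[n_train + n_test:]]
    return train, test, val
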